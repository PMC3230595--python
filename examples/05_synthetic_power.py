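"""Generate synthetic datasets and check that the pipeline detects an
injected ecological effect (and stays quiet when there is none).

The generator evolves species means by Brownian motion on the study tree,
applies sex-specific allometries, clusters habitat phylogenetically, and
draws individuals around species means, so the synthetic tables have the
same layout and statistical structure as the real ones.
"""

import numpy as np

from phylodigit import (
    SimulationParams,
    generate_dataset,
    gls_fit,
    phylo_covariance,
)
from phylodigit.traits import build_species_table

params = SimulationParams(seed=0)
tree = params.tree
species = tree.tip_labels
C = phylo_covariance(tree)


def pgls_perch_slope(seed: int, effect: float):
    morph, eco, _ = generate_dataset(
        SimulationParams(seed=seed, ecological_effect=effect)
    )
    ds = build_species_table(morph, eco, tree)
    y = ds.table.loc[species, "resid_fl_f"].to_numpy()
    x = ds.table.loc[species, "perches"].to_numpy()
    X = np.column_stack([np.ones(len(x)), x])
    fit = gls_fit(y, X, C)
    return fit.slope, fit.slope_p


for effect, label in ((0.0, "null"), (0.2, "injected perch effect")):
    slopes, rejections = [], 0
    n_rep = 40
    for s in range(n_rep):
        slope, p = pgls_perch_slope(100 + s, effect)
        slopes.append(slope)
        rejections += p < 0.05
    print(f"{label}: mean PGLS slope {np.mean(slopes):+.3f}, "
          f"rejection rate {rejections / n_rep:.2f} ({n_rep} replicates)")
# Under the null the slope is centred on zero and rejections sit near the
# nominal 5%; lengthening the female front-limb digit IV with perch use
# produces a clearly negative slope detected in most replicates.
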