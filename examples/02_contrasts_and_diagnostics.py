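"""Independent contrasts of the packaged data, and the diagnostic used to
choose among branch-length schemes.

Each of the 24 standardized contrasts is an independent draw under Brownian
evolution; the phylogenetic correlation of two traits is the correlation of
their contrasts through the origin.  A scheme standardizes adequately when
|contrast| shows no trend against its standard deviation.
"""

from phylodigit import (
    assign_branch_lengths,
    contrast_correlation,
    independent_contrasts,
    load_morphometrics,
    load_substrate_indices,
    load_tree,
    standardization_diagnostic,
)
from phylodigit.traits import build_species_table

ds = build_species_table(load_morphometrics(), load_substrate_indices(),
                         load_tree())
tree = ds.tree  # Nee branch lengths by default

ratio = independent_contrasts(tree, ds.table["ratio_fl_m"].to_dict())
size = independent_contrasts(tree, ds.table["log_svl_m"].to_dict())
print(f"{ratio.count} contrasts from {tree.n_tips} species")

corr = contrast_correlation(ratio, size)
print(f"phylogenetic correlation, male front-limb ratio vs log10 SVL: "
      f"r = {corr.r:.3f} (df = {corr.df}, P = {corr.p_value:.2g})")
# A strongly positive r: bigger-bodied species have digit II closer in
# length to digit IV, even after removing shared ancestry.

for method in ("constant", "grafen", "pagel", "nee"):
    t = assign_branch_lengths(load_tree(), method)
    cs = independent_contrasts(t, ds.table["ratio_fl_m"].to_dict())
    d = standardization_diagnostic(cs)
    print(f"{method:9s} diagnostic slope {d.slope:+.3f} "
          f"(P = {d.p_value:.3f}) -> {'pass' if d.passed else 'FAIL'}")
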