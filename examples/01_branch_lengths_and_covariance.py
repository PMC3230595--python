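"""Assign arbitrary branch lengths to a topology and read off the Brownian
covariance structure they imply.

With no divergence-time estimates, lengths come from the topology alone;
under Brownian trait evolution the expected covariance between two species
equals their shared root-to-ancestor path length.
"""

import numpy as np

from phylodigit import assign_branch_lengths, parse_newick, phylo_covariance

tree = parse_newick("((A,B),(C,(D,E)));")
for method in ("constant", "grafen", "pagel", "nee"):
    t = assign_branch_lengths(tree, method)
    C = phylo_covariance(t)
    depths = t.root_to_tip_depths()
    print(f"\n{method}: root-to-tip depths "
          f"{ {k: round(v, 3) for k, v in depths.items()} }")
    print(np.round(C.matrix, 3))

# The diagonal is each species' total expected variance; off-diagonals are
# the variance shared through common ancestry. The three ultrametric schemes
# (grafen, pagel, nee) give every tip the same total depth; 'constant' does
# not, so tips behind more nodes accumulate more expected variance.
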