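"""Phylogenetically independent contrasts and their diagnostics.

Under Brownian evolution, the difference between trait values of two sister
lineages, divided by the square root of the expected variance of that
difference (the summed, adjusted branch lengths), is a draw from a single
normal distribution: standardized contrasts are exchangeable and can feed
ordinary statistics.  This module implements the classic pruning recursion,
correlation of two contrast sets through the origin, and the diagnostic
regression of absolute standardized contrasts on their standard deviations
used to choose among arbitrary branch-length schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    BranchLengthError,
    DataError,
    DegenerateNodeError,
    TreeValidationError,
    UndefinedStatisticError,
)
from .stats import t_sf_two_sided
from .tree import PhyloTree


@dataclass
class ContrastSet:
    """Standardized independent contrasts in postorder of internal nodes."""

    node_ids: list[str]
    raw: np.ndarray
    sd: np.ndarray
    standardized: np.ndarray

    @property
    def count(self) -> int:
        return len(self.raw)


@dataclass(frozen=True)
class ContrastCorrelation:
    r: float
    df: int
    p_value: float


@dataclass(frozen=True)
class DiagnosticResult:
    slope: float
    p_value: float
    passed: bool
    degenerate: bool = False


def independent_contrasts(tree: PhyloTree, trait: dict[str, float]) -> ContrastSet:
    """Felsenstein's pruning recursion on a binary tree.

    At an internal node with child values x1, x2 and adjusted branch
    lengths v1, v2: the contrast is x1 - x2 with standard deviation
    sqrt(v1 + v2); the node is assigned the precision-weighted value
    (x1/v1 + x2/v2) / (1/v1 + 1/v2) and its parent branch is lengthened by
    v1 v2 / (v1 + v2).  Zero-length child branches (from polytomy
    resolution) are allowed singly; both zero raises
    :class:`DegenerateNodeError`.
    """
    if not tree.is_binary():
        raise TreeValidationError("contrasts require a strictly binary tree")
    if not tree.has_branch_lengths():
        raise BranchLengthError("assign branch lengths before contrasts")
    missing = [t for t in tree.tip_labels if t not in trait]
    if missing:
        raise DataError(f"trait values missing for tips: {missing}")

    values: dict = {}
    vlens: dict = {}
    node_ids, raws, sds = [], [], []
    counter = 0
    for node in tree.postorder_nodes():
        if node.is_leaf():
            values[node] = float(trait[node.taxon.label.replace(" ", "_")])
            vlens[node] = float(node.edge.length)
            continue
        c1, c2 = node.child_nodes()
        x1, x2 = values[c1], values[c2]
        v1, v2 = vlens[c1], vlens[c2]
        if v1 + v2 <= 0.0:
            label = node.taxon.label if node.taxon else f"internal#{counter}"
            raise DegenerateNodeError(
                f"node {label}: both child branches have zero adjusted length"
            )
        raw = x1 - x2
        sd = np.sqrt(v1 + v2)
        # precision-weighted mean, written so equal child values stay exact
        # and a single zero-length branch passes its value through
        values[node] = x2 + v2 * (x1 - x2) / (v1 + v2)
        own = float(node.edge.length) if node.parent_node is not None else 0.0
        vlens[node] = own + v1 * v2 / (v1 + v2)
        node_ids.append(node.taxon.label if node.taxon else f"internal#{counter}")
        raws.append(raw)
        sds.append(sd)
        counter += 1

    raw_arr = np.array(raws)
    sd_arr = np.array(sds)
    return ContrastSet(node_ids, raw_arr, sd_arr, raw_arr / sd_arr)


def contrast_correlation(cx: ContrastSet, cy: ContrastSet) -> ContrastCorrelation:
    """Correlation of two contrast sets, constrained through the origin.

    r = sum(x_i y_i) / sqrt(sum x_i^2 * sum y_i^2), with a two-sided P from
    t = r sqrt(df / (1 - r^2)) on df = (number of contrasts) - 1 degrees of
    freedom (the through-origin convention of the contrasts literature).
    """
    if cx.count != cy.count:
        raise DataError("contrast sets differ in length")
    if cx.node_ids != cy.node_ids:
        raise DataError("contrast sets come from different trees/orders")
    if cx.count < 3:
        raise DataError("need at least 3 contrasts")
    x, y = cx.standardized, cy.standardized
    sx2 = float(np.sum(x * x))
    sy2 = float(np.sum(y * y))
    if sx2 == 0.0 or sy2 == 0.0:
        raise UndefinedStatisticError(
            "contrast correlation undefined: zero sum of squares"
        )
    r = float(np.sum(x * y) / np.sqrt(sx2 * sy2))
    r = max(-1.0, min(1.0, r))
    df = cx.count - 1
    if abs(r) == 1.0:
        return ContrastCorrelation(r, df, 0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    return ContrastCorrelation(r, df, t_sf_two_sided(t, df))


def standardization_diagnostic(
    contrasts: ContrastSet, alpha: float = 0.05
) -> DiagnosticResult:
    """Regress |standardized contrast| on its standard deviation.

    Branch lengths standardize the contrasts adequately when the absolute
    standardized contrasts show no trend against their standard deviations;
    the scheme passes when the slope's two-sided P exceeds ``alpha``.
    All-identical standard deviations leave the slope undefined and are
    reported as a degenerate (but passing) diagnostic.
    """
    if contrasts.count < 3:
        raise DataError("need at least 3 contrasts for the diagnostic")
    x = contrasts.sd
    y = np.abs(contrasts.standardized)
    n = len(x)
    xc = x - x.mean()
    sxx = float(np.sum(xc * xc))
    if sxx == 0.0:
        return DiagnosticResult(np.nan, np.nan, passed=True, degenerate=True)
    slope = float(np.sum(xc * (y - y.mean())) / sxx)
    resid = y - y.mean() - slope * xc
    s2 = float(np.sum(resid**2)) / (n - 2)
    if s2 == 0.0:
        p = 0.0 if slope != 0 else 1.0
    else:
        se = np.sqrt(s2 / sxx)
        p = t_sf_two_sided(slope / se, n - 2)
    return DiagnosticResult(slope, p, passed=p > alpha)
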