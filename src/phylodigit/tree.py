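"""Rooted species trees: parsing, arbitrary branch lengths, Brownian covariance.

The comparative methods in this package operate on a rooted topology whose
branch lengths are in arbitrary units of expected variance of trait
evolution.  When divergence times are unavailable, lengths are assigned
analytically from the topology alone using one of four classical schemes
(constant, Grafen, Pagel, Nee); under a Brownian-motion model the expected
covariance between two tips is then the shared root-to-ancestor path length.

Newick I/O is delegated to :mod:`dendropy`; :class:`PhyloTree` is a thin,
validated wrapper around a ``dendropy.Tree`` that the rest of the package
treats as immutable (transforms return copies).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import dendropy
import numpy as np

from .errors import (
    BranchLengthError,
    ConfigurationError,
    NewickParseError,
    TreeValidationError,
)

BRANCH_LENGTH_METHODS = ("constant", "grafen", "pagel", "nee")


@dataclass
class PhyloTree:
    """A rooted phylogeny with optional branch lengths.

    Wraps a ``dendropy.Tree``.  Tip labels are unique species names; branch
    lengths (``edge.length``) may be unset (``None``) until assigned by
    :func:`assign_branch_lengths`.
    """

    dtree: dendropy.Tree
    method: str | None = field(default=None)

    def __post_init__(self) -> None:
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        tips = self.tip_labels
        if len(tips) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        dupes = {t for t in tips if tips.count(t) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for leaf in self.dtree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeValidationError("unlabeled tip in tree")

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in the tree's stable (postorder-of-first-visit) order."""
        return [
            leaf.taxon.label.replace(" ", "_")
            for leaf in self.dtree.leaf_node_iter()
        ]

    @property
    def n_tips(self) -> int:
        return len(self.dtree.leaf_nodes())

    def is_binary(self) -> bool:
        for node in self.dtree.preorder_node_iter():
            nch = len(node.child_nodes())
            if nch not in (0, 2):
                return False
        return True

    def has_branch_lengths(self) -> bool:
        return all(
            node.edge.length is not None
            for node in self.dtree.preorder_node_iter()
            if node.parent_node is not None
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.dtree.clone(depth=1), method=self.method)

    def postorder_nodes(self) -> Iterator[dendropy.Node]:
        return self.dtree.postorder_node_iter()

    # -- I/O ---------------------------------------------------------------
    def to_newick(self) -> str:
        return self.dtree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- heights -----------------------------------------------------------
    def root_to_tip_depths(self) -> dict[str, float]:
        """Sum of branch lengths from the root to each tip."""
        if not self.has_branch_lengths():
            raise BranchLengthError("branch lengths are unset")
        depths: dict[dendropy.Node, float] = {}
        out: dict[str, float] = {}
        for node in self.dtree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
            if node.is_leaf():
                out[node.taxon.label.replace(" ", "_")] = depths[node]
        return out


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted newick string into a :class:`PhyloTree`.

    Lines starting with ``#`` are treated as comments and stripped, so the
    packaged fixture files can carry a documentation header.  Absent branch
    lengths are recorded as unset, not zero.
    """
    payload = "\n".join(
        line for line in text.splitlines() if not line.lstrip().startswith("#")
    ).strip()
    if not payload:
        raise NewickParseError("empty newick input")
    try:
        dtree = dendropy.Tree.get(
            data=payload,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        if "Duplicate taxon label" in str(exc):
            raise TreeValidationError(f"duplicate tip label: {exc}") from exc
        raise NewickParseError(f"malformed newick: {exc}") from exc
    dtree.is_rooted = True
    return PhyloTree(dtree)


def read_newick(path: str | Path) -> PhyloTree:
    """Read a newick file (``#`` header lines allowed)."""
    return parse_newick(Path(path).read_text())


def resolve_polytomies(tree: PhyloTree, seed: int = 0) -> PhyloTree:
    """Resolve multifurcations into zero-length bifurcations.

    Resolution order is deterministic for a fixed ``seed``.  Inserted
    internal branches get length 0 so no artificial shared history is
    created; an already-binary tree is returned unchanged (as a copy).
    """
    out = tree.copy()
    rng = random.Random(seed)
    out.dtree.resolve_polytomies(rng=rng)
    for node in out.dtree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            if not node.is_leaf() and _was_inserted(node):
                node.edge.length = 0.0
    # dendropy labels inserted edges with length None; make every inserted
    # internal edge explicit zero while leaving genuinely-unset tip lengths
    # alone when the source tree had no lengths at all.
    return PhyloTree(out.dtree, method=tree.method)


def _was_inserted(node: dendropy.Node) -> bool:
    return node.taxon is None and node.edge.length is None


def _count_descendant_tips(dtree: dendropy.Tree) -> dict[dendropy.Node, int]:
    counts: dict[dendropy.Node, int] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            counts[node] = 1
        else:
            counts[node] = sum(counts[c] for c in node.child_nodes())
    return counts


def assign_branch_lengths(tree: PhyloTree, method: str = "nee") -> PhyloTree:
    """Assign arbitrary branch lengths from the topology alone.

    ``constant``
        every branch length 1 (not ultrametric in general).
    ``grafen``
        node height = (number of descendant tips - 1), scaled so the root
        is at height 1 and tips at 0; branch = parent height - child height.
    ``pagel``
        node depth = 1 + max(child depths), tips at 0 (ultrametric);
        branch = parent depth - child depth.
    ``nee``
        node height = ln(number of descendant tips), tips at ln 1 = 0;
        branch = ln n(parent) - ln n(child).

    Heights for Grafen and Nee are defined up to a global scale factor,
    which cancels in GLS estimates; the conventions above (root height 1,
    natural log) are fixed so outputs are reproducible.
    """
    if method not in BRANCH_LENGTH_METHODS:
        raise ConfigurationError(
            f"unknown branch-length method {method!r}; "
            f"choose one of {BRANCH_LENGTH_METHODS}"
        )
    out = tree.copy()
    dtree = out.dtree
    if method == "constant":
        for node in dtree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = 1.0
    else:
        counts = _count_descendant_tips(dtree)
        root = dtree.seed_node
        if method == "grafen":
            denom = counts[root] - 1
            height = {n: (counts[n] - 1) / denom for n in counts}
        elif method == "nee":
            height = {n: math.log(counts[n]) for n in counts}
        else:  # pagel: depths bottom-up, then read as heights
            height = {}
            for node in dtree.postorder_node_iter():
                if node.is_leaf():
                    height[node] = 0.0
                else:
                    height[node] = 1.0 + max(
                        height[c] for c in node.child_nodes()
                    )
        for node in dtree.preorder_node_iter():
            if node.parent_node is not None:
                bl = height[node.parent_node] - height[node]
                if bl < 0:
                    raise BranchLengthError(
                        f"negative branch length under {method}"
                    )
                node.edge.length = bl
    return PhyloTree(dtree, method=method)


@dataclass
class CovarianceMatrix:
    """Brownian expected covariance among tips, with its tip order."""

    matrix: np.ndarray
    tip_order: list[str]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise TreeValidationError("covariance matrix must be square")
        if m.shape[0] != len(self.tip_order):
            raise TreeValidationError("tip order does not match matrix size")

    def reordered(self, tip_order: list[str]) -> "CovarianceMatrix":
        """Return a copy with rows/columns permuted to ``tip_order``."""
        idx = [self.tip_order.index(t) for t in tip_order]
        return CovarianceMatrix(self.matrix[np.ix_(idx, idx)], list(tip_order))


def phylo_covariance(tree: PhyloTree) -> CovarianceMatrix:
    """Expected Brownian covariance matrix of tip values.

    Entry (i, j) is the summed branch length on the path from the root to
    the most recent common ancestor of tips i and j; diagonal entries are
    root-to-tip path lengths.
    """
    if not tree.has_branch_lengths():
        raise BranchLengthError("assign branch lengths before the covariance")
    dtree = tree.dtree
    tip_order = tree.tip_labels
    index = {label: k for k, label in enumerate(tip_order)}
    n = len(tip_order)
    C = np.zeros((n, n))

    node_depth: dict[dendropy.Node, float] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            node_depth[node] = 0.0
        else:
            node_depth[node] = node_depth[node.parent_node] + node.edge.length

    # For each internal node, tip pairs split across different children have
    # that node as their MRCA; covariance = depth of the node.
    tips_below: dict[dendropy.Node, list[int]] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            k = index[node.taxon.label.replace(" ", "_")]
            C[k, k] = node_depth[node]
            tips_below[node] = [k]
        else:
            children = node.child_nodes()
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in tips_below[children[a]]:
                        for j in tips_below[children[b]]:
                            C[i, j] = C[j, i] = node_depth[node]
            tips_below[node] = [
                t for c in children for t in tips_below[c]
            ]
    return CovarianceMatrix(C, tip_order)
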