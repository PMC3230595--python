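"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phylodigit import (
    assign_branch_lengths,
    load_morphometrics,
    load_substrate_indices,
    load_tree,
    parse_newick,
)
from phylodigit.traits import build_species_table


def random_binary_newick(rng: np.random.Generator, n_tips: int) -> str:
    """A random rooted binary topology with branch lengths in [0.1, 2]."""

    def build(labels):
        if len(labels) == 1:
            return labels[0]
        split = int(rng.integers(1, len(labels)))
        left, right = labels[:split], labels[split:]
        bl1, bl2 = rng.uniform(0.1, 2.0, size=2)
        return f"({build(left)}:{bl1:.6f},{build(right)}:{bl2:.6f})"

    labels = [f"t{i}" for i in range(n_tips)]
    order = rng.permutation(n_tips)
    return build([labels[i] for i in order]) + ";"


def random_tree(rng: np.random.Generator, n_tips: int):
    return parse_newick(random_binary_newick(rng, n_tips))


def brute_force_covariance(tree) -> tuple[np.ndarray, list[str]]:
    """Oracle: C[i, j] = summed lengths of shared root-to-tip edges."""
    paths = {}
    for leaf in tree.dtree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append((id(node), node.edge.length))
            node = node.parent_node
        paths[leaf.taxon.label.replace(" ", "_")] = edges
    tips = tree.tip_labels
    n = len(tips)
    C = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            ids_b = {e for e, _ in paths[b]}
            C[i, j] = sum(l for e, l in paths[a] if e in ids_b)
    return C, tips


@pytest.fixture(scope="session")
def fixture_tree():
    return load_tree()


@pytest.fixture(scope="session")
def nee_tree(fixture_tree):
    return assign_branch_lengths(fixture_tree, "nee")


@pytest.fixture(scope="session")
def morphometrics():
    return load_morphometrics()


@pytest.fixture(scope="session")
def substrate_indices():
    return load_substrate_indices()


@pytest.fixture(scope="session")
def species_dataset(morphometrics, substrate_indices, fixture_tree):
    return build_species_table(morphometrics, substrate_indices, fixture_tree)
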