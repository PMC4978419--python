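"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phylospace import parse_newick, spectral_profile
from phylospace.synthetic import planted_type_corpus
from phylospace.tree_io import TreeRecord


# -- independent oracles -------------------------------------------------


def path_to_root(t: TreeRecord, node: int) -> list[int]:
    out = [node]
    while t.parent[out[-1]] >= 0:
        out.append(int(t.parent[out[-1]]))
    return out


def brute_force_node_distances(t: TreeRecord) -> np.ndarray:
    """All-pairs path lengths by explicit path walking (no graph library).

    Independent of `node_distance_matrix`: distances come from summing
    branch lengths along the two root paths above the most recent common
    ancestor.
    """
    n = t.n_nodes
    D = np.zeros((n, n))
    paths = [path_to_root(t, i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            anc_j = set(paths[j])
            lca = next(a for a in paths[i] if a in anc_j)
            d = 0.0
            for a in paths[i]:
                if a == lca:
                    break
                d += t.edge_length[a]
            for a in paths[j]:
                if a == lca:
                    break
                d += t.edge_length[a]
            D[i, j] = D[j, i] = d
    return D


def random_newick(n_tips: int, rng: np.random.Generator) -> str:
    """A random binary tree with U(0.1, 2) branch lengths, as Newick text."""
    subtrees = [f"t{i}" for i in range(n_tips)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        la, lb = rng.uniform(0.1, 2.0, size=2)
        subtrees.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return subtrees[0] + ";"


def tip_distance_map(t: TreeRecord) -> dict:
    """Label-keyed pairwise tip distances (via the brute-force oracle)."""
    D = brute_force_node_distances(t)
    out = {}
    for i in range(t.n_tips):
        for j in range(i + 1, t.n_tips):
            key = tuple(sorted((t.tip_labels[i], t.tip_labels[j])))
            out[key] = D[i, j]
    return out


# -- fixtures ------------------------------------------------------------


@pytest.fixture(scope="session")
def small_planted_corpus():
    """A reduced planted corpus shared across tests (12 trees per regime)."""
    trees, labels = planted_type_corpus(n_per_type=12, seed=77)
    return trees, labels


@pytest.fixture(scope="session")
def small_planted_profiles(small_planted_corpus):
    trees, labels = small_planted_corpus
    return [spectral_profile(t) for t in trees], labels


@pytest.fixture
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")
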