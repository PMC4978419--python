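"""Random constrained-Laplacian "phylogeny-type networks".

To chart the space of trees available in principle (not just those realized
by evolution), random weighted-graph Laplacians are drawn — symmetric
positive-semidefinite M-matrices with zero row sums — and converted into
bifurcating, rooted, ultrametric trees: all-pairs Dijkstra distances over
the implied weighted graph, a complete-linkage dendrogram on those
distances, mean-path-length ultrametricization, and polytomy resolution.
Each final tree's branches are rescaled so that its own spectral
``lambda_star`` hits a target drawn from a supplied pool (eigenvalues are
linear in branch lengths, so the constraint is exactly attainable); this
keeps the sampled corpus inside the empirical ``lambda_star`` range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.linalg import eigvalsh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import squareform

from .spectral import SpectralProfile, spectral_profile
from .tree_io import TreeRecord, mpl_ultrametricize, resolve_polytomies

__all__ = [
    "SamplerConfig",
    "sample_mgl_matrix",
    "matrix_to_tree",
    "generate_network_corpus",
]


@dataclass
class SamplerConfig:
    """Generative parameters for a corpus of phylogeny-type networks.

    ``edge_density=None`` draws a per-tree density log-uniformly between a
    connectivity floor (~2 ln n / n) and 1; together with a per-tree
    lognormal weight dispersion drawn from ``sigma_range`` this produces a
    heterogeneous corpus that charts a wide range of tree shapes.  A fixed
    ``edge_density`` and ``weight_law='exponential'`` recover the dense
    exchangeable law.
    """

    n_nodes_range: tuple = (20, 100)
    target_lambda_star_pool: Sequence[float] = (np.log(5.0),)
    n_trees: int = 100
    seed: int = 0
    edge_density: Optional[float] = None
    weight_law: str = "lognormal"  # 'lognormal' | 'exponential'
    sigma_range: tuple = (0.2, 2.5)  # lognormal dispersion, drawn per tree

    def __post_init__(self) -> None:
        if self.n_nodes_range[0] < 3:
            raise ValueError("n_nodes must be at least 3")
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if len(self.target_lambda_star_pool) == 0:
            raise ValueError("target pool must be non-empty")


def sample_mgl_matrix(
    n: int,
    target_lambda_star: float,
    seed: int = 0,
    edge_density: float = 1.0,
    weight_law: str = "exponential",
    sigma: float = 1.0,
    max_retries: int = 50,
) -> np.ndarray:
    """Random symmetric PSD M-matrix with zero row sums and fixed lambda_star.

    Off-diagonal entries are (negated) i.i.d. weights — Exponential(1) or
    Lognormal(0, sigma) — on a complete graph, thinned to ``edge_density``
    (disconnected draws are resampled).  The matrix is rescaled so
    ``ln(largest eigenvalue) == target_lambda_star``.
    """
    if n < 3:
        raise ValueError("n must be at least 3")
    if not np.isfinite(target_lambda_star):
        raise ValueError("target lambda_star must be finite")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        W = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        if weight_law == "exponential":
            w = rng.exponential(1.0, size=iu[0].size)
        elif weight_law == "lognormal":
            w = rng.lognormal(0.0, sigma, size=iu[0].size)
        else:
            raise ValueError(f"unknown weight_law {weight_law!r}")
        if edge_density < 1.0:
            w *= rng.random(iu[0].size) < edge_density
        W[iu] = w
        W = W + W.T
        ncomp, _ = connected_components(csr_matrix(W), directed=False)
        if ncomp != 1:
            continue
        L = np.diag(W.sum(axis=1)) - W
        lam_max = eigvalsh(L)[-1]
        return L * (np.exp(target_lambda_star) / lam_max)
    raise RuntimeError("could not sample a connected weighted graph")


def matrix_to_tree(L: np.ndarray, seed: int = 0) -> TreeRecord:
    """Convert a Laplacian-like matrix into a binary, rooted, ultrametric tree.

    Edge weights are the magnitudes of the off-diagonal entries; all-pairs
    shortest paths (Dijkstra) give a distance matrix; complete-linkage
    clustering turns it into a rooted dendrogram (node age = half the merge
    height); mean-path-length ultrametricization and polytomy resolution
    finish the job.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(L, L.T, rtol=1e-8, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    n = L.shape[0]
    W = -np.asarray(L, dtype=float)
    np.fill_diagonal(W, 0.0)
    W = np.abs(W) * (np.abs(W) > 0)
    D = dijkstra(csr_matrix(W), directed=False)
    if not np.all(np.isfinite(D)):
        raise ValueError("implied graph is disconnected")
    Z = linkage(squareform(D, checks=False), method="complete")
    tree = linkage_to_tree(Z, [f"t{i}" for i in range(n)])
    tree = mpl_ultrametricize(tree)
    tree = resolve_polytomies(tree, seed=seed)
    return tree


def linkage_to_tree(Z: np.ndarray, tip_labels: Sequence[str]) -> TreeRecord:
    """Rooted ultrametric tree from a scipy linkage matrix.

    A merge at height h becomes an internal node at age h/2, so tip-to-tip
    cophenetic distances equal the merge heights.
    """
    n = len(tip_labels)
    age = {i: 0.0 for i in range(n)}
    parent_of, length_of, children_of = {}, {}, {}
    for j, (a, b, h, _) in enumerate(Z):
        node = n + j
        a, b = int(a), int(b)
        age[node] = h / 2.0
        children_of[node] = [a, b]
        for c in (a, b):
            parent_of[c] = node
            length_of[c] = age[node] - age[c]
    root = n + Z.shape[0] - 1
    return TreeRecord.from_links(
        parent_of, length_of, children_of, list(range(n)), list(tip_labels), root
    )


def generate_network_corpus(cfg: SamplerConfig) -> list[tuple[TreeRecord, SpectralProfile]]:
    """Sample ``cfg.n_trees`` phylogeny-type networks with matched lambda_star.

    Each tree's branch lengths are rescaled so its own profile's
    ``lambda_star`` equals its drawn target (the spectrum is linear in
    branch lengths); the profile is recomputed on the rescaled tree.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    lo, hi = cfg.n_nodes_range
    pool = np.asarray(cfg.target_lambda_star_pool, dtype=float)
    for i in range(cfg.n_trees):
        n = int(rng.integers(lo, hi + 1))
        target = float(pool[rng.integers(pool.size)])
        if cfg.edge_density is None:
            floor = min(1.0, 2.0 * np.log(n) / n)
            density = float(np.exp(rng.uniform(np.log(floor), 0.0)))
        else:
            density = cfg.edge_density
        sigma = float(rng.uniform(*cfg.sigma_range))
        L = sample_mgl_matrix(
            n,
            target,
            seed=int(rng.integers(2**31)),
            edge_density=density,
            weight_law=cfg.weight_law,
            sigma=sigma,
        )
        tree = matrix_to_tree(L, seed=int(rng.integers(2**31)))
        prof = spectral_profile(tree, label=f"net_{i}")
        tree = tree.with_scaled_branches(np.exp(target - prof.lambda_star))
        tree.label = f"net_{i}"
        prof = spectral_profile(tree, label=f"net_{i}")
        out.append((tree, prof))
    return out
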