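"""Distances between spectral density profiles and clustering into types.

Profiles are compared with the Jensen–Shannon divergence (natural log, so
values lie in ``[0, ln 2]``) after re-evaluating both densities on a shared
uniform grid.  Trees are grouped by average-linkage hierarchical clustering
with bootstrap clade support and by PAM k-medoids with the number of
clusters selected by optimum average silhouette width (widths above 0.5
read as supported structure).  A per-class multinomial null quantifies
over-/under-representation of taxonomic classes within clusters, and a
stability routine summarizes how clusterings vary across resampled corpora.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import jensenshannon, squareform
from sklearn.metrics import silhouette_samples

from .spectral import SpectralProfile

__all__ = [
    "ProfileDistanceMatrix",
    "ClusteringResult",
    "js_distance",
    "distance_matrix",
    "hierarchical_cluster_bootstrap",
    "kmedoids_select_k",
    "cluster_stability",
    "class_composition_null",
]

DEFAULT_GRID_SIZE = 512
LN2 = float(np.log(2.0))


# -- Jensen–Shannon machinery -------------------------------------------


def _shared_grid(profiles: Sequence[SpectralProfile], grid_size: int) -> np.ndarray:
    lo = min(p.grid[0] for p in profiles)
    hi = max(p.grid[-1] for p in profiles)
    return np.linspace(lo, hi, grid_size)


def profiles_to_matrix(
    profiles: Sequence[SpectralProfile], grid_size: int = DEFAULT_GRID_SIZE
) -> np.ndarray:
    """Discretize profiles on a shared grid as rows summing to 1."""
    grid = _shared_grid(profiles, grid_size)
    X = np.vstack([p.density_at(grid) for p in profiles])
    return _renormalize_rows(X)


def _renormalize_rows(X: np.ndarray) -> np.ndarray:
    # Gaussian tails produce subnormal ordinates that overflow entropy
    # ratios; mass below 1e-15 of the row peak is numerically meaningless
    X = np.where(X < X.max(axis=1, keepdims=True) * 1e-15, 0.0, X)
    s = X.sum(axis=1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("empty density")
    return X / s


def _jsd(P: np.ndarray) -> np.ndarray:
    """Pairwise Jensen–Shannon divergence (nats) between probability rows."""
    n = P.shape[0]
    D = np.zeros((n, n))
    for i in range(n - 1):
        # scipy's jensenshannon returns sqrt(JSD); square back to divergence
        d = jensenshannon(P[i][None, :].repeat(n - i - 1, axis=0).T, P[i + 1 :].T)
        D[i, i + 1 :] = np.square(d)
    D = D + D.T
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, LN2)


def js_distance(
    p: SpectralProfile, q: SpectralProfile, grid_size: int = DEFAULT_GRID_SIZE
) -> float:
    """Jensen–Shannon divergence between two profiles on a shared grid."""
    P = profiles_to_matrix([p, q], grid_size)
    return float(_jsd(P)[0, 1])


@dataclass
class ProfileDistanceMatrix:
    """Symmetric Jensen–Shannon distances between labeled profiles."""

    labels: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise ValueError("distance matrix / label size mismatch")
        self.distances = d

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.distances, checks=False)


def distance_matrix(
    profiles: Sequence[SpectralProfile], grid_size: int = DEFAULT_GRID_SIZE
) -> ProfileDistanceMatrix:
    """All pairwise Jensen–Shannon divergences between profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    labels = [p.label if p.label is not None else f"tree_{i}" for i, p in enumerate(profiles)]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate profile labels")
    P = profiles_to_matrix(profiles, grid_size)
    return ProfileDistanceMatrix(labels, _jsd(P))


# -- clustering ----------------------------------------------------------


@dataclass
class ClusteringResult:
    labels: list[str]
    assignments: np.ndarray  # cluster id per tree
    k: int
    silhouettes: Optional[np.ndarray] = None
    mean_silhouette: float = float("nan")
    cluster_mean_silhouette: dict = field(default_factory=dict)
    medoids: list = field(default_factory=list)
    supported: bool = False
    linkage_matrix: Optional[np.ndarray] = None
    clade_support: Optional[dict] = None  # frozenset(labels) -> bootstrap prob
    silhouette_by_k: dict = field(default_factory=dict)

    def assignment_map(self) -> dict:
        return dict(zip(self.labels, self.assignments.tolist()))


def _clades(Z: np.ndarray, labels: Sequence[str]) -> set[frozenset]:
    """Tip-label sets of every internal node of a scipy linkage tree."""
    root = to_tree(Z)
    out: set[frozenset] = set()

    def walk(node):
        if node.is_leaf():
            return frozenset([labels[node.id]])
        s = walk(node.left) | walk(node.right)
        out.add(s)
        return s

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(labels) + 100))
    try:
        walk(root)
    finally:
        sys.setrecursionlimit(old)
    return out


def hierarchical_cluster_bootstrap(
    profiles: Sequence[SpectralProfile],
    method: str = "average",
    B: int = 1000,
    alpha: float = 0.95,
    seed: int = 0,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> ClusteringResult:
    """Average-linkage dendrogram with bootstrap clade probabilities.

    Bootstrap resamples the shared-grid density ordinates (columns) with
    replacement, recomputes Jensen–Shannon distances and re-clusters; the
    support of a clade is the fraction of resamples in which the same tip
    set forms a clade.  Clades with support >= ``alpha`` count as
    significant.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles")
    if B < 2:
        raise ValueError("B must be at least 2")
    if B < 100:
        warnings.warn("bootstrap with B < 100 replicates is unreliable")
    labels = [p.label if p.label is not None else f"tree_{i}" for i, p in enumerate(profiles)]
    X = profiles_to_matrix(profiles, grid_size)
    Z = linkage(squareform(_jsd(X), checks=False), method=method)
    observed = _clades(Z, labels)
    counts = {c: 0 for c in observed}
    rng = np.random.default_rng(seed)
    G = X.shape[1]
    for _ in range(B):
        idx = rng.integers(0, G, size=G)
        Xb = X[:, idx]
        s = Xb.sum(axis=1, keepdims=True)
        s[s <= 0] = 1.0
        Xb = Xb / s
        Zb = linkage(squareform(_jsd(Xb), checks=False), method=method)
        for c in _clades(Zb, labels) & observed:
            counts[c] += 1
    support = {c: counts[c] / B for c in observed}
    flat = np.zeros(len(labels), dtype=int)  # dendrogram-only result
    return ClusteringResult(
        labels=labels,
        assignments=flat,
        k=1,
        linkage_matrix=Z,
        clade_support=support,
        supported=any(v >= alpha for v in support.values()),
    )


def _pam(D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 200):
    """PAM k-medoids on a precomputed dissimilarity matrix.

    Greedy BUILD followed by best-improvement SWAP; the objective (total
    distance of points to their nearest medoid) is non-increasing.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        dnear = D[:, medoids].min(axis=1)
        gain = np.maximum(dnear[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    medoids = list(medoids)
    for _ in range(max_iter):
        Dm = D[:, medoids]
        order = np.argsort(Dm, axis=1)
        dnear = Dm[np.arange(n), order[:, 0]]
        inear = np.asarray(medoids)[order[:, 0]]
        dsecond = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = 0.0, None
        base_cost = dnear.sum()
        for mi, m in enumerate(medoids):
            base = np.where(inear == m, dsecond, dnear)
            cand_cost = np.minimum(D, base[:, None]).sum(axis=0)
            cand_cost[medoids] = np.inf
            h = int(np.argmin(cand_cost))
            delta = cand_cost[h] - base_cost
            if delta < best_delta - 1e-12:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    Dm = D[:, medoids]
    assign = np.argmin(Dm, axis=1)
    return np.asarray(medoids), assign


def kmedoids_select_k(
    dm: ProfileDistanceMatrix,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
) -> ClusteringResult:
    """PAM k-medoids over a k range; select k by optimum average silhouette.

    The returned clustering is at the silhouette-optimal k, with per-tree
    silhouette widths, per-cluster means and the supported flag (overall
    mean silhouette > 0.5).  With degenerate (all-equal) distances no k is
    supported and a single cluster is reported.
    """
    n = dm.n
    if n < 4:
        raise ValueError("need at least 4 trees")
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("empty k range")
    D = dm.distances
    if np.allclose(D, 0.0):
        return ClusteringResult(
            labels=dm.labels, assignments=np.zeros(n, dtype=int), k=1, supported=False
        )
    rng = np.random.default_rng(seed)
    best = None
    sil_by_k: dict[int, float] = {}
    for k in k_range:
        medoids, assign = _pam(D, k, rng)
        if len(np.unique(assign)) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = silhouette_samples(D, assign, metric="precomputed")
        sbar = float(np.mean(s))
        sil_by_k[k] = sbar
        if best is None or sbar > best[0]:
            best = (sbar, k, medoids, assign, s)
    if best is None:
        return ClusteringResult(
            labels=dm.labels, assignments=np.zeros(n, dtype=int), k=1, supported=False
        )
    sbar, k, medoids, assign, s = best
    per_cluster = {
        int(c): float(np.mean(s[assign == c])) for c in np.unique(assign)
    }
    return ClusteringResult(
        labels=dm.labels,
        assignments=assign.astype(int),
        k=int(k),
        silhouettes=s,
        mean_silhouette=sbar,
        cluster_mean_silhouette=per_cluster,
        medoids=[dm.labels[m] for m in medoids],
        supported=bool(sbar > 0.5),
        silhouette_by_k=sil_by_k,
    )


# -- robustness ----------------------------------------------------------


def _match_assignments(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Relabel ``b`` to maximally agree with ``a`` (Hungarian matching)."""
    ca, cb = np.unique(a), np.unique(b)
    agree = np.zeros((cb.size, ca.size))
    for i, x in enumerate(cb):
        for j, y in enumerate(ca):
            agree[i, j] = np.sum((b == x) & (a == y))
    ri, ci = linear_sum_assignment(-agree)
    mapping = {int(cb[i]): int(ca[j]) for i, j in zip(ri, ci)}
    fresh = max(ca.max(), cb.max()) + 1
    out = np.empty_like(b)
    for i, x in enumerate(b):
        out[i] = mapping.get(int(x), fresh + int(x))
    return out


def cluster_stability(
    corpora: Sequence[Sequence[SpectralProfile]],
    reference: ClusteringResult,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> dict:
    """Re-cluster each corpus and compare against a reference clustering.

    Reports the fraction of corpora selecting the reference k, the fraction
    with an identical assignment (up to cluster relabeling, matched by
    maximum-agreement Hungarian matching) and the worst-case fraction of
    trees placed differently.
    """
    ref_labels = list(reference.labels)
    ref_assign = np.asarray(reference.assignments)
    same_k = identical = 0
    max_mismatch = 0.0
    for ci, profiles in enumerate(corpora):
        labels = [p.label for p in profiles]
        if set(labels) != set(ref_labels):
            raise ValueError("corpus labels do not match the reference")
        order = [labels.index(l) for l in ref_labels]
        dm = distance_matrix([profiles[i] for i in order], grid_size)
        res = kmedoids_select_k(dm, k_range, seed=seed + ci)
        if res.k == reference.k:
            same_k += 1
        matched = _match_assignments(ref_assign, np.asarray(res.assignments))
        mism = float(np.mean(matched != ref_assign))
        if mism == 0.0:
            identical += 1
        max_mismatch = max(max_mismatch, mism)
    n = len(corpora)
    return {
        "pct_same_k": 100.0 * same_k / n,
        "pct_identical_assignment": 100.0 * identical / n,
        "max_pct_mismatched": 100.0 * max_mismatch,
    }


def class_composition_null(
    assignments: dict,
    class_labels: dict,
    n_iter: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(class, cluster) two-tailed significance against a multinomial null.

    For a class with x trees, x hypothetical trees are dropped into clusters
    with probabilities proportional to cluster sizes, ``n_iter`` times; the
    observed count is significant when it falls in the lower or upper
    ``alpha`` tail of that null.
    """
    if n_iter < 100:
        warnings.warn("composition null with n_iter < 100 is unreliable")
    labels = list(assignments)
    if set(labels) - set(class_labels):
        raise ValueError("every tree needs a class label")
    clusters = sorted(set(assignments.values()))
    sizes = np.array([sum(1 for v in assignments.values() if v == c) for c in clusters])
    p = sizes / sizes.sum()
    rng = np.random.default_rng(seed)
    rows = []
    for cls in sorted(set(class_labels[l] for l in labels)):
        members = [l for l in labels if class_labels[l] == cls]
        x = len(members)
        null = rng.multinomial(x, p, size=n_iter)
        for j, c in enumerate(clusters):
            obs = sum(1 for l in members if assignments[l] == c)
            p_lower = float(np.mean(null[:, j] <= obs))
            p_upper = float(np.mean(null[:, j] >= obs))
            rows.append(
                {
                    "class": cls,
                    "cluster": c,
                    "n_class": x,
                    "observed": obs,
                    "expected": float(x * p[j]),
                    "p_lower": p_lower,
                    "p_upper": p_upper,
                    "significant": bool(min(p_lower, p_upper) < alpha),
                    "direction": "over" if obs > x * p[j] else "under",
                }
            )
    return pd.DataFrame(rows)
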