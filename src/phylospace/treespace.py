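"""Phylogenetic space: mapping, archetypes, trade-offs, volumes, regions.

Trees live as points in the 3-D space spanned by the spectral statistics
(``lambda_star``, ``psi``, ``eta``).  This module fits minimal enclosing
polytopes ("archetypes") to those clouds with an archetypal-analysis-style
alternating optimization followed by a gauge-inflation step that pushes the
vertices out just far enough to enclose every point, tests polytope fits
with a t-ratio permutation test, quantifies pairwise trade-offs between the
statistics with AIC-selected regressions, measures bounding-box occupancy
and overlap between point sets, delimits per-cluster convex-hull regions,
and runs the rarefaction (saturation) analysis of archetype coordinates.

Coordinates are min–max normalized per statistic before any polytope or
contribution computation: the three statistics have incommensurate scales
and per-vertex percentage contributions only make sense on a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .spectral import SpectralProfile

__all__ = [
    "STAT_NAMES",
    "PolytopeFit",
    "RegressionFit",
    "TypeHulls",
    "map_points",
    "fit_polytope",
    "t_ratio_test",
    "archetype_contributions",
    "tradeoff_regressions",
    "volume_stats",
    "type_hulls",
    "rarefaction_saturation",
]

STAT_NAMES = ("lambda_star", "psi", "eta")


def map_points(profiles: Sequence[SpectralProfile]) -> pd.DataFrame:
    """One (lambda_star, psi, eta) point per profile, coordinates verbatim."""
    rows = []
    for i, p in enumerate(profiles):
        coords = (p.lambda_star, p.psi, p.eta)
        if not all(np.isfinite(coords)):
            raise ValueError(f"non-finite statistic for tree {p.label or i}")
        rows.append(
            {
                "label": p.label if p.label is not None else f"tree_{i}",
                "lambda_star": p.lambda_star,
                "psi": p.psi,
                "eta": p.eta,
                "taxon_class": p.taxon_class,
                "crown_age": p.crown_age,
                "n_tips": p.n_tips,
            }
        )
    return pd.DataFrame(rows)


def _as_coords(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points.loc[:, list(STAT_NAMES)].to_numpy(dtype=float)
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a 2-D array or DataFrame")
    return X


def _minmax(X: np.ndarray, bounds=None):
    if bounds is None:
        lo, hi = X.min(axis=0), X.max(axis=0)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    rng = np.where(hi - lo > 0, hi - lo, 1.0)
    return (X - lo) / rng, (lo, rng)


# -- archetypal analysis -------------------------------------------------


def _proj_simplex(A: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = A.shape
    U = np.sort(A, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    rho = np.count_nonzero(U - css / ind > 0, axis=1)
    theta = css[np.arange(n), rho - 1] / rho
    return np.maximum(A - theta[:, None], 0.0)


def _aa_optimize(X, B, A, n_outer=100, n_inner=15, tol=1e-12):
    """Archetypal analysis: minimize ||X - A B X||^2, A and B rows on simplexes.

    Vertices Z = B X are convex combinations of the data (Cutler–Breiman
    form), so the zero-residual optimum is unique up to permutation and the
    fitted polytope hugs the data from inside; projected-gradient steps are
    used for both blocks.
    """
    n, k = A.shape
    sx = np.linalg.svd(X, compute_uv=False)
    xnorm2 = float(sx[0] ** 2) + 1e-12
    prev = np.inf
    for _ in range(n_outer):
        Z = B @ X
        G = Z @ Z.T
        L = np.linalg.norm(G, 2) + 1e-12
        XZt = X @ Z.T
        for _ in range(n_inner):
            A = _proj_simplex(A - (A @ G - XZt) / L)
        AtA = A.T @ A
        LB = (np.linalg.norm(AtA, 2) + 1e-12) * xnorm2
        AtX = A.T @ X
        for _ in range(n_inner):
            Zb = B @ X
            grad = (AtA @ Zb - AtX) @ X.T
            B = _proj_simplex(B - grad / LB)
        w = A.sum(axis=0)
        if np.any(w < 1e-8):  # re-seed unused archetypes at worst-fit points
            resid = np.linalg.norm(X - A @ (B @ X), axis=1)
            for j in np.flatnonzero(w < 1e-8):
                B[j] = 0.0
                B[j, int(np.argmax(resid))] = 1.0
        sse = float(((X - A @ (B @ X)) ** 2).sum())
        if prev - sse < tol * max(prev, 1.0):
            prev = sse
            break
        prev = sse
    return B @ X, (A, B), prev


def _aa_init(X: np.ndarray, k: int, rng: np.random.Generator):
    """Furthest-point initial archetypes (as data-point indicators)."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    dist = np.linalg.norm(X - X[idx[0]], axis=1)
    for _ in range(k - 1):
        idx.append(int(np.argmax(dist)))
        dist = np.minimum(dist, np.linalg.norm(X - X[idx[-1]], axis=1))
    B = np.zeros((k, n))
    B[np.arange(k), idx] = 1.0
    A = np.full((n, k), 1.0 / k)
    return B, A


def _support_polish(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Snap each archetype to the extreme data point in its own direction.

    Directions run from the vertex centroid to each archetype; the support
    point of the data in that direction replaces the archetype.  This
    finishes the slow tail of the projected-gradient optimization when the
    optimum has vertices at extreme data points, and leaves the subsequent
    inflation step with less slack.
    """
    c = Z.mean(axis=0)
    out = Z.copy()
    for j in range(Z.shape[0]):
        d = Z[j] - c
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            continue
        out[j] = X[int(np.argmax((X - c) @ (d / nrm)))]
    return out


def _subspace(Z: np.ndarray):
    """Centroid and orthonormal basis of the affine hull of the vertices."""
    c = Z.mean(axis=0)
    Zc = Z - c
    _, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    scale = s.max(initial=0.0)
    m = int(np.sum(s > max(scale, 1e-30) * 1e-9))
    return c, Vt[:m]


def _inflate(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Scale vertices about their centroid until all points are enclosed.

    Enclosure is judged in the affine hull of the vertices (points are
    projected into it first); the scale is the smallest s >= 1 such that the
    gauge of every projected point w.r.t. the centered polytope is <= s.
    """
    c, basis = _subspace(Z)
    m = basis.shape[0]
    if m == 0:
        return Z
    Pz = (Z - c) @ basis.T
    Px = (X - c) @ basis.T
    if m == 1:
        lo, hi = float(Pz.min()), float(Pz.max())
        t = np.where(Px[:, 0] > 0, Px[:, 0] / max(hi, 1e-300), Px[:, 0] / min(lo, -1e-300))
        s = max(1.0, float(t.max(initial=1.0)))
    else:
        hull = ConvexHull(Pz)
        Af = hull.equations[:, :-1]
        bf = -hull.equations[:, -1]  # a.x <= b with b > 0 (centroid inside)
        t = (Px @ Af.T) / bf
        s = max(1.0, float(t.max(initial=1.0)))
    return c + (Z - c) * s


@dataclass
class PolytopeFit:
    """A fitted enclosing polytope in normalized statistic space."""

    k: int
    vertices: np.ndarray  # (k, d), min–max normalized coordinates
    vertices_raw: np.ndarray  # (k, d), original units
    explained_variance: dict  # k -> 1 - SSE/SStot (pre-inflation fit)
    contributions: np.ndarray  # (k, d), per-vertex % of each statistic
    norm_lo: np.ndarray
    norm_range: np.ndarray
    sse: float
    stat_names: tuple = STAT_NAMES


def archetype_contributions(vertices: np.ndarray) -> np.ndarray:
    """Per-vertex percentage contribution of each normalized statistic.

    A vertex's contributions are its (non-negative-clipped) normalized
    coordinates divided by their sum, times 100; each row sums to 100.
    """
    V = np.maximum(np.asarray(vertices, dtype=float), 0.0)
    s = V.sum(axis=1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("all-zero normalized vertex")
    return 100.0 * V / s


def _fit_archetypes_at_k(X, ks, rng, n_restarts=3, n_outer=250, n_inner=20):
    """Warm-started chain of AA fits for each k in ``ks`` (ascending).

    Warm-starting k+1 from the k solution plus the worst-fit point makes the
    SSE (hence explained variance) monotone in k.
    """
    results = {}
    prev = None
    for k in ks:
        cands = []
        if prev is not None:
            Zp, (Ap, Bp), _ = prev
            resid = np.linalg.norm(X - Ap @ Zp, axis=1)
            Bw = np.vstack([Bp, np.zeros((1, X.shape[0]))])
            Bw[-1, int(np.argmax(resid))] = 1.0
            Aw = np.hstack([Ap, np.zeros((X.shape[0], 1))])
            cands.append(_aa_optimize(X, Bw, Aw, n_outer=n_outer, n_inner=n_inner))
        for r in range(n_restarts):
            B0, A0 = _aa_init(X, k, rng)
            cands.append(_aa_optimize(X, B0, A0, n_outer=n_outer, n_inner=n_inner))
        best = min(cands, key=lambda c: c[2])
        results[k] = best
        prev = best
    return results


def fit_polytope(
    points,
    k_max: int = 6,
    seed: int = 0,
    k: Optional[int] = None,
    elbow_threshold: float = 0.05,
    norm_bounds=None,
    n_restarts: int = 3,
    n_outer: int = 250,
) -> PolytopeFit:
    """Fit a minimal enclosing polytope (archetypes) to points in space.

    For each candidate vertex count the archetypal decomposition is fitted
    on min–max-normalized coordinates; explained variance is 1 - SSE/SStot
    of the projection onto the polytope.  Unless ``k`` is fixed, the
    selected vertex count is the elbow: the first k whose marginal gain in
    explained variance falls below ``elbow_threshold``.  The selected
    vertices are then inflated about their centroid until every point is
    enclosed (within the vertices' affine hull).
    """
    X_raw = _as_coords(points)
    n, d = X_raw.shape
    X, (lo, rngs) = _minmax(X_raw, norm_bounds)
    ks = [k] if k is not None else list(range(2, k_max + 1))
    if n < max(ks) + 1:
        raise ValueError("need at least k_max + 1 points")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-9)
    if rank < 2 and max(ks) >= 3:
        raise ValueError("degenerate (collinear) data for requested k")
    rng = np.random.default_rng(seed)
    sstot = float(((X - X.mean(axis=0)) ** 2).sum())
    sstot = max(sstot, 1e-300)
    fits = _fit_archetypes_at_k(X, ks, rng, n_restarts=n_restarts, n_outer=n_outer)
    ev = {kk: 1.0 - fits[kk][2] / sstot for kk in ks}
    if k is not None:
        k_sel = k
    else:
        k_sel = ks[-1]
        for kk in ks[:-1]:
            if ev[kk + 1] - ev[kk] < elbow_threshold:
                k_sel = kk
                break
    Z, _, sse = fits[k_sel]
    Z = _inflate(_support_polish(Z, X), X)
    try:
        contrib = archetype_contributions(Z)
    except ValueError:  # a vertex sits exactly at the normalized origin
        contrib = np.full_like(Z, np.nan)
    return PolytopeFit(
        k=int(k_sel),
        vertices=Z,
        vertices_raw=Z * rngs + lo,
        explained_variance=ev,
        contributions=contrib,
        norm_lo=lo,
        norm_range=rngs,
        sse=sse,
    )


# -- t-ratio test --------------------------------------------------------


def _polytope_t_ratio(X: np.ndarray, k: int, rng: np.random.Generator, n_outer=25):
    """Hull-volume / fitted-polytope-volume ratio for one dataset."""
    B0, A0 = _aa_init(X, k, rng)
    Z, _, _ = _aa_optimize(X, B0, A0, n_outer=n_outer, n_inner=8)
    Z = _inflate(_support_polish(Z, X), X)
    try:
        hull_vol = ConvexHull(X).volume
        poly_vol = ConvexHull(Z).volume
    except QhullError:
        return 0.0
    if poly_vol <= 0:
        return 0.0
    return min(hull_vol / poly_vol, 1.0)


def t_ratio_test(
    points, k: int = 3, n_perm: int = 200, seed: int = 0, norm_bounds=None
) -> dict:
    """Permutation t-ratio test for a k-vertex polytope fit.

    The t-ratio is the volume of the convex hull of the points over the
    volume of the fitted enclosing k-polytope (both in normalized
    coordinates; for a flat polytope, e.g. a triangle over 3-D points, the
    cloud is first projected onto its top k-1 principal components).  The
    p-value is the fraction of datasets with axis-wise independently
    permuted coordinates whose t-ratio is at least the observed one.
    """
    if k < 3:
        raise ValueError("t-ratio test requires k >= 3")
    if n_perm < 100:
        warnings.warn("t-ratio test with n_perm < 100 is unreliable")
    X_raw = _as_coords(points)
    X, _ = _minmax(X_raw, norm_bounds)
    d = X.shape[1]
    if k <= d:  # flat polytope: work in the top (k-1)-dim principal subspace
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        X = Xc @ Vt[: k - 1].T
    rng = np.random.default_rng(seed)
    observed = _polytope_t_ratio(X, k, rng)
    hits = 0
    for _ in range(n_perm):
        Xp = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        if _polytope_t_ratio(Xp, k, rng) >= observed:
            hits += 1
    return {"t_ratio": float(observed), "p_value": hits / n_perm, "n_perm": n_perm}


# -- trade-off regressions ----------------------------------------------


@dataclass
class RegressionFit:
    """An AIC-selected regression of one statistic on another."""

    response: str
    predictor: str
    form: str  # 'constant' | 'linear' | 'logarithmic' | 'quadratic' | 'cubic'
    coefficients: dict
    r2: float
    p_value: float  # F-test of the selected form vs intercept-only
    p_adjusted: float  # Bonferroni over the candidate forms tried
    aic: float
    significant: bool


def _candidate_designs(x: np.ndarray, forms: Sequence[str]):
    designs = {}
    for form in forms:
        if form == "constant":
            designs[form] = (np.empty((x.size, 0)), [])
        elif form == "linear":
            designs[form] = (x[:, None], ["x"])
        elif form == "logarithmic":
            if np.min(x) <= 0:
                continue  # log form skipped, not errored
            designs[form] = (np.log(x)[:, None], ["ln_x"])
        elif form == "quadratic":
            designs[form] = (np.column_stack([x, x**2]), ["x", "x2"])
        elif form == "cubic":
            designs[form] = (np.column_stack([x, x**2, x**3]), ["x", "x2", "x3"])
    return designs


def fit_best_form(
    x: np.ndarray,
    y: np.ndarray,
    response: str,
    predictor: str,
    forms: Sequence[str] = ("constant", "linear", "logarithmic", "quadratic", "cubic"),
    alpha: float = 0.05,
) -> RegressionFit:
    """Fit candidate functional forms by OLS and keep the AIC-minimal one.

    The constant (intercept-only) model competes too, so "no trend" is a
    possible outcome.  Selection uses the small-sample-corrected AICc; the
    selected form's F-test p-value (vs intercept-only) is Bonferroni-
    adjusted for the number of candidate forms tried, which keeps the
    family-wise false-trend rate at the nominal level despite the
    selection step.
    """
    best = None
    n = np.asarray(x).size
    designs = _candidate_designs(np.asarray(x, float), forms)
    n_tested = sum(1 for f in designs if f != "constant")
    for form, (D, names) in designs.items():
        model = sm.OLS(y, sm.add_constant(D, has_constant="add")).fit()
        p_par = model.df_model + 2  # coefficients + intercept + error variance
        aicc = model.aic + 2.0 * p_par * (p_par + 1) / max(n - p_par - 1, 1)
        if best is None or aicc < best[3] - 1e-9:
            best = (form, model, names, aicc)
    form, model, names, _ = best
    p = float(model.f_pvalue) if form != "constant" and len(names) else 1.0
    if not np.isfinite(p):
        p = 1.0
    p_adj = min(1.0, p * max(n_tested, 1)) if form != "constant" else 1.0
    coefs = dict(zip(["intercept"] + names, np.atleast_1d(model.params).tolist()))
    return RegressionFit(
        response=response,
        predictor=predictor,
        form=form,
        coefficients=coefs,
        r2=float(model.rsquared) if form != "constant" else 0.0,
        p_value=p,
        p_adjusted=p_adj,
        aic=float(model.aic),
        significant=bool(form != "constant" and p_adj < alpha),
    )


def tradeoff_regressions(points, alpha: float = 0.05) -> list[RegressionFit]:
    """Pairwise trade-off regressions between the three spectral statistics.

    Every ordered pair is regressed with candidate forms {constant, linear,
    logarithmic, quadratic, cubic} selected by AIC.
    """
    df = points if isinstance(points, pd.DataFrame) else pd.DataFrame(
        _as_coords(points), columns=list(STAT_NAMES)
    )
    if len(df) < 10:
        raise ValueError("need at least 10 points")
    out = []
    for resp in STAT_NAMES:
        for pred in STAT_NAMES:
            if resp == pred:
                continue
            out.append(
                fit_best_form(
                    df[pred].to_numpy(), df[resp].to_numpy(), resp, pred, alpha=alpha
                )
            )
    return out


# -- volumes and regions -------------------------------------------------


def _bbox(X: np.ndarray):
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.any(hi - lo <= 0):
        raise ValueError("zero-volume bounding box (degenerate axis)")
    return lo, hi


def volume_stats(setA, setB) -> dict:
    """Bounding-box occupancy and overlap between two 3-D point sets.

    ``occupancy_pct``: volume of A's axis-aligned bounding box as a
    percentage of B's.  ``overlap_pct``: intersection volume of the two
    boxes over their union volume, as a percentage.
    """
    A, B = _as_coords(setA), _as_coords(setB)
    loA, hiA = _bbox(A)
    loB, hiB = _bbox(B)
    volA = float(np.prod(hiA - loA))
    volB = float(np.prod(hiB - loB))
    inter = np.maximum(np.minimum(hiA, hiB) - np.maximum(loA, loB), 0.0)
    vol_inter = float(np.prod(inter))
    union = volA + volB - vol_inter
    return {
        "occupancy_pct": 100.0 * volA / volB,
        "overlap_pct": 100.0 * vol_inter / union,
    }


@dataclass
class TypeHulls:
    """Per-cluster convex-hull regions of phylogenetic space."""

    hulls: dict  # cluster id -> Delaunay triangulation of member points
    centroids: dict  # cluster id -> centroid
    skipped: list  # cluster ids too small / degenerate for a hull

    def assign(self, points) -> list:
        """Cluster id per query point, or None when outside all hulls.

        Points inside several hulls go to the nearest cluster centroid.
        """
        X = _as_coords(points)
        out = []
        for x in X:
            inside = [
                cid
                for cid, tri in self.hulls.items()
                if tri.find_simplex(x[None, :])[0] >= 0
            ]
            if not inside:
                out.append(None)
            elif len(inside) == 1:
                out.append(inside[0])
            else:
                dists = {c: np.linalg.norm(x - self.centroids[c]) for c in inside}
                out.append(min(dists, key=dists.get))
        return out


def type_hulls(points, cluster_ids) -> TypeHulls:
    """Convex hull per cluster; degenerate clusters are flagged and skipped."""
    X = _as_coords(points)
    cids = np.asarray(cluster_ids)
    hulls, centroids, skipped = {}, {}, []
    for cid in np.unique(cids):
        P = X[cids == cid]
        if P.shape[0] < X.shape[1] + 1:
            skipped.append(cid)
            continue
        try:
            hulls[int(cid)] = Delaunay(P)
            centroids[int(cid)] = P.mean(axis=0)
        except QhullError:
            skipped.append(cid)
    return TypeHulls(hulls=hulls, centroids=centroids, skipped=skipped)


# -- rarefaction ---------------------------------------------------------


def rarefaction_saturation(
    points,
    sample_sizes: Sequence[int],
    replicates: int = 50,
    seed: int = 0,
) -> dict:
    """Saturation of archetype coordinates under bootstrapped subsampling.

    For each sample size, ``replicates`` bootstrap samples are drawn and a
    3-vertex polytope fitted (normalization fixed to the full data so
    coordinates are comparable); fitted vertices are matched to the
    full-data archetypes by nearest assignment and each vertex's maximum
    normalized coordinate recorded.  A logarithmic curve (max coordinate ~
    a + b ln n) is fitted per vertex.
    """
    X_raw = _as_coords(points)
    n = X_raw.shape[0]
    if any(s < 4 for s in sample_sizes):
        raise ValueError("sample sizes must be at least k + 1 = 4")
    if any(s > n for s in sample_sizes):
        raise ValueError("sample sizes cannot exceed the number of points")
    bounds = (X_raw.min(axis=0), X_raw.max(axis=0))
    ref = fit_polytope(X_raw, k=3, seed=seed, norm_bounds=bounds)
    rng = np.random.default_rng(seed)
    from scipy.optimize import linear_sum_assignment

    rows = []
    for size in sample_sizes:
        for rep in range(replicates):
            idx = rng.integers(0, n, size=size)
            try:
                fit = fit_polytope(
                    X_raw[idx],
                    k=3,
                    seed=int(rng.integers(2**31)),
                    norm_bounds=bounds,
                    n_restarts=1,
                )
            except ValueError:
                continue  # degenerate bootstrap sample
            cost = np.linalg.norm(
                ref.vertices[:, None, :] - fit.vertices[None, :, :], axis=2
            )
            ri, ci = linear_sum_assignment(cost)
            for v_ref, v_fit in zip(ri, ci):
                rows.append(
                    {
                        "size": size,
                        "replicate": rep,
                        "vertex": int(v_ref),
                        "max_coordinate": float(fit.vertices[v_fit].max()),
                    }
                )
    detail = pd.DataFrame(rows)
    summary = (
        detail.groupby(["size", "vertex"])["max_coordinate"]
        .agg(["mean", "std"])
        .reset_index()
    )
    curves = {}
    for v in sorted(detail["vertex"].unique()):
        sub = detail[detail["vertex"] == v]
        curves[int(v)] = fit_best_form(
            sub["size"].to_numpy(float),
            sub["max_coordinate"].to_numpy(),
            response=f"max_coordinate_vertex_{v}",
            predictor="sample_size",
            forms=("constant", "logarithmic"),
        )
    return {"summary": summary, "detail": detail, "curves": curves, "reference": ref}
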