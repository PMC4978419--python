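"""Average trajectories through phylogenetic space over crown age.

Trees are binned by crown age with Fisher–Jenks natural breaks (exact
dynamic program minimizing within-class sum of squared deviations; in auto
mode the smallest class count whose goodness-of-variance fit reaches 0.9,
capped at 7, is used).  Each bin contributes its arithmetic-mean point in
(lambda_star, psi, eta) space, is assigned to the diversification-type
region containing that mean (nearest type centroid when it falls in no
hull), and is represented by a median tree — the member closest to the bin
mean in min–max-normalized coordinates.  Per-statistic age trends are
fitted with AIC-selected polynomials up to cubic; "no significant trend" is
a possible outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .treespace import STAT_NAMES, RegressionFit, TypeHulls, _as_coords, fit_best_form

__all__ = [
    "AgeBins",
    "jenks_breaks",
    "assign_bins",
    "trajectory_through_space",
    "trajectory_regressions",
]


def _class_cost(values: np.ndarray) -> np.ndarray:
    """cost[i, j] = SSD of sorted values[i..j] via prefix sums."""
    n = values.size
    cs = np.concatenate([[0.0], np.cumsum(values)])
    cs2 = np.concatenate([[0.0], np.cumsum(values**2)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = j - i + 1
    s = cs[j + 1] - cs[i]
    s2 = cs2[j + 1] - cs2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = s2 - s * s / cnt
    return np.where(j >= i, np.maximum(cost, 0.0), np.inf)


def _jenks_dp(sorted_values: np.ndarray, k: int):
    """Optimal k-class partition of sorted values (Fisher–Jenks DP)."""
    n = sorted_values.size
    cost = _class_cost(sorted_values)
    best = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    best[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            cand = best[c - 1, c - 1 : j] + cost[c - 1 : j, j - 1]
            m = int(np.argmin(cand))
            best[c, j] = cand[m]
            split[c, j] = m + c - 1
    # recover class boundaries (start index of each class)
    starts = []
    j = n
    for c in range(k, 0, -1):
        s = split[c, j]
        starts.append(s)
        j = s
    starts.reverse()
    return starts, float(best[k, n])


def jenks_breaks(
    values: Sequence[float],
    k: Optional[int] = None,
    gvf_target: float = 0.9,
    max_k: int = 7,
) -> np.ndarray:
    """Fisher–Jenks natural breaks of a 1-D sample.

    Returns ``k + 1`` ascending breakpoints (first = min, last = max); a
    value v belongs to class c when ``breaks[c] <= v <= breaks[c+1]`` (upper
    edges exclusive except the last).  With ``k=None`` the smallest k whose
    goodness-of-variance fit reaches ``gvf_target`` (capped at ``max_k``) is
    chosen.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n_distinct = np.unique(v).size
    if k is not None:
        if k > n_distinct:
            raise ValueError("k exceeds the number of distinct values")
        ks = [k]
    else:
        ks = list(range(1, min(max_k, n_distinct) + 1))
    ssd_total = float(((v - v.mean()) ** 2).sum())
    chosen = None
    for kk in ks:
        starts, ssd = _jenks_dp(v, kk)
        gvf = 1.0 - ssd / ssd_total if ssd_total > 0 else 1.0
        chosen = (kk, starts, ssd)
        if k is None and gvf >= gvf_target:
            break
    kk, starts, _ = chosen
    edges = [v[0]]
    for s in starts[1:]:
        edges.append((v[s - 1] + v[s]) / 2.0)  # midpoint between classes
    edges.append(v[-1])
    return np.asarray(edges)


def assign_bins(values: Sequence[float], breaks: np.ndarray) -> np.ndarray:
    """Class index per value for breakpoints from `jenks_breaks`."""
    v = np.asarray(values, dtype=float)
    idx = np.searchsorted(breaks[1:-1], v, side="right")
    return idx.astype(int)


@dataclass
class AgeBins:
    """Crown-age bins with per-bin positions in phylogenetic space."""

    breaks: np.ndarray
    assignments: np.ndarray  # bin index per tree
    table: pd.DataFrame  # one row per bin: means, type, median tree
    gvf: float


def trajectory_through_space(
    points: pd.DataFrame,
    ages: Sequence[float],
    hulls: Optional[TypeHulls] = None,
    k: Optional[int] = None,
) -> AgeBins:
    """Mean path through (lambda_star, psi, eta) space across age bins.

    ``points`` must carry label + statistic columns aligned with ``ages``.
    Bins are ordered by age; each bin's mean point is assigned to the type
    hull containing it (or the nearest type centroid) and to a median tree,
    the member minimizing Euclidean distance to the bin mean in min–max-
    normalized coordinates (ties broken by label order).
    """
    ages = np.asarray(ages, dtype=float)
    X = _as_coords(points)
    labels = list(points["label"]) if "label" in points else [str(i) for i in range(len(ages))]
    breaks = jenks_breaks(ages, k=k)
    assign = assign_bins(ages, breaks)
    lo, hi = X.min(axis=0), X.max(axis=0)
    rngs = np.where(hi - lo > 0, hi - lo, 1.0)
    Xn = (X - lo) / rngs
    ssd_total = float(((ages - ages.mean()) ** 2).sum())
    ssd_within = sum(
        float(((ages[assign == b] - ages[assign == b].mean()) ** 2).sum())
        for b in np.unique(assign)
    )
    gvf = 1.0 - ssd_within / ssd_total if ssd_total > 0 else 1.0
    rows = []
    for b in sorted(np.unique(assign)):
        members = np.flatnonzero(assign == b)
        if members.size == 0:
            raise ValueError(f"empty age bin {b}")
        mean_pt = X[members].mean(axis=0)
        mean_n = (mean_pt - lo) / rngs
        dists = np.linalg.norm(Xn[members] - mean_n, axis=1)
        order = np.lexsort(([labels[i] for i in members], dists))
        median_label = labels[members[order[0]]]
        type_id = None
        if hulls is not None and hulls.hulls:
            inside = hulls.assign(mean_pt[None, :])[0]
            if inside is None:
                cents = {c: np.linalg.norm(mean_pt - v) for c, v in hulls.centroids.items()}
                inside = min(cents, key=cents.get) if cents else None
            type_id = inside
        rows.append(
            {
                "bin": int(b),
                "age_lo": float(breaks[b]),
                "age_hi": float(breaks[b + 1]),
                "mean_age": float(ages[members].mean()),
                "n": int(members.size),
                "lambda_star": float(mean_pt[0]),
                "psi": float(mean_pt[1]),
                "eta": float(mean_pt[2]),
                "type": type_id,
                "median_tree": median_label,
            }
        )
    return AgeBins(
        breaks=breaks,
        assignments=assign,
        table=pd.DataFrame(rows).sort_values("mean_age").reset_index(drop=True),
        gvf=gvf,
    )


def trajectory_regressions(
    points: pd.DataFrame, ages: Sequence[float], alpha: float = 0.05
) -> list[RegressionFit]:
    """Per-statistic trend of (lambda_star, psi, eta) against crown age.

    Polynomials up to cubic compete by AIC with an intercept-only model, so
    a statistic may report no significant trend.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 10:
        raise ValueError("need at least 10 trees")
    X = _as_coords(points)
    out = []
    for j, name in enumerate(STAT_NAMES):
        y = X[:, j]
        if np.allclose(y, y[0]):
            out.append(
                RegressionFit(
                    response=name,
                    predictor="crown_age",
                    form="constant",
                    coefficients={"intercept": float(y[0])},
                    r2=0.0,
                    p_value=1.0,
                    p_adjusted=1.0,
                    aic=float("nan"),
                    significant=False,
                )
            )
            continue
        out.append(
            fit_best_form(
                ages,
                y,
                response=name,
                predictor="crown_age",
                forms=("constant", "linear", "quadratic", "cubic"),
                alpha=alpha,
            )
        )
    return out
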