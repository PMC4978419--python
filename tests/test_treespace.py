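"""Archetype fitting, trade-offs, volumes, type regions and rarefaction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment, linprog

from phylospace import (
    archetype_contributions,
    fit_polytope,
    map_points,
    rarefaction_saturation,
    t_ratio_test,
    tradeoff_regressions,
    type_hulls,
    volume_stats,
)
from phylospace.treespace import _inflate, _subspace, fit_best_form


def triangle_points(n, seed, tri=None):
    tri = np.array([[0.0, 0.0], [4.0, 0.5], [1.0, 3.0]]) if tri is None else tri
    return np.random.default_rng(seed).dirichlet([1, 1, 1], n) @ tri, tri


class TestMapPoints:
    def test_coordinates_verbatim(self, small_planted_profiles):
        profiles, _ = small_planted_profiles
        df = map_points(profiles)
        assert len(df) == len(profiles)
        assert df.iloc[0]["lambda_star"] == profiles[0].lambda_star
        assert df.iloc[0]["psi"] == profiles[0].psi
        assert df.iloc[0]["eta"] == profiles[0].eta

    def test_non_finite_statistic_names_tree(self, small_planted_profiles):
        profiles, _ = small_planted_profiles
        bad = profiles[0].__class__(**{**profiles[0].__dict__})
        bad.psi = float("nan")
        bad.label = "broken_tree"
        with pytest.raises(ValueError, match="broken_tree"):
            map_points([bad])


class TestFitPolytope:
    def test_atoms_at_vertices_recovered_exactly(self):
        V = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.5], [0.2, 1.0, 0.1]])
        X = V[np.random.default_rng(0).integers(0, 3, 300)]
        fit = fit_polytope(X, k_max=6, seed=0)
        assert fit.k == 3
        assert fit.explained_variance[3] == pytest.approx(1.0, abs=1e-9)
        cost = np.linalg.norm(V[:, None] - fit.vertices_raw[None], axis=2)
        ri, ci = linear_sum_assignment(cost)
        assert cost[ri, ci].max() < 1e-6

    def test_planted_triangle_recovery(self):
        X, tri = triangle_points(500, seed=1)
        fit = fit_polytope(X, k_max=6, seed=1)
        assert fit.k == 3
        lo, hi = X.min(axis=0), X.max(axis=0)
        tn = (tri - lo) / (hi - lo)
        cost = np.linalg.norm(tn[:, None] - fit.vertices[None], axis=2)
        ri, ci = linear_sum_assignment(cost)
        assert cost[ri, ci].max() <= 0.05 * np.sqrt(2)  # 5% of bbox diagonal

    def test_square_elbows_at_four(self):
        X = np.random.default_rng(2).random((500, 2))
        fit = fit_polytope(X, k_max=6, seed=2)
        assert fit.k == 4

    def test_explained_variance_monotone(self, small_planted_profiles):
        profiles, _ = small_planted_profiles
        fit = fit_polytope(map_points(profiles), k_max=6, seed=3)
        ev = [fit.explained_variance[k] for k in sorted(fit.explained_variance)]
        assert all(b >= a - 1e-9 for a, b in zip(ev, ev[1:]))

    def test_all_points_enclosed_within_tolerance(self):
        X, _ = triangle_points(300, seed=5)
        fit = fit_polytope(X, k_max=4, seed=5)
        c, basis = _subspace(fit.vertices)
        lo, hi = X.min(axis=0), X.max(axis=0)
        Xn = (X - lo) / (hi - lo)
        Pz = (fit.vertices - c) @ basis.T
        Px = (Xn - c) @ basis.T
        from scipy.spatial import ConvexHull

        hull = ConvexHull(Pz)
        viol = (Px @ hull.equations[:, :-1].T + hull.equations[:, -1]).max()
        assert viol <= 1e-8

    def test_collinear_data_errors(self):
        x = np.linspace(0, 1, 50)
        X = np.column_stack([x, 2 * x, 3 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_polytope(X, k_max=4, seed=0)


class TestTRatio:
    def test_triangle_fill_significant(self):
        X, _ = triangle_points(400, seed=7)
        res = t_ratio_test(X, k=3, n_perm=100, seed=0)
        assert res["t_ratio"] > 0.7
        assert res["p_value"] < 0.01

    def test_p_value_in_unit_interval(self):
        X = np.random.default_rng(8).normal(size=(150, 2))
        res = t_ratio_test(X, k=3, n_perm=100, seed=1)
        assert 0.0 <= res["p_value"] <= 1.0

    def test_k_below_three_errors(self):
        X = np.random.default_rng(9).normal(size=(50, 2))
        with pytest.raises(ValueError):
            t_ratio_test(X, k=2)


class TestContributions:
    def test_axis_vertex(self):
        out = archetype_contributions(np.array([[0.0, 1.0, 0.0]]))
        assert np.allclose(out, [[0.0, 100.0, 0.0]])

    def test_even_split(self):
        out = archetype_contributions(np.array([[0.5, 0.5, 0.0]]))
        assert np.allclose(out, [[50.0, 50.0, 0.0]])

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(0)
        V = rng.random((5, 3))
        assert np.allclose(archetype_contributions(V).sum(axis=1), 100.0, atol=0.1)

    def test_axis_permutation_equivariance(self):
        V = np.random.default_rng(1).random((4, 3))
        perm = [2, 0, 1]
        assert np.allclose(
            archetype_contributions(V[:, perm]),
            archetype_contributions(V)[:, perm],
        )

    def test_all_zero_vertex_errors(self):
        with pytest.raises(ValueError):
            archetype_contributions(np.array([[0.0, 0.0, 0.0]]))


class TestTradeoffRegressions:
    def test_linear_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 5, 200)
        y = 2.0 * x + rng.normal(0, 0.3, 200)
        fit = fit_best_form(x, y, "y", "x")
        assert fit.form == "linear"
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=0.1)
        assert fit.significant

    def test_logarithmic_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.2, 5, 300)
        y = -np.log(x) + rng.normal(0, 0.05, 300)
        fit = fit_best_form(x, y, "y", "x")
        assert fit.form == "logarithmic"

    def test_log_form_skipped_for_nonpositive_predictor(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-1, 1, 100)
        y = x + rng.normal(0, 0.1, 100)
        fit = fit_best_form(x, y, "y", "x")  # must not raise
        assert fit.form != "logarithmic"

    def test_pure_noise_rarely_significant(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            x = rng.uniform(0.5, 5, 40)
            y = rng.normal(0, 1, 40)
            if fit_best_form(x, y, "y", "x").significant:
                hits += 1
        assert hits <= 10  # type-I behavior near the nominal level

    def test_runs_on_all_ordered_pairs(self, small_planted_profiles):
        profiles, _ = small_planted_profiles
        fits = tradeoff_regressions(map_points(profiles))
        assert len(fits) == 6
        assert {(f.response, f.predictor) for f in fits} == {
            (a, b)
            for a in ("lambda_star", "psi", "eta")
            for b in ("lambda_star", "psi", "eta")
            if a != b
        }


class TestVolumeStats:
    def test_nested_cubes_occupancy(self):
        A = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).reshape(3, -1).T
        B = 2.0 * A
        out = volume_stats(A, B)
        assert out["occupancy_pct"] == pytest.approx(12.5)

    def test_identity(self):
        A = np.random.default_rng(0).random((20, 3))
        out = volume_stats(A, A)
        assert out["occupancy_pct"] == pytest.approx(100.0)
        assert out["overlap_pct"] == pytest.approx(100.0)

    def test_disjoint_boxes_no_overlap(self):
        A = np.random.default_rng(1).random((20, 3))
        out = volume_stats(A, A + 10.0)
        assert out["overlap_pct"] == 0.0

    def test_scale_consistency(self):
        rng = np.random.default_rng(2)
        A, B = rng.random((30, 3)), rng.random((30, 3)) + 0.3
        o1 = volume_stats(A, B)
        o2 = volume_stats(5.0 * A, 5.0 * B)
        assert o1["occupancy_pct"] == pytest.approx(o2["occupancy_pct"])
        assert o1["overlap_pct"] == pytest.approx(o2["overlap_pct"])

    def test_degenerate_axis_errors(self):
        A = np.zeros((10, 3))
        with pytest.raises(ValueError):
            volume_stats(A, np.random.default_rng(0).random((10, 3)))


def lp_inside_hull(x, P):
    """Linear-programming membership oracle: x in conv(P)?"""
    n = P.shape[0]
    res = linprog(
        c=np.zeros(n),
        A_eq=np.vstack([P.T, np.ones(n)]),
        b_eq=np.concatenate([x, [1.0]]),
        bounds=[(0, None)] * n,
        method="highs",
    )
    return res.status == 0


class TestTypeHulls:
    def test_cube_membership(self):
        corners = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).reshape(3, -1).T
        hulls = type_hulls(corners.astype(float), np.zeros(8, dtype=int))
        assert hulls.assign([[0.5, 0.5, 0.5]]) == [0]
        assert hulls.assign([[5.0, 5.0, 5.0]]) == [None]

    def test_membership_agrees_with_lp_oracle(self):
        rng = np.random.default_rng(3)
        P = rng.random((30, 3))
        hulls = type_hulls(P, np.zeros(30, dtype=int))
        queries = rng.uniform(-0.2, 1.2, size=(100, 3))
        ours = [a == 0 for a in hulls.assign(queries)]
        oracle = [lp_inside_hull(q, P) for q in queries]
        assert ours == oracle

    def test_small_cluster_skipped(self):
        P = np.random.default_rng(4).random((10, 3))
        ids = np.array([0] * 7 + [1] * 3)  # cluster 1 too small for a 3-D hull
        hulls = type_hulls(P, ids)
        assert 1 in hulls.skipped and 0 in hulls.hulls

    def test_overlapping_hulls_assign_nearest_centroid(self):
        rng = np.random.default_rng(5)
        A = rng.random((150, 3))  # unit cube
        B = rng.random((150, 3)) + 0.5  # shifted, overlapping cube
        X = np.vstack([A, B])
        ids = np.array([0] * 150 + [1] * 150)
        hulls = type_hulls(X, ids)
        # inside A only; below B's support
        assert hulls.assign([[0.25, 0.25, 0.25]]) == [0]
        # in the overlap: goes to the nearer centroid (A's, at ~0.5 each axis)
        assert hulls.assign([[0.6, 0.6, 0.6]]) == [0]


class TestRarefaction:
    def test_saturated_triangle_is_flat(self):
        V = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.5], [0.2, 1.0, 0.1]])
        X = V[np.random.default_rng(0).integers(0, 3, 200)]
        out = rarefaction_saturation(X, [30, 60, 120], replicates=8, seed=0)
        by_size = out["summary"].groupby("size")["mean"].mean()
        assert by_size.max() - by_size.min() < 0.02  # already saturated

    def test_deterministic_given_seed(self):
        X, _ = triangle_points(150, seed=6)
        X3 = np.column_stack([X, X[:, 0] * 0.5 + 0.1 * X[:, 1]])
        o1 = rarefaction_saturation(X3, [30, 80], replicates=5, seed=9)
        o2 = rarefaction_saturation(X3, [30, 80], replicates=5, seed=9)
        pd.testing.assert_frame_equal(o1["summary"], o2["summary"])

    def test_sample_size_validation(self):
        X, _ = triangle_points(50, seed=7)
        with pytest.raises(ValueError):
            rarefaction_saturation(X, [3], replicates=2, seed=0)
        with pytest.raises(ValueError):
            rarefaction_saturation(X, [500], replicates=2, seed=0)
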