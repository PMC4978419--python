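"""Jensen–Shannon distances, clustering, stability and composition nulls."""

import numpy as np
import pytest

from phylospace import (
    ProfileDistanceMatrix,
    class_composition_null,
    cluster_stability,
    distance_matrix,
    hierarchical_cluster_bootstrap,
    js_distance,
    kmedoids_select_k,
)
from phylospace.profile_compare import _jsd, _pam
from phylospace.spectral import SpectralProfile

LN2 = np.log(2.0)


def make_profile(loc, label, n=25, spread=0.3, bandwidth=0.1, seed=0):
    """A synthetic profile: Gaussian bump of ln-eigenvalues around ``loc``."""
    rng = np.random.default_rng(seed)
    ln_ev = rng.normal(loc, spread, size=n)
    grid = np.linspace(ln_ev.min() - 3 * bandwidth, ln_ev.max() + 3 * bandwidth, 256)
    p = SpectralProfile(
        eigenvalues=np.exp(np.sort(ln_ev))[::-1],
        ln_eigenvalues=ln_ev,
        grid=grid,
        density=np.empty(256),
        bandwidth=bandwidth,
        lambda_star=float(ln_ev.max()),
        psi=0.0,
        eta=1.0,
        modality=1,
        label=label,
    )
    p.density = p.density_at(grid)
    return p


def entropy_nats(p):
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


class TestJsDistance:
    def test_identity(self):
        p = make_profile(0.0, "p")
        assert js_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        p, q = make_profile(0.0, "p"), make_profile(1.0, "q", seed=1)
        assert js_distance(p, q) == pytest.approx(js_distance(q, p), abs=1e-12)

    def test_disjoint_supports_reach_ln2(self):
        p, q = make_profile(0.0, "p"), make_profile(100.0, "q", seed=1)
        assert js_distance(p, q) == pytest.approx(LN2, abs=1e-6)

    def test_two_point_entropy_arithmetic_oracle(self):
        # JSD = H(m) - (H(p) + H(q))/2 evaluated by hand on discrete rows
        P = np.array([[0.5, 0.5], [0.9, 0.1]])
        m = P.mean(axis=0)
        expected = entropy_nats(m) - 0.5 * (entropy_nats(P[0]) + entropy_nats(P[1]))
        assert _jsd(P)[0, 1] == pytest.approx(expected, abs=1e-12)


class TestDistanceMatrix:
    def test_identical_profiles_zero_matrix(self):
        p = make_profile(0.0, "a")
        q = make_profile(0.0, "b")
        q.ln_eigenvalues = p.ln_eigenvalues.copy()
        dm = distance_matrix([p, q])
        assert np.allclose(dm.distances, 0.0, atol=1e-12)

    def test_duplicate_labels_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix([make_profile(0, "x"), make_profile(1, "x", seed=1)])

    def test_matches_looped_js_distance(self):
        profiles = [make_profile(i * 0.5, f"p{i}", seed=i) for i in range(6)]
        dm = distance_matrix(profiles)
        for i in range(6):
            for j in range(i + 1, 6):
                # shared grid differs pairwise vs globally; allow loose match
                assert dm.distances[i, j] == pytest.approx(
                    js_distance(profiles[i], profiles[j]), abs=5e-3
                )

    def test_permutation_consistency(self):
        profiles = [make_profile(i * 0.7, f"p{i}", seed=i) for i in range(5)]
        dm = distance_matrix(profiles)
        perm = [3, 1, 4, 0, 2]
        dm2 = distance_matrix([profiles[i] for i in perm])
        assert np.allclose(
            dm2.distances, dm.distances[np.ix_(perm, perm)], atol=1e-12
        )

    def test_sqrt_jsd_triangle_inequality(self):
        rng = np.random.default_rng(4)
        profiles = [
            make_profile(rng.uniform(0, 3), f"p{i}", seed=i, spread=rng.uniform(0.1, 1))
            for i in range(12)
        ]
        R = np.sqrt(distance_matrix(profiles).distances)
        for _ in range(200):
            i, j, k = rng.choice(12, size=3, replace=False)
            assert R[i, j] <= R[i, k] + R[k, j] + 1e-9


class TestHierarchicalBootstrap:
    def test_planted_groups_get_high_support(self):
        a = [make_profile(0.0, f"a{i}", seed=i, spread=0.2) for i in range(5)]
        b = [make_profile(5.0, f"b{i}", seed=10 + i, spread=0.2) for i in range(5)]
        res = hierarchical_cluster_bootstrap(a + b, B=100, seed=0)
        support = res.clade_support
        set_a = frozenset(p.label for p in a)
        set_b = frozenset(p.label for p in b)
        assert support[set_a] >= 0.95
        assert support[set_b] >= 0.95

    def test_deterministic_given_seed(self):
        profiles = [make_profile(i * 0.3, f"p{i}", seed=i) for i in range(6)]
        r1 = hierarchical_cluster_bootstrap(profiles, B=50, seed=3)
        r2 = hierarchical_cluster_bootstrap(profiles, B=50, seed=3)
        assert r1.clade_support == r2.clade_support

    def test_tiny_b_errors(self):
        profiles = [make_profile(i, f"p{i}", seed=i) for i in range(4)]
        with pytest.raises(ValueError):
            hierarchical_cluster_bootstrap(profiles, B=1)


class TestKmedoids:
    def test_two_blobs_silhouette_oracle(self):
        # distance structure of points {0, 0.1} and {10, 10.1} on a line
        x = np.array([0.0, 0.1, 10.0, 10.1])
        D = np.abs(x[:, None] - x[None, :])
        dm = ProfileDistanceMatrix([f"p{i}" for i in range(4)], D)
        res = kmedoids_select_k(dm, range(2, 4), seed=0)
        assert res.k == 2
        assert set(map(tuple, [res.assignments[:2], res.assignments[2:]])) == {
            (res.assignments[0],) * 2,
            (res.assignments[2],) * 2,
        }
        # silhouette by hand: a = 0.1, b = mean(10, 10.1) = 10.05 for point 0
        s0 = (10.05 - 0.1) / 10.05
        assert res.silhouettes[0] == pytest.approx(s0, abs=1e-9)
        assert res.mean_silhouette > 0.95 and res.supported

    def test_identical_points_report_no_supported_k(self):
        D = np.zeros((6, 6))
        dm = ProfileDistanceMatrix([f"p{i}" for i in range(6)], D)
        res = kmedoids_select_k(dm, range(2, 5), seed=0)
        assert not res.supported
        assert res.k == 1

    def test_pam_objective_beats_random_medoids(self):
        rng = np.random.default_rng(8)
        X = np.concatenate([rng.normal(0, 1, 20), rng.normal(8, 1, 20)])
        D = np.abs(X[:, None] - X[None, :])
        medoids, assign = _pam(D, 2, rng)
        cost = D[np.arange(40), medoids[assign]].sum()
        for _ in range(50):
            m = rng.choice(40, 2, replace=False)
            rand_cost = D[:, m].min(axis=1).sum()
            assert cost <= rand_cost + 1e-9

    def test_too_few_points_error(self):
        dm = ProfileDistanceMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            kmedoids_select_k(dm, range(2, 3))


class TestClusterStability:
    def _five_group_profiles(self, jitter_seed=None):
        # wide bandwidth smooths out sampling noise so groups are compact
        profiles = []
        for g in range(5):
            for i in range(4):
                p = make_profile(
                    g * 4.0, f"g{g}_{i}", seed=100 * g + i, spread=0.2, bandwidth=0.6
                )
                profiles.append(p)
        return profiles

    def test_identical_corpora_fully_stable(self):
        profiles = self._five_group_profiles()
        ref = kmedoids_select_k(distance_matrix(profiles), range(2, 8), seed=0)
        out = cluster_stability([profiles, profiles], ref, k_range=range(2, 8))
        assert out == {
            "pct_same_k": 100.0,
            "pct_identical_assignment": 100.0,
            "max_pct_mismatched": 0.0,
        }

    def test_single_swap_detected(self):
        profiles = self._five_group_profiles()
        ref = kmedoids_select_k(distance_matrix(profiles), range(2, 8), seed=0)
        assert ref.k == 5
        # move one tree's profile onto another cluster's center
        swapped = [
            make_profile(4.0, "g0_0", seed=999, spread=0.2, bandwidth=0.6)
        ] + profiles[1:]
        out = cluster_stability([swapped], ref, k_range=range(2, 8))
        assert out["max_pct_mismatched"] == pytest.approx(100.0 / 20.0)

    def test_label_mismatch_errors(self):
        profiles = self._five_group_profiles()
        ref = kmedoids_select_k(distance_matrix(profiles), range(2, 8), seed=0)
        with pytest.raises(ValueError):
            cluster_stability([profiles[:-1]], ref)


class TestClassCompositionNull:
    def _assignments(self):
        # two clusters of 10 each -> cluster probability 0.5 apiece
        assignments = {}
        for i in range(10):
            assignments[f"t{i}"] = 0
        for i in range(10, 20):
            assignments[f"t{i}"] = 1
        return assignments

    def test_three_of_three_not_significant(self):
        assignments = self._assignments()
        classes = {l: ("X" if l in ("t0", "t1", "t2") else "Y") for l in assignments}
        df = class_composition_null(assignments, classes, n_iter=20000, seed=0)
        row = df[(df["class"] == "X") & (df["cluster"] == 0)].iloc[0]
        # binomial oracle: P(all 3 in cluster 0) = 0.5^3 = 0.125
        assert row["p_upper"] == pytest.approx(0.125, abs=0.01)
        assert not row["significant"]

    def test_ten_of_ten_significant(self):
        assignments = self._assignments()
        classes = {l: ("X" if int(l[1:]) < 10 else "Y") for l in assignments}
        df = class_composition_null(assignments, classes, n_iter=20000, seed=0)
        row = df[(df["class"] == "X") & (df["cluster"] == 0)].iloc[0]
        # binomial oracle: 0.5^10 ~ 0.001
        assert row["p_upper"] == pytest.approx(0.5**10, abs=0.005)
        assert row["significant"]

    def test_null_conforming_composition_not_significant(self):
        assignments = self._assignments()
        # class composition mirrors the global 50/50 split
        classes = {l: ("X" if int(l[1:]) % 2 == 0 else "Y") for l in assignments}
        df = class_composition_null(assignments, classes, n_iter=500, seed=1)
        assert not df["significant"].any()

    def test_missing_class_label_errors(self):
        with pytest.raises(ValueError):
            class_composition_null({"a": 0, "b": 1}, {"a": "X"}, n_iter=100)
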