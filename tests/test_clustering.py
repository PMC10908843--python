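import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import max_ncc_by_scan, silhouette_by_formula
from sclshape.clustering import (
    _kshape_once,
    consensus,
    ClusterResult,
    compare_k,
    kshape,
    sbd,
    sbd_matrix,
    silhouette,
    zscore_rows,
)
from sclshape.errors import (
    DegenerateSeriesError,
    InvalidKError,
    InvalidParameterError,
    UndefinedScoreError,
)
from sclshape.simulate import simulate_shape_groups


class TestSbd:
    def test_self_distance_zero(self, rng):
        x = rng.normal(size=50)
        d, aligned, lag = sbd(x, x)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert lag == 0
        np.testing.assert_allclose(aligned, x)

    def test_range_and_symmetry(self, rng):
        for _ in range(50):
            x, y = rng.normal(size=32), rng.normal(size=32)
            d_xy, _, _ = sbd(x, y)
            d_yx, _, _ = sbd(y, x)
            assert 0.0 <= d_xy <= 2.0
            assert d_xy == pytest.approx(d_yx, abs=1e-9)

    def test_recovers_shift_of_delayed_sinusoid(self):
        x = np.sin(np.linspace(0, 4 * np.pi, 64, endpoint=False))
        y = np.zeros_like(x)
        y[5:] = x[:-5]
        d, aligned, lag = sbd(x, y)
        assert d < 0.05
        assert lag == 5
        # the aligned copy correlates with x at least as well as raw y
        assert np.dot(aligned, x) >= np.dot(y, x)

    def test_matches_brute_force_lag_scan(self, rng):
        for _ in range(50):
            x, y = rng.normal(size=24), rng.normal(size=24)
            d, _, lag = sbd(x, y)
            best, best_lag = max_ncc_by_scan(x, y)
            assert d == pytest.approx(1.0 - best, abs=1e-9)
            assert lag == best_lag

    def test_opposite_sign_pair_has_negative_lag0_correlation(self, rng):
        # The maximizing shift usually finds some positive correlation, so
        # the distance stays below 2 even for y = -x; at lag 0 the
        # normalized correlation is exactly -1.
        x = rng.normal(size=40)
        x -= x.mean()
        d, _, _ = sbd(x, -x)
        assert 0.0 < d <= 2.0
        assert np.dot(x, -x) / (np.linalg.norm(x) ** 2) == pytest.approx(-1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            sbd(np.zeros(10), np.ones(10))


class TestKshape:
    def test_recovers_two_template_groups(self):
        X, truth = simulate_shape_groups(n_per_group=10, length=120,
                                         noise_sd=0.05, seed=4)
        labels, _, _, _, degenerate = kshape(X, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert not degenerate

    def test_deterministic_for_fixed_seed(self):
        X, _ = simulate_shape_groups(n_per_group=8, length=80, noise_sd=0.3, seed=2)
        a = kshape(X, k=3, seed=7)[0]
        b = kshape(X, k=3, seed=7)[0]
        np.testing.assert_array_equal(a, b)

    def test_objective_non_increasing_over_iterations(self):
        X, _ = simulate_shape_groups(n_per_group=10, length=100, noise_sd=0.4, seed=3)
        Z = zscore_rows(X)
        _, _, _, _, history = _kshape_once(Z, 2, np.random.default_rng(0), 100)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_identical_series_flagged_degenerate(self):
        x = np.sin(np.linspace(0, 6, 40))
        X = np.tile(x, (6, 1))
        labels, _, obj, _, degenerate = kshape(X, k=2, seed=0)
        assert degenerate
        assert obj == pytest.approx(0.0, abs=1e-9)

    def test_invalid_k_rejected(self, rng):
        X = rng.normal(size=(5, 20))
        with pytest.raises(InvalidKError):
            kshape(X, k=1)
        with pytest.raises(InvalidKError):
            kshape(X, k=6)


class TestSilhouette:
    def test_two_tight_far_clusters_score_one(self):
        D = np.array([[0.0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]])
        values, mean = silhouette(D, np.array([0, 0, 1, 1]))
        assert mean == pytest.approx(1.0)

    def test_equidistant_point_scores_zero(self):
        D = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        values, _ = silhouette(D, np.array([0, 0, 1]))
        assert values[2] == pytest.approx(0.0)  # singleton convention
        # points whose intra and inter distances coincide score 0
        assert values[0] == pytest.approx(0.0)

    def test_matches_direct_formula_on_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            raw = rng.uniform(0.1, 2.0, size=(n, n))
            D = (raw + raw.T) / 2
            np.fill_diagonal(D, 0.0)
            labels = rng.integers(0, 3, size=n)
            if np.unique(labels).size < 2:
                continue
            values, mean = silhouette(D, labels)
            np.testing.assert_allclose(values, silhouette_by_formula(D, labels),
                                       atol=1e-9)

    def test_single_cluster_rejected(self):
        with pytest.raises(UndefinedScoreError):
            silhouette(np.zeros((3, 3)), np.zeros(3, dtype=int))


def _result(condition, labels, persons=None):
    labels = np.asarray(labels)
    persons = persons or [f"P{i:02d}" for i in range(len(labels))]
    return ClusterResult(condition=condition, persons=persons, labels=labels,
                         k=2, seed=0, n_iter=1, objective=0.0)


class TestConsensus:
    def test_identical_partitions_give_extreme_counts(self):
        labels = [0, 0, 0, 1, 1, 1]
        graph = consensus([_result(f"c{i}", labels) for i in range(12)],
                          threshold=10)
        counts = graph.counts
        assert counts[0, 1] == 12 and counts[0, 3] == 0
        within = [(a, b) for a, b, _ in graph.edges]
        assert len(within) == 6  # 2 * C(3,2) fully co-assigned pairs

    def test_threshold_above_condition_count_empties_graph(self):
        graph = consensus([_result(f"c{i}", [0, 1, 0, 1]) for i in range(12)],
                          threshold=13)
        assert graph.edges == []

    def test_invariant_to_global_label_flip(self):
        rng = np.random.default_rng(0)
        partitions = [rng.integers(0, 2, size=8) for _ in range(12)]
        a = consensus([_result(f"c{i}", p) for i, p in enumerate(partitions)])
        flipped = [1 - partitions[0]] + partitions[1:]
        b = consensus([_result(f"c{i}", p) for i, p in enumerate(flipped)])
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_mismatched_person_sets_rejected(self):
        a = _result("c0", [0, 1], persons=["A", "B"])
        b = _result("c1", [0, 1], persons=["A", "C"])
        with pytest.raises(InvalidParameterError):
            consensus([a, b])

    def test_networkx_export_carries_tiers(self):
        graph = consensus([_result(f"c{i}", [0, 0, 1, 1]) for i in range(12)],
                          threshold=10,
                          tiers={"P00": "tier4", "P01": "tier4",
                                 "P02": "tiers1_3", "P03": "tiers1_3"})
        g = graph.to_networkx()
        assert g.nodes["P00"]["tier"] == "tier4"
        assert g.has_edge("P00", "P01")


class TestCompareK:
    def test_two_template_data_prefers_k2(self):
        X, _ = simulate_shape_groups(n_per_group=8, length=80, noise_sd=0.05, seed=1)
        conditions = {("tpl", "guided"): {f"S{i:02d}": X[i] for i in range(len(X))}}
        sil = compare_k(conditions, ks=(2, 3, 4), seed=0, n_init=5)
        assert sil[2] > sil[3] > sil[4]

    def test_three_template_data_prefers_k3(self):
        X, _ = simulate_shape_groups(n_per_group=8, n_groups=3, length=80,
                                     noise_sd=0.05, seed=2)
        conditions = {("tpl", "guided"): {f"S{i:02d}": X[i] for i in range(len(X))}}
        sil = compare_k(conditions, ks=(2, 3, 4), seed=0, n_init=5)
        assert sil[3] == max(sil.values())


class TestSbdMatrix:
    def test_matches_pairwise_sbd(self, rng):
        X = zscore_rows(rng.normal(size=(5, 30)))
        D = sbd_matrix(X)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(sbd(X[i], X[j])[0], abs=1e-9)
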