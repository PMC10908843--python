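import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import dtw_by_path_enumeration
from sclshape.errors import InvalidParameterError, TooShortError
from sclshape.similarity import (
    SimilarityMatrix,
    average_similarity,
    dtw_distance,
    group_similarity,
    modality_similarity,
    resample_block,
    similarity_matrix,
    znorm,
)


class TestZnorm:
    def test_basic_example(self):
        z, degenerate = znorm(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.2247448, 0.0, 1.2247448], atol=1e-6)
        assert not degenerate

    def test_constant_flagged_degenerate(self):
        z, degenerate = znorm(np.full(5, 2.0))
        assert degenerate and not z.any()

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=-5.0, max_value=5.0))
    def test_affine_invariance(self, a, c):
        x = np.array([0.3, -1.2, 2.5, 0.0, 1.1])
        za, _ = znorm(a * x + c)
        zx, _ = znorm(x)
        np.testing.assert_allclose(za, zx, atol=1e-9)

    def test_too_short(self):
        with pytest.raises(TooShortError):
            znorm(np.array([1.0]))


class TestResampleBlock:
    def test_block_means(self):
        np.testing.assert_allclose(resample_block(np.array([1.0, 2, 3, 4]), 4, 2),
                                   [1.5, 3.5])

    def test_constant_stays_constant(self):
        out = resample_block(np.full(400, 2.5), 40, 4)
        assert out.size == 40 and np.all(out == 2.5)

    def test_linear_ramp_block_means(self):
        x = np.arange(40, dtype=float)
        out = resample_block(x, 40, 4)
        np.testing.assert_allclose(out, x.reshape(4, 10).mean(axis=1))

    def test_half_full_trailing_block_kept(self):
        x = np.arange(10, dtype=float)
        out = resample_block(x, 4, 1)  # blocks of 4 -> [0..3], [4..7], rem 2 kept
        np.testing.assert_allclose(out, [1.5, 5.5, 8.5])
        out = resample_block(x[:9], 4, 1)  # rem 1 < half -> dropped
        np.testing.assert_allclose(out, [1.5, 5.5])

    def test_upsampling_rejected(self):
        with pytest.raises(InvalidParameterError):
            resample_block(np.arange(4.0), 4, 8)


class TestDtwDistance:
    def test_identical_series(self):
        x = np.array([0.2, 1.5, -0.3, 0.0])
        assert dtw_distance(x, x) == 0.0

    def test_small_example_by_hand(self):
        # 3x3 table for [0,1,0] vs [0,2,0]: the middle step costs 1 on the
        # diagonal path, every alternative is costlier.
        assert dtw_distance(np.array([0.0, 1, 0]), np.array([0.0, 2, 0])) == 1.0

    def test_symmetry(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=17)
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_matches_path_enumeration_on_random_small_series(self, rng):
        for _ in range(300):
            a = rng.integers(0, 3, size=rng.integers(1, 7)).astype(float)
            b = rng.integers(0, 3, size=rng.integers(1, 7)).astype(float)
            assert dtw_distance(a, b) == pytest.approx(dtw_by_path_enumeration(a, b))

    def test_band_constraint_matches_unconstrained_when_wide(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert dtw_distance(a, b, window=30) == pytest.approx(dtw_distance(a, b))

    def test_empty_series_rejected(self):
        with pytest.raises(TooShortError):
            dtw_distance(np.array([]), np.array([1.0]))


class TestSimilarityMatrix:
    def test_minmax_mapping_with_hand_distances(self):
        # dtw distances among single-sample series [0],[1],[2] are 1, 2, 1
        series = {"A": [0.0], "B": [1.0], "C": [2.0]}
        m = similarity_matrix({k: np.array(v) for k, v in series.items()},
                              already_normalized=True)
        assert m.sim[m.index("A"), m.index("C")] == 0.0  # the d_max pair
        assert m.sim[m.index("A"), m.index("B")] == 50.0
        assert m.sim[m.index("B"), m.index("C")] == 50.0
        assert np.all(np.diag(m.sim) == 100.0)

    def test_duplicated_participant_is_perfectly_similar(self, rng):
        x = rng.normal(size=30)
        m = similarity_matrix({"A": x, "B": x.copy(), "C": rng.normal(size=30)})
        assert m.sim[m.index("A"), m.index("B")] == pytest.approx(100.0)

    def test_degenerate_participants_excluded(self, rng):
        m = similarity_matrix({"A": rng.normal(size=10), "B": rng.normal(size=10),
                               "C": np.full(10, 3.0)})
        assert m.excluded == ["C"] and m.persons == ["A", "B"]

    def test_all_identical_gives_full_similarity(self):
        x = np.sin(np.linspace(0, 3, 25))
        m = similarity_matrix({"A": x, "B": x.copy()})
        assert np.all(m.sim == 100.0)

    def test_scale_and_offset_invariance(self, rng):
        base = {p: rng.normal(size=40) for p in "ABCD"}
        scaled = {p: 3.0 * x + 11.0 for p, x in base.items()}
        ma, mb = similarity_matrix(base), similarity_matrix(scaled)
        np.testing.assert_allclose(ma.sim, mb.sim, atol=1e-8)

    def test_fewer_than_two_participants_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            similarity_matrix({"A": rng.normal(size=10)})


class TestAverageSimilarity:
    def _mat(self, persons, values):
        sim = np.asarray(values, dtype=float)
        return SimilarityMatrix(persons=persons, condition="c", sim=sim,
                                dist=np.zeros_like(sim))

    def test_identical_matrices_average_to_themselves(self):
        m = self._mat(["A", "B"], [[100, 70], [70, 100]])
        out = average_similarity([m, m])
        np.testing.assert_allclose(out.sim, m.sim)

    def test_elementwise_mean(self):
        a = self._mat(["A", "B"], [[100, 40], [40, 100]])
        b = self._mat(["A", "B"], [[100, 60], [60, 100]])
        out = average_similarity([a, b])
        assert out.sim[0, 1] == 50.0

    def test_missing_condition_averaged_over_present(self):
        a = self._mat(["A", "B", "C"],
                      [[100, 40, 20], [40, 100, 30], [20, 30, 100]])
        b = self._mat(["A", "B"], [[100, 60], [60, 100]])
        out = average_similarity([a, b])
        assert out.sim[out.index("A"), out.index("B")] == 50.0
        assert out.sim[out.index("A"), out.index("C")] == 20.0
        assert out.counts[out.index("A"), out.index("C")] == 1
        assert out.counts[out.index("A"), out.index("B")] == 2


class TestGroupSimilarity:
    def test_within_group_means(self):
        sim = np.array([[100.0, 30, 50], [30, 100, 70], [50, 70, 100]])
        m = SimilarityMatrix(persons=["A", "B", "C"], condition="c", sim=sim,
                             dist=np.zeros_like(sim))
        out = group_similarity(m, {"A": "g", "B": "g", "C": "g"})
        assert out["g"] == pytest.approx((30 + 50 + 70) / 3)

    def test_pair_and_singleton_groups(self):
        sim = np.array([[100.0, 70, 10], [70, 100, 20], [10, 20, 100]])
        m = SimilarityMatrix(persons=["A", "B", "C"], condition="c", sim=sim,
                             dist=np.zeros_like(sim))
        out = group_similarity(m, {"A": "x", "B": "x", "C": "y"})
        assert out["x"] == pytest.approx(70.0)
        assert out["y"] is None


class TestModalitySimilarity:
    def test_produces_one_matrix_per_modality(self, small_segments, small_config):
        mats = modality_similarity(small_segments, fs_in=small_config.fs,
                                   scenes=small_config.scenes)
        assert set(mats) == {"guided", "self"}
        for mat in mats.values():
            assert len(mat.persons) == small_config.n_participants
            np.testing.assert_allclose(mat.sim, mat.sim.T, atol=1e-9)
            assert np.nanmin(mat.sim) >= -1e-9 and np.nanmax(mat.sim) <= 100.0 + 1e-9
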