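"""CBS: arc statistic vs brute force, permutation p, recursion, sd-undo."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnaseg import (
    CbsParams,
    CBSSegmenter,
    classify_segments,
    estimate_noise,
    max_t_statistic,
    permutation_pvalue,
    segment_chromosome,
    segment_track,
    undo_splits,
)


from oracles import brute_force_max_t


class TestMaxT:
    def test_clean_step_found_at_planted_boundary(self):
        values = np.array([0, 0, 0, 0, 2, 2, 2, 2], dtype=float)
        i, j, t = max_t_statistic(values)
        # the split {0..3} vs {4..7}; smaller-i representation of the tie
        assert (i, j) == (0, 4)
        assert t == np.inf

    def test_constant_vector_gives_zero(self):
        i, j, t = max_t_statistic(np.full(10, 3.14))
        assert t == 0.0

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 51))
            values = rng.normal(0, 1, n)
            i, j, t = max_t_statistic(values)
            bi, bj, bt = brute_force_max_t(values)
            assert (i, j) == (bi, bj)
            assert t == pytest.approx(bt, rel=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 41))
        values = np.round(rng.normal(0, 1, n), 3)  # rounding provokes ties
        i, j, t = max_t_statistic(values)
        bi, bj, bt = brute_force_max_t(values)
        assert t == pytest.approx(bt, rel=1e-9)
        assert (i, j) == (bi, bj)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            max_t_statistic(np.array([1.0, 2.0, 3.0]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            max_t_statistic(np.array([1.0, np.nan, 0.0, 1.0]))


class TestPermutationP:
    def test_strong_step_is_significant(self, rng):
        values = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(1.0, 0.1, 20)])
        _, _, t = max_t_statistic(values)
        p = permutation_pvalue(values, t, CbsParams(n_permutations=10_000, seed=4))
        assert p <= 0.001

    def test_zero_statistic_gives_p_one(self):
        values = np.random.default_rng(0).normal(0, 1, 30)
        p = permutation_pvalue(values, 0.0, CbsParams(seed=1))
        assert p >= 0.5

    def test_deterministic_given_seed(self, rng):
        values = rng.normal(0, 1, 50)
        _, _, t = max_t_statistic(values)
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        params = CbsParams(n_permutations=2000, seed=0)
        assert permutation_pvalue(values, t, params, rng1) == permutation_pvalue(
            values, t, params, rng2
        )


class TestSegmentChromosome:
    def test_noiseless_two_level(self):
        values = np.concatenate([np.zeros(20), np.full(20, 1.5)])
        segs = segment_chromosome(values, np.arange(1, 41), CbsParams(n_permutations=1000))
        assert [(s.start_idx, s.end_idx) for s in segs] == [(0, 20), (20, 40)]
        assert segs[0].mean == pytest.approx(0.0)
        assert segs[1].mean == pytest.approx(1.5)

    def test_constant_signal_single_segment(self):
        segs = segment_chromosome(np.zeros(50), np.arange(1, 51), CbsParams(n_permutations=1000))
        assert len(segs) == 1
        assert segs[0].n_probes == 50

    def test_noiseless_three_level(self):
        values = np.concatenate([np.zeros(15), np.full(10, 2.0), np.zeros(15)])
        segs = segment_chromosome(values, np.arange(1, 41), CbsParams(n_permutations=1000))
        assert [s.start_idx for s in segs] == [0, 15, 25]

    def test_short_input_single_segment(self):
        segs = segment_chromosome(np.array([0.0, 5.0, 0.0]), np.array([1, 2, 3]))
        assert len(segs) == 1

    def test_partition_invariant(self, rng):
        values = rng.normal(0, 0.2, 80)
        values[30:50] += 1.2
        segs = segment_chromosome(values, np.arange(1, 81), CbsParams(n_permutations=1000))
        assert segs[0].start_idx == 0
        assert segs[-1].end_idx == 80
        for a, b in zip(segs, segs[1:]):
            assert a.end_idx == b.start_idx
        for s in segs:
            assert s.mean == pytest.approx(values[s.start_idx : s.end_idx].mean(), abs=1e-9)

    def test_affine_invariance_of_boundaries(self, rng):
        values = rng.normal(0, 0.2, 60)
        values[20:40] += 1.0
        params = CbsParams(n_permutations=1000, seed=3)
        pos = np.arange(1, 61)
        b1 = [s.start_idx for s in segment_chromosome(values, pos, params)]
        b2 = [s.start_idx for s in segment_chromosome(values * 3.7 - 2.0, pos, params)]
        assert b1 == b2


class TestUndoSplits:
    def test_small_difference_merged(self):
        values = np.concatenate([np.zeros(10), np.full(10, 0.1)])
        bounds = undo_splits([0, 10, 20], values, undo_sd=0.5, sigma=0.5)
        assert bounds == [0, 20]  # 0.1 < 0.25

    def test_large_difference_kept(self):
        values = np.concatenate([np.zeros(10), np.full(10, 2.0)])
        bounds = undo_splits([0, 10, 20], values, undo_sd=0.5, sigma=0.5)
        assert bounds == [0, 10, 20]

    def test_undo_sd_zero_never_merges(self):
        values = np.concatenate([np.zeros(5), np.full(5, 1e-9)])
        bounds = undo_splits([0, 5, 10], values, undo_sd=0.0, sigma=1.0)
        assert bounds == [0, 5, 10]

    def test_cascading_merges_recompute_means(self):
        # 0 | 0.2 | 0.4 with threshold 0.325: the first merge (diff 0.2)
        # moves the combined mean to 0.1, and the remaining pair
        # (0.1 vs 0.4, diff 0.3) still falls under the rule.
        values = np.concatenate([np.zeros(10), np.full(10, 0.2), np.full(10, 0.4)])
        bounds = undo_splits([0, 10, 20, 30], values, undo_sd=0.65, sigma=0.5)
        assert bounds == [0, 30]

    def test_merge_stops_at_threshold(self):
        # same layout, threshold 0.3: second gap is exactly 0.3, not < 0.3
        values = np.concatenate([np.zeros(10), np.full(10, 0.2), np.full(10, 0.4)])
        bounds = undo_splits([0, 10, 20, 30], values, undo_sd=0.6, sigma=0.5)
        assert bounds == [0, 20, 30]


class TestNoiseEstimate:
    def test_recovers_iid_sd(self):
        x = np.random.default_rng(5).normal(0, 0.2, 10_000)
        assert estimate_noise(x) == pytest.approx(0.2, abs=0.01)

    def test_noiseless_piecewise_constant_is_zero(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        assert estimate_noise(x) == 0.0

    def test_robust_to_single_step(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.2, 5000)
        with_step = x.copy()
        with_step[2500:] += 10.0
        s0, s1 = estimate_noise(x), estimate_noise(with_step)
        assert abs(s1 - s0) / s0 < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise(np.array([1.0]))


class TestClassifySegments:
    def test_all_zero_means_unchanged(self):
        track = _track_from_values(np.zeros(30))
        res = segment_track(track, CbsParams(n_permutations=1000))
        res, table = classify_segments(res)
        assert table["unchanged"] == 1.0

    def test_one_segment_per_category(self):
        from cnaseg.segmentation import Segment, SegmentationResult

        means = [-0.7, -0.3, 0.0, 0.3, 0.7]
        res = SegmentationResult(sample_id="x")
        res.segments["chr1"] = [
            Segment("chr1", i, i + 1, i * 10 + 1, i * 10 + 5, 1, m) for i, m in enumerate(means)
        ]
        res, table = classify_segments(res)
        assert np.allclose(table[:5].to_numpy(float), 0.2)
        assert [s.category for s in res.segments["chr1"]] == [
            "highly decreased", "slightly decreased", "unchanged",
            "slightly increased", "highly increased",
        ]


def _track_from_values(values, chrom="chr1"):
    import pandas as pd

    return pd.DataFrame({"chrom": chrom, "pos": np.arange(1, len(values) + 1), "log2ratio": values})


class TestEstimator:
    def test_fit_predict_returns_segment_means(self, rng):
        values = np.concatenate([np.zeros(20), np.full(20, 1.5)])
        est = CBSSegmenter(n_permutations=1000)
        fitted = est.fit_predict(values)
        assert np.allclose(fitted[:20], 0.0)
        assert np.allclose(fitted[20:], 1.5)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = CBSSegmenter(alpha=0.01, n_permutations=500)
        est2 = clone(est)
        assert est2.get_params()["alpha"] == 0.01

    def test_rerun_is_bit_identical(self, rng):
        values = rng.normal(0, 0.3, 100)
        values[40:70] += 1.0
        track = _track_from_values(values)
        r1 = segment_track(track, CbsParams(n_permutations=1000, seed=9), "s")
        r2 = segment_track(track, CbsParams(n_permutations=1000, seed=9), "s")
        assert r1.to_seg() == r2.to_seg()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CbsParams(alpha=0.001, n_permutations=10)  # < 1/alpha
        with pytest.raises(ValueError):
            CbsParams(min_width=1)
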