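"""e-karyotyping stages: centering, filters, PCF, calling, smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monokaryo import (
    EKaryoParams,
    EKaryotype,
    GeneAnnotation,
    CountMatrix,
    call_aberrations,
    moving_average,
    pcf_segment,
    relative_expression,
    variability_filter,
    winsorize_track,
)
from monokaryo.karyotype import RelativeTrack, Segment, estimate_noise_sd, segmentation_cost

from .oracles import brute_force_pcf_cost


def make_track(values, chromosomes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    n = values.shape[0]
    cols = samples or [f"s{j}" for j in range(values.shape[1])]
    idx = [f"g{i:04d}" for i in range(n)]
    chrom = pd.Series(chromosomes or ["chr1"] * n, index=idx)
    return RelativeTrack(pd.DataFrame(values, index=idx, columns=cols), chrom)


def simple_annotation(n, chrom="chr1"):
    return GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": [chrom] * n,
                "start": np.arange(n) * 100,
                "end": np.arange(n) * 100 + 50,
                "strand": "+",
            },
            index=pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id"),
        )
    )


class TestRelativeExpression:
    def test_median_subtraction_odd_and_even(self):
        ann = simple_annotation(2)
        log_expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]],
            index=["g0000", "g0001"],
            columns=["a", "b", "c"],
        )
        track = relative_expression(log_expr, ann)
        np.testing.assert_allclose(track.values.loc["g0000"], [-1, 0, 1])
        np.testing.assert_allclose(track.values.loc["g0001"], [0, 0, 0])

        log4 = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]], index=["g0000"], columns=list("abcd")
        )
        track4 = relative_expression(log4, simple_annotation(1))
        np.testing.assert_allclose(track4.values.loc["g0000"], [-1.5, -0.5, 0.5, 1.5])

    def test_genes_missing_from_annotation_are_excluded_with_warning(self):
        ann = simple_annotation(1)
        log_expr = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["g0000", "unknown"], columns=["a", "b"]
        )
        with pytest.warns(UserWarning, match="1 genes"):
            track = relative_expression(log_expr, ann)
        assert list(track.values.index) == ["g0000"]

    def test_reference_subset_defines_baseline(self):
        ann = simple_annotation(1)
        log_expr = pd.DataFrame(
            [[0.0, 2.0, 10.0]], index=["g0000"], columns=["a", "b", "c"]
        )
        track = relative_expression(log_expr, ann, reference_samples=["a", "b"])
        np.testing.assert_allclose(track.values.loc["g0000"], [-1, 1, 9])


class TestVariabilityFilter:
    def test_exact_removal_count(self):
        track = make_track(np.linspace(0, 1, 1000)[:, None] * [1.0, -1.0])
        out = variability_filter(track, 0.10)
        assert out.values.shape[0] == 900

    def test_floor_convention(self):
        track = make_track(np.arange(15, dtype=float)[:, None] * [1.0])
        out = variability_filter(track, 0.10)
        assert out.values.shape[0] == 14  # floor(1.5) = 1 removed

    def test_tie_rule_removes_latest_positions(self):
        track = make_track(np.ones((20, 2)))
        out = variability_filter(track, 0.10)
        # all SS equal -> the floor(0.1*20)=2 latest genes go
        assert list(out.values.index) == [f"g{i:04d}" for i in range(18)]

    def test_keeps_least_variable(self):
        values = np.zeros((10, 2))
        values[3] = [5, -5]
        track = make_track(values)
        out = variability_filter(track, 0.10)
        assert "g0003" not in out.values.index


class TestWinsorize:
    def test_quantile_zero_is_identity(self):
        track = make_track(np.random.default_rng(0).normal(size=(100, 2)))
        out = winsorize_track(track, 0.0)
        pd.testing.assert_frame_equal(out.values, track.values)

    def test_constant_unchanged(self):
        track = make_track(np.full((50, 2), 3.14))
        out = winsorize_track(track, 0.01)
        pd.testing.assert_frame_equal(out.values, track.values)

    def test_altered_count_matches_order_statistics(self):
        """With 1,000 distinct sorted values and q=0.001, exactly the values
        strictly below the 2nd order statistic and strictly above the 999th
        are altered -- one at each tail."""
        rng = np.random.default_rng(1)
        vals = np.sort(rng.normal(size=1000))
        track = make_track(vals[:, None])
        out = winsorize_track(track, 0.001)
        altered = (out.values.to_numpy()[:, 0] != vals).sum()
        # independent order-statistics count
        lo, hi = vals[1], vals[998]  # ceil(0.001*999)=1, floor(0.999*999)=998
        expected = int((vals < lo).sum() + (vals > hi).sum())
        assert altered == expected == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=60),
        st.sampled_from([0.001, 0.01, 0.1, 0.25]),
    )
    def test_idempotent(self, values, q):
        track = make_track(np.asarray(values)[:, None])
        once = winsorize_track(track, q)
        twice = winsorize_track(once, q)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestPCF:
    def test_constant_track_single_segment(self):
        segs = pcf_segment(np.full(80, 2.5), penalty=12)
        assert segs == [Segment(0, 79, 2.5)]

    def test_noiseless_step(self):
        y = np.r_[np.zeros(60), np.ones(60)]
        segs = pcf_segment(y, penalty=12, min_size=50)
        assert [(s.start, s.end) for s in segs] == [(0, 59), (60, 119)]
        assert segs[0].mean == 0.0 and segs[1].mean == 1.0

    def test_short_track_returns_single_segment(self):
        segs = pcf_segment(np.array([1.0, 5.0]), min_size=50)
        assert segs == [Segment(0, 1, 3.0)]

    def test_empty_track(self):
        assert pcf_segment(np.array([])) == []

    def test_dp_cost_equals_brute_force(self, rng):
        """Exhaustive-enumeration oracle on short random tracks."""
        for _ in range(60):
            n = int(rng.integers(2, 13))
            y = rng.normal(size=n)
            gamma = float(rng.choice([0.0, 0.3, 1.0, 4.0]))
            segs = pcf_segment(y, penalty=gamma, min_size=1, sigma=1.0)
            cost = segmentation_cost(y, segs, gamma)
            assert cost == pytest.approx(brute_force_pcf_cost(y, gamma), abs=1e-9)

    def test_min_size_constraint_respected(self, rng):
        for _ in range(20):
            y = rng.normal(size=24)
            segs = pcf_segment(y, penalty=0.1, min_size=5, sigma=1.0)
            assert all(s.length >= 5 for s in segs)

    def test_partition_invariant(self, rng):
        y = rng.normal(size=300) + np.r_[np.zeros(150), np.ones(150)]
        segs = pcf_segment(y, penalty=12)
        assert segs[0].start == 0 and segs[-1].end == 299
        for a, b in zip(segs, segs[1:]):
            assert b.start == a.end + 1

    def test_penalty_monotonicity(self, rng):
        y = rng.normal(size=200) * 0.2 + np.repeat([0.0, 1.0, 0.0, -1.0], 50)
        counts = [
            len(pcf_segment(y, penalty=g, sigma=1.0))
            for g in [0.01, 0.1, 1.0, 10.0, 100.0]
        ]
        assert counts == sorted(counts, reverse=True)


class TestCallAberrations:
    params = EKaryoParams()

    def test_strong_long_segment_called_as_gain(self):
        calls = call_aberrations([Segment(0, 59, 0.30)], self.params, sigma=0.01)
        row = calls.iloc[0]
        assert bool(row["called"]) and row["direction"] == "gain"

    def test_too_short_not_called(self):
        calls = call_aberrations([Segment(0, 48, 0.30)], self.params, sigma=0.01)
        assert not calls["called"].any()

    def test_too_shallow_not_called(self):
        calls = call_aberrations([Segment(0, 499, 0.20)], self.params, sigma=0.01)
        assert not calls["called"].any()

    def test_insignificant_not_called(self):
        # deviation and size pass but noise is huge -> p above threshold
        calls = call_aberrations([Segment(0, 59, 0.30)], self.params, sigma=10.0)
        assert not calls["called"].any()

    def test_loss_direction(self):
        calls = call_aberrations([Segment(0, 99, -0.5)], self.params, sigma=0.01)
        assert calls.iloc[0]["direction"] == "loss" and bool(calls.iloc[0]["called"])


class TestMovingAverage:
    def test_window_one_is_identity(self):
        df = pd.DataFrame({"s": [1.0, 2.0, 3.0]})
        pd.testing.assert_frame_equal(moving_average(df, 1), df)

    def test_constant_stays_constant(self):
        df = pd.DataFrame({"s": np.full(30, 7.0)})
        np.testing.assert_allclose(moving_average(df, 5)["s"], 7.0)

    def test_hand_computed_window_three(self):
        df = pd.DataFrame({"s": [0.0, 0.0, 3.0, 0.0, 0.0]})
        out = moving_average(df, 3)
        np.testing.assert_allclose(out["s"], [0.0, 1.0, 1.0, 1.0, 0.0])

    def test_never_averages_across_chromosomes(self):
        df = pd.DataFrame({"s": [1.0, 1.0, 9.0, 9.0]})
        chrom = pd.Series(["chr1", "chr1", "chr2", "chr2"], index=df.index)
        out = moving_average(df, 3, chrom)
        np.testing.assert_allclose(out["s"], [1.0, 1.0, 9.0, 9.0])


class TestEKaryotypeModel:
    def test_identical_columns_give_zero_calls(self):
        n = 200
        col = np.random.default_rng(0).integers(30, 500, n)
        counts = CountMatrix(
            pd.DataFrame(
                {s: col for s in ["a", "b", "c", "d"]},
                index=[f"g{i:04d}" for i in range(n)],
            )
        )
        ann = simple_annotation(n)
        res = EKaryotype(counts, ann, EKaryoParams(least_allowed_aberration_size=20)).fit()
        assert res.calls.empty
        assert all(res.is_stable(s) for s in ["a", "b", "c", "d"])

    def test_segments_tile_each_chromosome(self, small_cohort):
        _, counts, ann, _ = small_cohort
        res = EKaryotype(counts, ann).fit()
        for (_, _), grp in res.segments.groupby(["sample", "chromosome"]):
            grp = grp.sort_values("start_idx")
            assert grp.iloc[0]["start_idx"] == 0
            starts = grp["start_idx"].to_numpy()[1:]
            ends = grp["end_idx"].to_numpy()[:-1]
            np.testing.assert_array_equal(starts, ends + 1)

    def test_needs_three_samples(self):
        counts = CountMatrix(
            pd.DataFrame({"a": [1, 2], "b": [3, 4]}, index=["g0000", "g0001"])
        )
        with pytest.raises(Exception, match="3 samples"):
            EKaryotype(counts, simple_annotation(2))

    def test_noise_sd_estimator_on_gaussian(self, rng):
        y = rng.normal(0, 0.35, 5000)
        assert estimate_noise_sd(y) == pytest.approx(0.35, rel=0.05)
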