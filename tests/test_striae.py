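"""Striae processing: break detection, back-calculation, truncation, synchronization."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclerogrowth.striae import (
    StriaeSeries,
    back_calculate_heights,
    detect_winter_breaks,
    mean_trajectory,
    synchronize_cohort,
    truncate_winters,
)
from sclerogrowth.synthetic import StationScenario, seasonal_envelope, simulate_cohort


def _truncated(series, **kw):
    return truncate_winters(
        replace(series, winter_breaks=detect_winter_breaks(series.increments_um, **kw)),
        **kw,
    )


class TestDetectWinterBreaks:
    def test_explicit_zero_run(self):
        x = [100, 110, 0, 0, 0, 0, 0, 120, 130]
        assert detect_winter_breaks(x, stop_threshold_um=0, min_stop_run_days=3) == [7]

    def test_no_stop_means_single_growth_year(self):
        assert detect_winter_breaks([50, 60, 70], stop_threshold_um=5) == []

    def test_short_slow_runs_ignored(self):
        x = [100, 0, 0, 100, 0, 0, 0, 100]
        assert detect_winter_breaks(x, stop_threshold_um=0, min_stop_run_days=3) == [7]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_winter_breaks([1.0], stop_threshold_um=-1)

    def test_matches_generator_boundaries_for_cohort(self):
        sc = StationScenario.linear_seasons(
            "b", 230.0, 240, -10, 4, n_individuals=25, noise_cv=0.05,
            start_jitter_days=10, seed=2,
        )
        cohort = simulate_cohort(sc)
        for s, t in zip(cohort.series, cohort.truth):
            assert detect_winter_breaks(s.increments_um) == t.winter_breaks


class TestBackCalculateHeights:
    def test_simple_arithmetic(self):
        s = StriaeSeries("a", np.full(200, 100.0), winter_breaks=[200])
        assert back_calculate_heights(s) == [(1, pytest.approx(20.0))]

    def test_initial_offset_only(self):
        s = StriaeSeries("a", np.array([]), initial_height_um=5000.0)
        assert back_calculate_heights(s) == [(1, pytest.approx(5.0))]

    def test_matches_generator_cumulative_heights(self, small_cohort):
        for s, t in zip(small_cohort.series, small_cohort.truth):
            heights = back_calculate_heights(s)
            expect = np.cumsum(t.season_height_gain_mm)
            assert len(heights) == len(expect)
            for (_, h), e in zip(heights, expect):
                assert h == pytest.approx(e, abs=1e-3)

    @given(
        incs=st.lists(st.floats(0, 500), min_size=1, max_size=60),
        init=st.floats(0, 10000),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_final_height_conserved_under_any_break_placement(self, incs, init, data):
        """Conservation: edge height = initial + total growth, however winters fall."""
        n = len(incs)
        breaks = sorted(
            data.draw(st.sets(st.integers(1, n), max_size=min(5, n)))
        )
        s = StriaeSeries("c", np.array(incs), winter_breaks=breaks, initial_height_um=init)
        final = back_calculate_heights(s)[-1][1]
        assert final == pytest.approx((init + sum(incs)) / 1000.0, rel=1e-12, abs=1e-12)


class TestTruncateWinters:
    def test_removes_flagged_run(self):
        s = StriaeSeries("t", np.array([100.0, 0, 0, 0, 120.0]), winter_breaks=[4])
        out = truncate_winters(s, stop_threshold_um=0, min_stop_run_days=3)
        assert [seg.tolist() for seg in out.segments] == [[100.0], [120.0]]
        assert out.winter_breaks == [1]

    def test_identity_without_breaks(self):
        s = StriaeSeries("t", np.array([100.0, 90.0, 110.0]))
        out = truncate_winters(s)
        assert np.array_equal(out.increments_um, s.increments_um)
        assert out.segments[0].tolist() == [100.0, 90.0, 110.0]

    def test_idempotent_after_detection(self, small_cohort):
        for s in small_cohort.series[:3]:
            once = _truncated(s)
            twice = truncate_winters(once)
            assert np.array_equal(once.increments_um, twice.increments_um)
            assert once.winter_breaks == twice.winter_breaks

    def test_segment_lengths_equal_generator_seasons(self, small_cohort):
        for s, t in zip(small_cohort.series, small_cohort.truth):
            segs = _truncated(s).segments
            assert [len(g) for g in segs] == t.season_lengths


class TestSynchronizeCohort:
    def test_preshifted_identical_series_realign_exactly(self):
        base = np.concatenate(
            [np.linspace(10, 200, 50), np.full(100, 200.0), np.linspace(200, 10, 50)]
        )
        offsets, objective = synchronize_cohort([base[5:], base], max_lag_days=10)
        assert offsets == [0, -5]
        assert objective == pytest.approx(0.0, abs=1e-8)

    def test_single_series_trivial(self):
        assert synchronize_cohort([np.ones(30)]) == ([0], 0.0)

    def test_objective_invariant_under_global_shift(self):
        rng = np.random.default_rng(0)
        series = [rng.normal(100, 20, 60) for _ in range(4)]
        from sclerogrowth.striae import _pair_msd

        offs, obj = synchronize_cohort(series, max_lag_days=5)

        def total(offsets):
            return sum(
                _pair_msd(series[i], series[j], offsets[j] - offsets[i], 1e12)
                for i in range(4)
                for j in range(i + 1, 4)
            )

        assert total(offs) == pytest.approx(obj)
        assert total([o + 3 for o in offs]) == pytest.approx(obj)

    def test_recovers_planted_window_lags(self):
        """Windows of one shared seasonal curve realign to their planted lags."""
        rng = np.random.default_rng(42)
        mother = seasonal_envelope(np.arange(240), 200, 20, 250.0)
        mother = mother * (1 + 0.1 * np.sin(np.arange(240) / 3.0))  # day-scale texture
        shifts = rng.integers(-10, 11, size=10)
        shifts[0] = 0
        sig = np.sqrt(np.log(1 + 0.05**2))
        kids = [
            mother[20 + s : 20 + s + 180]
            * rng.lognormal(-sig * sig / 2, sig, 180)
            for s in shifts
        ]
        rec, _ = synchronize_cohort(kids, max_lag_days=15)
        errors = [abs(r - int(s - shifts[0])) for r, s in zip(rec, shifts)]
        assert sum(e <= 1 for e in errors) >= 9

    def test_recovers_generator_jitters(self):
        sc = StationScenario.linear_seasons(
            "s", 250.0, 200, 0, 1, n_individuals=10, noise_cv=0.05,
            start_jitter_days=10, seed=4,
        )
        cohort = simulate_cohort(sc)
        segs = [_truncated(s).segments[0] for s in cohort.series]
        jit = [t.jitter_days for t in cohort.truth]
        rec, _ = synchronize_cohort(segs, max_lag_days=25)
        errors = [abs(r - (j - jit[0])) for r, j in zip(rec, jit)]
        assert sum(e <= 1 for e in errors) >= 9


class TestMeanTrajectory:
    def test_constant_series_zero_ci(self):
        df = mean_trajectory([np.full(20, 100.0)] * 3)
        assert np.allclose(df["mean_um"], 100.0)
        assert np.allclose(df["ci95_um"], 0.0)
        assert (df["n"] == 3).all()

    def test_closed_form_t_interval(self):
        df = mean_trajectory([np.array([90.0]), np.array([100.0]), np.array([110.0])])
        assert df.loc[1, "mean_um"] == pytest.approx(100.0)
        # SE = 5.774, t(0.975, 2) = 4.303
        assert df.loc[1, "ci95_um"] == pytest.approx(24.84, abs=0.01)

    def test_single_contributor_days_degenerate(self):
        df = mean_trajectory([np.array([1.0, 2.0, 3.0]), np.array([1.0])])
        assert df.loc[2, "n"] == 1
        assert df.loc[2, "ci95_um"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_trajectory([])

    def test_cohort_mean_tracks_deterministic_curve(self, small_cohort):
        """The synchronized mean stays within 3 SE of the shared curve almost everywhere."""
        from scipy import stats

        from sclerogrowth.synthetic import _season_curve

        segs = [_truncated(s).segments[0] for s in small_cohort.series]
        offs, _ = synchronize_cohort(segs, max_lag_days=20)
        df = mean_trajectory(segs, offs)
        sc = small_cohort.scenario
        curve = _season_curve(sc, 0)
        # anchor (offset 0) day d sits at calendar x = J + jitter_0 + d
        x0 = sc.start_jitter_days + small_cohort.truth[0].jitter_days + min(offs) - 1
        rows = df[df["n"] >= 4]
        ok = 0
        for idx, row in rows.iterrows():
            expected = curve[x0 + idx]
            se = row["ci95_um"] / stats.t.ppf(0.975, row["n"] - 1)
            ok += abs(row["mean_um"] - expected) <= 3 * max(se, 1e-9)
        assert ok / len(rows) >= 0.95
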