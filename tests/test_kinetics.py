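"""Kinetics: crossings, alignment, speeds, summaries and population
averages, checked against analytic logistic identities and dense-grid
oracles."""

import numpy as np
import pytest

from conftest import logistic_trace, trace_from_arrays
from furrow.exceptions import (
    LevelNotReachedError,
    NonMonotoneTraceError,
    WindowError,
)
from furrow.kinetics import (
    align_traces,
    asymmetry_at_closure,
    average_speed_20_80,
    crossing_time,
    kinetics_summary,
    peak_speed,
    population_average,
    speed_series,
)
from furrow.simulate import logistic_closure


def linear_trace(rate=10.0, dt=0.5, t_end=10.0, **kw):
    t = np.arange(0, t_end + dt / 2, dt)
    return trace_from_arrays(t, rate * t, **kw)


class TestCrossingTime:
    def test_linear_interpolation_between_brackets(self):
        tr = trace_from_arrays([3, 4, 5, 6, 7], [40, 48, 52, 60, 70])
        assert crossing_time(tr, 50.0) == pytest.approx(4.5)

    def test_exact_sample_at_level(self):
        tr = trace_from_arrays([0, 1, 2, 3, 4], [10, 30, 50, 70, 90])
        assert crossing_time(tr, 50.0) == 2.0

    def test_level_never_reached(self):
        tr = trace_from_arrays([0, 1, 2, 3, 4], [10, 20, 30, 35, 40])
        with pytest.raises(LevelNotReachedError):
            crossing_time(tr, 50.0)


class TestAlignment:
    def test_single_trace_shifted_by_its_midpoint(self):
        tr = trace_from_arrays([3, 4, 5, 6, 7], [40, 48, 52, 60, 70])
        (aligned,) = align_traces([tr])
        assert aligned.times == pytest.approx(
            tuple(t - 4.5 for t in tr.times)
        )
        assert crossing_time(aligned, 50.0) == pytest.approx(0.0, abs=1e-12)

    def test_identical_traces_align_identically(self):
        tr = logistic_trace(0.5, 10.0, 0.5)
        a, b = align_traces([tr, tr])
        assert a.times == b.times

    def test_idempotent_and_all_cross_at_zero(self):
        traces = [logistic_trace(0.5, t0, 0.5) for t0 in (6.0, 9.0, 12.0)]
        once = align_traces(traces)
        twice = align_traces(once)
        for tr1, tr2 in zip(once, twice):
            assert tr1.times == pytest.approx(tr2.times, abs=1e-12)
            assert crossing_time(tr1, 50.0) == pytest.approx(0.0, abs=1e-9)


class TestSpeedSeries:
    def test_linear_closure_gives_constant_speed(self):
        tr = linear_trace(10.0)
        for window in (1, 3, 5):
            _, v = speed_series(tr, window)
            assert v == pytest.approx(np.full_like(v, 10.0))

    def test_constant_closure_gives_zero_speed(self):
        tr = trace_from_arrays(np.arange(6.0), np.full(6, 30.0))
        _, v = speed_series(tr, 3)
        assert v == pytest.approx(np.zeros_like(v), abs=1e-12)

    def test_logistic_peak_near_analytic_maximum(self):
        """Logistic k = 0.5/min at dt = 0.5: the discrete speed maximum
        sits nearest t0 and within 3% of 25k = 12.5 %/min."""
        tr = logistic_trace(0.5, 10.0, 0.5)
        t, v = speed_series(tr, 1)
        i = int(np.argmax(v))
        assert abs(t[i] - 10.0) <= 0.5
        assert v[i] == pytest.approx(12.5, rel=0.03)

    def test_window_must_fit_trace(self):
        tr = linear_trace(10.0, dt=2.0, t_end=8.0)  # 5 frames
        with pytest.raises(WindowError):
            speed_series(tr, 7)

    def test_even_window_rejected(self):
        with pytest.raises(WindowError):
            speed_series(linear_trace(), 4)


class TestAverageSpeed2080:
    def test_linear_closure_recovers_rate(self):
        assert average_speed_20_80(linear_trace(10.0)) == pytest.approx(10.0)

    def test_matches_dense_grid_ols_oracle(self):
        """Densely sampled logistic (k = 0.5, dt = 0.01): the OLS slope
        over the 20-80% window matches an independent dense-grid OLS on
        the analytic curve (~11.4 %/min; above the endpoint average
        30k/ln4 ~ 10.82) within 2%."""
        k, t0 = 0.5, 10.0
        tr = logistic_trace(k, t0, 0.01)
        # oracle: OLS of the analytic curve on its own dense grid
        tt = np.linspace(t0 + np.log(0.25) / k, t0 + np.log(4.0) / k, 20001)
        cc = logistic_closure(tt, k, t0)
        oracle = np.polyfit(tt, cc, 1)[0]
        est = average_speed_20_80(tr)
        assert est == pytest.approx(oracle, rel=0.02)
        assert est == pytest.approx(11.4, rel=0.02)
        assert est > 30 * k / np.log(4.0)

    def test_slope_scales_with_rate(self):
        s1 = average_speed_20_80(logistic_trace(0.5, 10.0, 0.05))
        s2 = average_speed_20_80(logistic_trace(1.0, 10.0, 0.05))
        assert s2 / s1 == pytest.approx(2.0, rel=0.02)

    def test_invariant_under_time_translation_and_equivariant_under_scaling(self):
        tr = logistic_trace(0.5, 10.0, 0.25)
        shifted = tr.shifted(7.3)
        assert average_speed_20_80(shifted) == pytest.approx(
            average_speed_20_80(tr), rel=1e-9
        )
        squeezed = trace_from_arrays(
            tr.time_array / 2.0, tr.closure, tr.asymmetry
        )
        assert average_speed_20_80(squeezed) == pytest.approx(
            2.0 * average_speed_20_80(tr), rel=1e-9
        )

    def test_span_not_covered(self):
        tr = trace_from_arrays([0, 1, 2, 3, 4], [25, 30, 40, 50, 60])
        with pytest.raises(LevelNotReachedError):
            average_speed_20_80(tr)


class TestPeakSpeed:
    def test_linear_closure(self):
        speed, _ = peak_speed(linear_trace(10.0))
        assert speed == pytest.approx(10.0)

    def test_logistic_peak_18_percent_per_minute(self):
        """k = 0.72/min gives the analytic peak 25k = 18 %/min near half
        closure."""
        tr = logistic_trace(0.72, 5.0, 0.05)
        speed, closure_at = peak_speed(tr, 1)
        assert speed == pytest.approx(18.0, rel=0.03)
        assert abs(closure_at - 50.0) <= 5.0

    @pytest.mark.parametrize("k", [0.2, 0.5, 1.0])
    def test_symmetric_sigmoid_peaks_at_half_closure(self, k):
        tr = logistic_trace(k, 10.0, 0.1)
        _, closure_at = peak_speed(tr, 1)
        assert abs(closure_at - 50.0) <= 100 * k * 0.1 / 4 + 1e-9


class TestKineticsSummary:
    def test_linear_trace_summary(self):
        s = kinetics_summary(linear_trace(10.0, dt=0.25))
        assert s.t_mid == pytest.approx(5.0)
        assert s.avg_speed_20_80 == pytest.approx(10.0)
        assert s.endpoint_speed_20_80 == pytest.approx(10.0)
        assert s.peak_speed == pytest.approx(10.0)
        assert s.duration_10_90 == pytest.approx(8.0)

    def test_logistic_midpoint_is_t0(self):
        s = kinetics_summary(logistic_trace(0.5, 10.0, 0.5))
        assert s.t_mid == pytest.approx(10.0, abs=0.5)

    def test_decreasing_trace_rejected(self):
        t = np.arange(0, 5, 0.5)
        tr = trace_from_arrays(t, 90 - 15 * t)
        with pytest.raises(NonMonotoneTraceError):
            kinetics_summary(tr)

    def test_speed_integral_between_crossings_is_60_points(self):
        """Trapezoidal integral of the unsmoothed speed between the 20%
        and 80% crossings recovers the 60 closed percentage points."""
        tr = logistic_trace(0.5, 10.0, 0.01)
        t, v = speed_series(tr, 1)
        t20, t80 = crossing_time(tr, 20.0), crossing_time(tr, 80.0)
        mask = (t >= t20) & (t <= t80)
        integral = np.trapezoid(v[mask], t[mask])
        assert integral == pytest.approx(60.0, rel=0.01)


class TestPopulationAverage:
    def test_identical_traces_have_zero_sem(self):
        tr = logistic_trace(0.5, 10.0, 0.5)
        curve = population_average([tr, tr, tr], "closure")
        assert curve.sem == pytest.approx(np.zeros_like(curve.sem), abs=1e-9)
        assert np.all(curve.n == 3)

    def test_two_constant_traces_mean_and_sem(self):
        t = np.arange(0, 5, 0.5)
        a = trace_from_arrays(t, np.full(len(t), 40.0))
        b = trace_from_arrays(t, np.full(len(t), 60.0))
        curve = population_average([a, b], "closure", align=False)
        assert curve.mean == pytest.approx(np.full_like(curve.mean, 50.0))
        # sample sd (n-1) of {40, 60} is 10*sqrt(2); SEM = sd/sqrt(2) = 10,
        # i.e. half the separation, the two-point standard error
        assert curve.sem == pytest.approx(np.full_like(curve.sem, 10.0))

    def test_noisy_population_mean_covers_generating_curve(self, rng):
        """50 noisy logistic traces (sigma = 2 points): the mean curve
        lies within 2 SEM of the generating curve at >= 95% of the fully
        supported grid points."""
        k, t0 = 0.5, 10.0
        n_traces = 50
        traces = []
        for i in range(n_traces):
            base = logistic_trace(k, t0, 0.5, trace_id=f"n{i}")
            noisy = base.closure + rng.normal(0, 2.0, len(base.times))
            traces.append(trace_from_arrays(base.time_array, noisy))
        curve = population_average(traces, "closure")
        truth = logistic_closure(curve.grid, k, 0.0)  # aligned at midpoint
        ok = np.abs(curve.mean - truth) <= 2 * np.maximum(curve.sem, 1e-9)
        full = curve.n == n_traces
        assert ok[full].mean() >= 0.95

    def test_empty_population_rejected(self):
        with pytest.raises(Exception):
            population_average([], "closure")


class TestAsymmetryAtClosure:
    def test_concentric_trace_is_zero_everywhere(self):
        tr = logistic_trace(0.5, 10.0, 0.5, alpha=0.0)
        for level in (20.0, 50.0, 80.0):
            assert asymmetry_at_closure(tr, level) == pytest.approx(0.0)

    def test_drift_model_asymmetry_is_alpha_times_closure(self):
        tr = logistic_trace(0.5, 10.0, 0.1, alpha=0.6)
        assert asymmetry_at_closure(tr, 80.0) == pytest.approx(48.0, abs=0.1)

    def test_level_beyond_trace_maximum(self):
        tr = trace_from_arrays([0, 1, 2, 3, 4], [10, 30, 50, 60, 70])
        with pytest.raises(LevelNotReachedError):
            asymmetry_at_closure(tr, 80.0)


class TestSigmoidSignature:
    @pytest.mark.parametrize("k", [0.3, 0.72, 1.5])
    def test_speed_rises_before_midpoint_and_falls_after(self, k):
        """On any noise-free logistic trace the estimated speed increases
        up to the midpoint and decreases after (acceleration then
        deceleration)."""
        tr = logistic_trace(k, 10.0, 0.25)
        t, v = speed_series(tr, 3)
        i_mid = int(np.argmin(np.abs(t - 10.0)))
        before = np.diff(v[: i_mid + 1])
        after = np.diff(v[i_mid:])
        # interior differences strictly monotone; endpoints one-sided
        assert np.all(before[1:] > -1e-9)
        assert np.all(after[:-1] < 1e-9)
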