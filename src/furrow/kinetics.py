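"""Closure kinetics: aligned curves, speeds and population averages.

A :class:`RingTrace` is a time-ordered sequence of per-frame metrics for
one dividing cell, with times in minutes.  From it we derive the standard
kinetics read-outs of furrowing studies:

* the midpoint time (50% closure crossing), used to align traces before
  population averaging;
* speed over time (finite differences of closure after light smoothing),
  which rises to a peak near half closure and falls again — the
  acceleration/deceleration signature of metazoan cytokinesis;
* the average speed between 20% and 80% closure, the scalar most often
  compared across cell sizes, computed as the OLS slope of closure vs
  time over that window (an endpoint-difference estimate is also
  available);
* per-point mean ± SEM population curves over a common grid, in the time
  domain (closure, speed) or the closure domain (asymmetry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .exceptions import (
    KineticsError,
    LevelNotReachedError,
    NonMonotoneTraceError,
    WindowError,
)
from .geometry import FrameMetrics

__all__ = [
    "RingTrace",
    "KineticsSummary",
    "PopulationCurve",
    "crossing_time",
    "align_traces",
    "speed_series",
    "average_speed_20_80",
    "peak_speed",
    "kinetics_summary",
    "population_average",
    "asymmetry_at_closure",
]

#: traces whose smoothed closure drops by more than this many percentage
#: points are rejected as non-monotone rather than silently truncated
MONOTONE_GUARD_PCT = 5.0

DEFAULT_SMOOTH_WINDOW = 3


@dataclass(frozen=True)
class RingTrace:
    """One cell's division: times (minutes) and per-frame metrics.

    ``cell_label`` is free text, typically the stage ("3 VPC", "6 VPC",
    "12 VPC") or cell type.
    """

    trace_id: str
    times: tuple[float, ...]
    frames: tuple[FrameMetrics, ...]
    cell_label: str = ""

    def __post_init__(self) -> None:
        if len(self.times) != len(self.frames):
            raise KineticsError(
                f"trace {self.trace_id}: {len(self.times)} times vs "
                f"{len(self.frames)} frames"
            )
        if len(self.times) < 5:
            raise KineticsError(
                f"trace {self.trace_id}: needs >= 5 frames, got {len(self.times)}"
            )
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0))
            raise KineticsError(
                f"trace {self.trace_id}: times not strictly increasing at "
                f"index {bad + 1} (t={self.times[bad + 1]})"
            )

    @property
    def closure(self) -> np.ndarray:
        return np.array([f.closure_pct for f in self.frames])

    @property
    def asymmetry(self) -> np.ndarray:
        return np.array([f.asymmetry_pct for f in self.frames])

    @property
    def time_array(self) -> np.ndarray:
        return np.array(self.times)

    def shifted(self, dt: float) -> "RingTrace":
        return replace(self, times=tuple(t + dt for t in self.times))


@dataclass(frozen=True)
class KineticsSummary:
    """Scalar kinetics of one trace."""

    trace_id: str
    t_mid: float
    avg_speed_20_80: float
    endpoint_speed_20_80: float
    peak_speed: float
    closure_at_peak: float
    duration_10_90: float


@dataclass(frozen=True)
class PopulationCurve:
    """Per-grid-point mean ± SEM over a population of traces.

    ``low_n`` flags grid points supported by fewer than three traces.
    """

    grid: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    domain: str = "time"

    @property
    def low_n(self) -> np.ndarray:
        return self.n < 3


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; shrinking symmetric windows at the edges."""
    if window < 1 or window % 2 == 0:
        raise WindowError(f"smoothing window must be odd and >= 1, got {window}")
    if window > len(values):
        raise WindowError(
            f"smoothing window {window} exceeds trace length {len(values)}"
        )
    if window == 1:
        return values.astype(float)
    half = window // 2
    out = np.empty(len(values), dtype=float)
    for i in range(len(values)):
        k = min(half, i, len(values) - 1 - i)
        out[i] = values[i - k : i + k + 1].mean()
    return out


def _check_monotone(closure_sm: np.ndarray, trace_id: str) -> None:
    running_max = np.maximum.accumulate(closure_sm)
    drop = float(np.max(running_max - closure_sm))
    if drop > MONOTONE_GUARD_PCT:
        raise NonMonotoneTraceError(
            f"trace {trace_id}: smoothed closure drops {drop:.1f} points; "
            "not a monotone closure trace"
        )


def crossing_time(trace: RingTrace, level: float) -> float:
    """Time (min) of the first upward crossing of a closure level.

    Linear interpolation between the bracketing frames; an exact sample
    at the level returns that sample's time.
    """
    t = trace.time_array
    c = trace.closure
    at = np.nonzero(c == level)[0]
    up = np.nonzero((c[:-1] < level) & (c[1:] >= level))[0]
    first_at = at[0] if len(at) else np.inf
    first_up = up[0] + 1 if len(up) else np.inf
    if np.isinf(first_at) and np.isinf(first_up):
        raise LevelNotReachedError(
            f"trace {trace.trace_id}: closure never crosses {level}% "
            f"(max {c.max():.1f}%)"
        )
    if first_at <= first_up:
        return float(t[int(first_at)])
    i = int(first_up)
    frac = (level - c[i - 1]) / (c[i] - c[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def align_traces(traces: Sequence[RingTrace]) -> list[RingTrace]:
    """Shift each trace in time so its 50%-closure crossing sits at t = 0.

    This is the midpoint alignment applied before population averaging;
    order and frame spacing are preserved, so the operation is idempotent.
    """
    return [tr.shifted(-crossing_time(tr, 50.0)) for tr in traces]


def speed_series(
    trace: RingTrace, smooth_window: int = DEFAULT_SMOOTH_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """Closure speed over time (%/min) by finite differences.

    Closure is moving-average smoothed (odd window, default 3 frames to
    suppress 30-s annotation jitter), then differentiated: central
    differences in the interior, one-sided at the endpoints.

    Returns ``(times, speeds)``.
    """
    if len(trace.times) < 3:
        raise KineticsError(
            f"trace {trace.trace_id}: speed needs >= 3 frames"
        )
    t = trace.time_array
    c = _moving_average(trace.closure, smooth_window)
    speeds = np.gradient(c, t)
    return t, speeds


def average_speed_20_80(trace: RingTrace) -> float:
    """Average furrowing speed between 20% and 80% closure (%/min).

    OLS slope of closure vs time over frames with closure in [20, 80],
    with the interpolated 20% and 80% crossing points appended as virtual
    samples so sparse traces are anchored at the window edges.
    """
    t20 = crossing_time(trace, 20.0)
    t80 = crossing_time(trace, 80.0)
    t = trace.time_array
    c = trace.closure
    inside = (c >= 20.0) & (c <= 80.0) & (t >= t20) & (t <= t80)
    ts = np.concatenate([[t20], t[inside], [t80]])
    cs = np.concatenate([[20.0], c[inside], [80.0]])
    order = np.argsort(ts)
    ts, cs = ts[order], cs[order]
    # OLS slope; >= 2 distinct abscissae guaranteed since t80 > t20
    slope = np.polyfit(ts, cs, 1)[0]
    return float(slope)


def endpoint_speed_20_80(trace: RingTrace) -> float:
    """Endpoint-difference speed, 60 points / (t80 - t20), in %/min."""
    t20 = crossing_time(trace, 20.0)
    t80 = crossing_time(trace, 80.0)
    return 60.0 / (t80 - t20)


def peak_speed(
    trace: RingTrace, smooth_window: int = DEFAULT_SMOOTH_WINDOW
) -> tuple[float, float]:
    """Maximum of the smoothed speed series and the closure there.

    Returns ``(speed %/min, closure_at_peak %)``.  For a symmetric
    sigmoid the peak sits at half closure.
    """
    _, speeds = speed_series(trace, smooth_window)
    i = int(np.argmax(speeds))
    return float(speeds[i]), float(trace.closure[i])


def kinetics_summary(
    trace: RingTrace, smooth_window: int = DEFAULT_SMOOTH_WINDOW
) -> KineticsSummary:
    """Bundle the scalar kinetics of one trace.

    Requires the trace to span 10–90% closure; rejects non-monotone
    traces (smoothed closure dropping > 5 points).
    """
    _check_monotone(_moving_average(trace.closure, smooth_window), trace.trace_id)
    pk, c_at_pk = peak_speed(trace, smooth_window)
    return KineticsSummary(
        trace_id=trace.trace_id,
        t_mid=crossing_time(trace, 50.0),
        avg_speed_20_80=average_speed_20_80(trace),
        endpoint_speed_20_80=endpoint_speed_20_80(trace),
        peak_speed=pk,
        closure_at_peak=c_at_pk,
        duration_10_90=crossing_time(trace, 90.0) - crossing_time(trace, 10.0),
    )


def _trace_xy(
    trace: RingTrace,
    value: str,
    smooth_window: int,
) -> tuple[np.ndarray, np.ndarray]:
    if value == "closure":
        return trace.time_array, trace.closure
    if value == "speed":
        return speed_series(trace, smooth_window)
    if value == "asymmetry":
        # closure-domain curve: asymmetry as a function of % closure
        c = trace.closure
        a = trace.asymmetry
        order = np.argsort(c)
        return c[order], a[order]
    raise KineticsError(f"unknown population value {value!r}")


def population_average(
    traces: Sequence[RingTrace],
    value: Literal["closure", "speed", "asymmetry"] = "closure",
    grid_dt: float | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    align: bool = True,
) -> PopulationCurve:
    """Mean ± SEM curve over a population of traces.

    Time-domain curves (``closure``, ``speed``) are midpoint-aligned
    first and sampled on a common grid (default 0.5 min); the asymmetry
    curve uses percent closure as abscissa (grid 0–100%, default 2%).
    Each trace contributes by linear interpolation only inside its own
    domain; ``n`` reports per-point trace counts and SEM = sd/√n.
    """
    if not traces:
        raise KineticsError("population_average needs at least one trace")
    if value == "asymmetry":
        dt = 2.0 if grid_dt is None else grid_dt
        xys = [_trace_xy(tr, value, smooth_window) for tr in traces]
        grid = np.arange(0.0, 100.0 + dt / 2, dt)
        domain = "closure"
    else:
        dt = 0.5 if grid_dt is None else grid_dt
        use = align_traces(traces) if align else list(traces)
        xys = [_trace_xy(tr, value, smooth_window) for tr in use]
        lo = min(x.min() for x, _ in xys)
        hi = max(x.max() for x, _ in xys)
        grid = np.arange(np.floor(lo / dt) * dt, hi + dt / 2, dt)
        domain = "time"

    stack = np.full((len(xys), len(grid)), np.nan)
    for row, (x, y) in zip(stack, xys):
        inside = (grid >= x.min()) & (grid <= x.max())
        row[inside] = np.interp(grid[inside], x, y)

    n = np.sum(~np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        # grid points supported by no / one trace are filtered below
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    keep = n >= 1
    return PopulationCurve(
        grid=grid[keep], mean=mean[keep], sem=sem[keep], n=n[keep], domain=domain
    )


def asymmetry_at_closure(trace: RingTrace, level: float) -> float:
    """Asymmetry (%) linearly interpolated at a closure level.

    This is the quantity compared across stages at 80% closed.
    """
    t_cross = crossing_time(trace, level)
    t = trace.time_array
    a = trace.asymmetry
    return float(np.interp(t_cross, t, a))
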