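"""Model/Results interface over the analysis pipeline.

Two model classes mirror the two questions the analysis answers:

* :class:`ClosureKinetics` — built from annotated traces, its
  :meth:`~ClosureKinetics.fit` quantifies every frame (circle fits,
  closure, asymmetry), summarizes per-trace kinetics, fits a logistic
  closure law per trace, and assembles midpoint-aligned population
  curves.  The returned :class:`ClosureKineticsResults` carries the
  estimates with their uncertainties and renders a summary table.
* :class:`ScalingRegression` — an OLS scaling line (ring breadth vs cell
  length, or furrowing speed vs division-plane perimeter) with standard
  errors and R², optionally pooling user-supplied external reference
  points into the joint fit.

Simulation hangs off the model (:meth:`ClosureKinetics.simulate`) and
plotting off the results objects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import geometry, kinetics, morphometrics
from .exceptions import FurrowError, KineticsError
from .geometry import AnnotatedFrame
from .kinetics import KineticsSummary, PopulationCurve, RingTrace
from .simulate import ClosureModel, logistic_closure, simulate_trace

__all__ = [
    "quantify_trace",
    "LogisticFit",
    "ClosureKinetics",
    "ClosureKineticsResults",
    "ScalingRegression",
    "ScalingRegressionResults",
]

logger = logging.getLogger(__name__)


def quantify_trace(
    trace_id: str,
    frames: Sequence[AnnotatedFrame],
    cell_label: str = "",
    min_frames: int = 5,
) -> RingTrace:
    """Run the geometry stage over one trace's annotated frames.

    Frame times are converted from seconds to minutes.  Frames whose
    annotations are degenerate (collinear points, ring outside the cell
    beyond tolerance) are logged and skipped rather than failing the
    trace; the trace fails only if fewer than ``min_frames`` frames
    survive.
    """
    times: list[float] = []
    metrics: list[geometry.FrameMetrics] = []
    for i, frame in enumerate(frames):
        try:
            m = geometry.frame_metrics(frame, index=i)
        except FurrowError as exc:
            logger.warning("trace %s: skipping frame %d: %s", trace_id, i, exc)
            continue
        times.append(frame.time / 60.0)
        metrics.append(m)
    if len(times) < min_frames:
        raise KineticsError(
            f"trace {trace_id}: only {len(times)} of {len(frames)} frames "
            f"quantifiable (need >= {min_frames})"
        )
    return RingTrace(
        trace_id=trace_id,
        times=tuple(times),
        frames=tuple(metrics),
        cell_label=cell_label,
    )


@dataclass(frozen=True)
class LogisticFit:
    """Least-squares logistic closure fit c(t) = 100/(1+exp(-k(t-t0)))."""

    k: float
    t0: float
    k_se: float
    t0_se: float
    rss: float

    @property
    def peak_speed(self) -> float:
        """Analytic peak of the fitted law, 25 k %/min."""
        return 25.0 * self.k


def fit_logistic(trace: RingTrace) -> LogisticFit:
    """Fit the logistic closure law to one trace by least squares."""
    t = trace.time_array
    c = trace.closure
    t_mid = kinetics.crossing_time(trace, 50.0)
    k0 = 4.0 * max(np.max(np.gradient(c, t)), 1e-3) / 100.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(
            lambda tt, k, t0: logistic_closure(tt, k, t0),
            t, c, p0=[k0, t_mid], maxfev=10000,
        )
    resid = c - logistic_closure(t, *popt)
    ses = np.sqrt(np.diag(pcov))
    return LogisticFit(
        k=float(popt[0]), t0=float(popt[1]),
        k_se=float(ses[0]), t0_se=float(ses[1]),
        rss=float(np.sum(resid**2)),
    )


class ClosureKinetics:
    """Ring-closure kinetics model over a set of annotated traces.

    Parameters
    ----------
    annotations
        Mapping of trace id to the trace's annotated frames, or a list of
        already-quantified :class:`RingTrace` objects.
    smooth_window
        Odd moving-average window (frames) applied before
        differentiation; default 3.
    """

    def __init__(
        self,
        annotations: dict[str, Sequence[AnnotatedFrame]] | Sequence[RingTrace],
        smooth_window: int = kinetics.DEFAULT_SMOOTH_WINDOW,
        labels: dict[str, str] | None = None,
    ) -> None:
        if isinstance(annotations, dict):
            labels = labels or {}
            self.traces = [
                quantify_trace(tid, frames, cell_label=labels.get(tid, ""))
                for tid, frames in annotations.items()
            ]
        else:
            self.traces = list(annotations)
        if not self.traces:
            raise KineticsError("model needs at least one trace")
        self.smooth_window = smooth_window

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, smooth_window: int = kinetics.DEFAULT_SMOOTH_WINDOW
    ) -> "ClosureKinetics":
        """Build from a long-form per-frame metrics table.

        Expects columns ``trace_id, time_min, closure_pct, asymmetry_pct``
        and optionally per-frame circle columns; intended for re-loading
        previously quantified traces.
        """
        traces = []
        for tid, group in df.groupby("trace_id", sort=False):
            frames = tuple(
                geometry.FrameMetrics(
                    closure_pct=row.closure_pct,
                    asymmetry_pct=row.asymmetry_pct,
                    apical_displacement=getattr(row, "apical_displacement_um", 0.0),
                    cell=geometry.CircleFit(
                        geometry.Point2D(0.0, 0.0), getattr(row, "R_um", 1.0)
                    ),
                    ring=geometry.CircleFit(
                        geometry.Point2D(0.0, 0.0),
                        max(getattr(row, "r_um", 1.0), 1e-9),
                    ),
                )
                for row in group.itertuples()
            )
            traces.append(
                RingTrace(
                    trace_id=str(tid),
                    times=tuple(group["time_min"]),
                    frames=frames,
                    cell_label=str(group["cell_label"].iloc[0])
                    if "cell_label" in group else "",
                )
            )
        return cls(traces, smooth_window=smooth_window)

    @staticmethod
    def simulate(models: Sequence[ClosureModel]) -> "ClosureKinetics":
        """Simulate annotated traces from generator models and wrap them."""
        annotations = {}
        for i, m in enumerate(models):
            _, frames = simulate_trace(m)
            annotations[f"sim_{i:03d}"] = frames
        return ClosureKinetics(annotations)

    def fit(self, logistic: bool = True) -> "ClosureKineticsResults":
        """Estimate kinetics for every trace and the population.

        Computes per-trace summaries (midpoint, 20–80% speed, peak speed
        and closure at peak, 10–90% duration), optional logistic fits,
        and midpoint-aligned population mean ± SEM curves for closure,
        speed and asymmetry-vs-closure.

        Traces the kinetics layer rejects — e.g. the monotonicity guard
        firing on a wild annotation outlier, or the trace never spanning
        10–90% closure — are logged, recorded on the results object and
        dropped, mirroring the pipeline's per-trace failure contract;
        the fit fails only when no trace survives.
        """
        kept: list[RingTrace] = []
        summaries: list[KineticsSummary] = []
        failed: dict[str, str] = {}
        for tr in self.traces:
            try:
                summaries.append(kinetics.kinetics_summary(tr, self.smooth_window))
            except KineticsError as exc:
                logger.warning("dropping trace %s: %s", tr.trace_id, exc)
                failed[tr.trace_id] = str(exc)
                continue
            kept.append(tr)
        if not kept:
            raise KineticsError("no trace passed the kinetics guards")
        logi = [fit_logistic(tr) for tr in kept] if logistic else None
        curves = {
            "closure": kinetics.population_average(
                kept, "closure", smooth_window=self.smooth_window
            ),
            "speed": kinetics.population_average(
                kept, "speed", smooth_window=self.smooth_window
            ),
            "asymmetry": kinetics.population_average(
                kept, "asymmetry", smooth_window=self.smooth_window
            ),
        }
        return ClosureKineticsResults(self, summaries, logi, curves,
                                      traces=kept, failed=failed)


class ClosureKineticsResults:
    """Fitted kinetics: per-trace summaries, logistic fits, population
    curves; renders a summary table and plots."""

    def __init__(
        self,
        model: ClosureKinetics,
        summaries: list[KineticsSummary],
        logistic_fits: list[LogisticFit] | None,
        curves: dict[str, PopulationCurve],
        traces: list[RingTrace] | None = None,
        failed: dict[str, str] | None = None,
    ) -> None:
        self.model = model
        self.summaries = summaries
        self.logistic_fits = logistic_fits
        self.curves = curves
        self.traces = list(model.traces) if traces is None else traces
        self.failed = failed or {}

    @property
    def summary_frame(self) -> pd.DataFrame:
        """One row per trace with all scalar kinetics."""
        rows = []
        for i, s in enumerate(self.summaries):
            row = {
                "trace_id": s.trace_id,
                "cell_label": self.traces[i].cell_label,
                "t_mid_min": s.t_mid,
                "avg_speed_20_80_pct_per_min": s.avg_speed_20_80,
                "endpoint_speed_20_80_pct_per_min": s.endpoint_speed_20_80,
                "peak_speed_pct_per_min": s.peak_speed,
                "closure_at_peak_pct": s.closure_at_peak,
                "duration_10_90_min": s.duration_10_90,
            }
            if self.logistic_fits is not None:
                lf = self.logistic_fits[i]
                row.update(
                    logistic_k_per_min=lf.k, logistic_k_se=lf.k_se,
                    logistic_t0_min=lf.t0, logistic_t0_se=lf.t0_se,
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def asymmetry_closure_slope(self) -> morphometrics.ScalingFit:
        """OLS slope of asymmetry vs closure pooled over all frames.

        Under apically polarized drift this slope estimates the drift
        fraction (asymmetry ≈ alpha × closure).
        """
        closure = np.concatenate([tr.closure for tr in self.traces])
        asym = np.concatenate([tr.asymmetry for tr in self.traces])
        return morphometrics.linear_scaling_fit(closure, asym)

    def asymmetry_at(self, level: float = 80.0) -> np.ndarray:
        """Per-trace asymmetry interpolated at a closure level (default 80%)."""
        return np.array(
            [kinetics.asymmetry_at_closure(tr, level) for tr in self.traces]
        )

    def summary(self) -> str:
        """Human-readable summary of the population kinetics."""
        df = self.summary_frame
        n = len(df)
        lines = [
            "Ring closure kinetics",
            "=" * 53,
            f"traces: {n}",
            f"t_mid (min):            {df.t_mid_min.mean():8.3f} "
            f"± {df.t_mid_min.sem():.3f} (SEM)",
            f"speed 20-80% (%/min):   "
            f"{df.avg_speed_20_80_pct_per_min.mean():8.3f} "
            f"± {df.avg_speed_20_80_pct_per_min.sem():.3f}",
            f"peak speed (%/min):     {df.peak_speed_pct_per_min.mean():8.3f} "
            f"± {df.peak_speed_pct_per_min.sem():.3f}",
            f"closure at peak (%):    {df.closure_at_peak_pct.mean():8.3f} "
            f"± {df.closure_at_peak_pct.sem():.3f}",
            f"duration 10-90% (min):  {df.duration_10_90_min.mean():8.3f} "
            f"± {df.duration_10_90_min.sem():.3f}",
        ]
        if self.logistic_fits is not None:
            lines.append(
                f"logistic k (1/min):     {df.logistic_k_per_min.mean():8.3f} "
                f"± {df.logistic_k_per_min.sem():.3f}"
            )
        slope = self.asymmetry_closure_slope()
        lines.append(
            f"asymmetry/closure slope: {slope.slope:7.3f} ± {slope.slope_se:.3f}"
        )
        return "\n".join(lines)

    def plot(self, which: str = "closure", ax=None):
        """Plot a population curve (``closure``, ``speed`` or
        ``asymmetry``) as mean ± SEM."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.curves[which]
        ax.errorbar(curve.grid, curve.mean, yerr=curve.sem, fmt="-", capsize=2)
        xlabel = ("time from midpoint (min)" if curve.domain == "time"
                  else "ring closure (%)")
        ylabel = {"closure": "ring closure (%)",
                  "speed": "closure speed (%/min)",
                  "asymmetry": "asymmetry (%)"}[which]
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        return ax


class ScalingRegression:
    """OLS scaling line between two measured quantities.

    Optionally pools external reference points — e.g. published speed /
    division-plane-perimeter pairs from other cell types — with the
    measured points before fitting, for joint cross-cell-type scaling.
    """

    def __init__(
        self,
        x: Sequence[float],
        y: Sequence[float],
        xname: str = "x",
        yname: str = "y",
    ) -> None:
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.xname = xname
        self.yname = yname

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, x: str, y: str
    ) -> "ScalingRegression":
        return cls(df[x].to_numpy(), df[y].to_numpy(), xname=x, yname=y)

    def with_reference_points(
        self, x: Sequence[float], y: Sequence[float]
    ) -> "ScalingRegression":
        """Return a new model with external reference points appended."""
        return ScalingRegression(
            np.concatenate([self.x, np.asarray(x, dtype=float)]),
            np.concatenate([self.y, np.asarray(y, dtype=float)]),
            xname=self.xname, yname=self.yname,
        )

    def fit(self) -> "ScalingRegressionResults":
        fit = morphometrics.linear_scaling_fit(self.x, self.y)
        return ScalingRegressionResults(self, fit)


class ScalingRegressionResults:
    """Fitted scaling line with standard errors and R²."""

    def __init__(self, model: ScalingRegression, fit: morphometrics.ScalingFit
                 ) -> None:
        self.model = model
        self.fit_ = fit

    @property
    def slope(self) -> float:
        return self.fit_.slope

    @property
    def intercept(self) -> float:
        return self.fit_.intercept

    @property
    def r_squared(self) -> float:
        return self.fit_.r_squared

    def predict(self, x: Sequence[float]) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def summary(self) -> str:
        f = self.fit_
        return (
            f"{self.model.yname} = {f.slope:.4g} * {self.model.xname} "
            f"+ {f.intercept:.4g}\n"
            f"slope SE {f.slope_se:.3g}, intercept SE {f.intercept_se:.3g}, "
            f"R² = {f.r_squared:.4f}, n = {f.n_points}"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.x, self.model.y)
        xs = np.linspace(self.model.x.min(), self.model.x.max(), 50)
        ax.plot(xs, self.predict(xs))
        ax.set_xlabel(self.model.xname)
        ax.set_ylabel(self.model.yname)
        return ax
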