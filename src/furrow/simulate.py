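"""Ground-truth generators for ring-closure traces, cell populations and
division-plane image stacks.

The generators produce data with the statistical structure the analysis
assumes, so every pipeline stage can be validated against known truth:

* **Closure traces** follow a logistic law — the minimal symmetric
  sigmoid matching the observed acceleration-then-deceleration of ring
  closure — with the ring center drifting toward the apical side as it
  constricts (``d = alpha * (R0 - r)``, giving asymmetry = alpha ×
  closure).  Annotations are three points per circle at fixed,
  well-conditioned angles, plus isotropic Gaussian jitter.
* **Cell populations** emulate reductional epithelial divisions: stage
  mean lengths halve each round while height and thickness stay roughly
  constant, and ring breadth follows a planted line in cell length.
* **Image stacks** render the division-plane (z, x) view as an annulus
  with a Gaussian radial profile over a flat background plus noise, for
  kymograph and intensity-measurement validation.

These laws are synthetic stand-ins chosen for analytic tractability, not
mechanistic models; every generator is a pure function of its model
parameters including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SimulationError
from .geometry import AnnotatedFrame, Point2D

__all__ = [
    "ClosureModel",
    "PopulationModel",
    "StageSpec",
    "ImageModel",
    "TraceGroundTruth",
    "logistic_closure",
    "simulate_trace",
    "simulate_population",
    "render_division_plane_movie",
    "make_kymograph",
]

# annotation angles (degrees): interleaved triples give well-conditioned
# circumcircles for both the cell outline and the ring
CELL_ANGLES_DEG = (90.0, 210.0, 330.0)
RING_ANGLES_DEG = (30.0, 150.0, 270.0)


@dataclass(frozen=True)
class ClosureModel:
    """Parameters of one simulated ring-closure trace.

    k
        logistic rate (1/min); the peak closure speed is 25·k %/min.
    t0
        midpoint of closure (min).
    R0
        initial cell radius in the division plane (µm).
    alpha
        apical drift fraction in [0, 1]; the ring center is displaced
        ``alpha * (R0 - r)`` toward the apical side, so the measured
        asymmetry equals ``alpha`` × closure.
    dt
        sampling interval (min); 0.5 corresponds to 30-s frames.
    jitter_sigma_um
        isotropic Gaussian annotation jitter per point coordinate (µm).
    closure_span
        simulated closure range (%); the time window is derived from it.
        The default upper bound of 95% keeps the ring diameter above the
        optical resolution limit (~0.25 µm at R0 = 2.5 µm) — annotation
        of a sub-resolution ring is not physically meaningful.
    """

    k: float = 0.72
    t0: float = 5.0
    R0: float = 2.5
    alpha: float = 0.4
    dt: float = 0.5
    jitter_sigma_um: float = 0.0
    seed: int = 0
    apical_axis: Point2D = field(default=Point2D(0.0, 1.0))
    closure_span: tuple[float, float] = (1.0, 95.0)

    def __post_init__(self) -> None:
        if self.k <= 0 or self.dt <= 0 or self.R0 <= 0:
            raise SimulationError("k, dt and R0 must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise SimulationError(f"alpha must lie in [0,1], got {self.alpha}")
        if self.jitter_sigma_um < 0:
            raise SimulationError("jitter sigma must be non-negative")


@dataclass(frozen=True)
class TraceGroundTruth:
    """The generating quantities behind one simulated trace (times in min)."""

    times_min: np.ndarray
    closure_pct: np.ndarray
    ring_radius_um: np.ndarray
    asymmetry_pct: np.ndarray
    cell_center: Point2D
    cell_radius_um: float
    ring_centers: np.ndarray  # (n, 2)


def logistic_closure(t: np.ndarray, k: float, t0: float) -> np.ndarray:
    """Logistic closure law c(t) = 100 / (1 + exp(-k (t - t0))) in percent."""
    return 100.0 / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - t0)))


def _closure_times(model: ClosureModel) -> np.ndarray:
    lo, hi = model.closure_span
    if not 0.0 < lo < hi < 100.0:
        raise SimulationError(f"closure span must satisfy 0 < lo < hi < 100")
    # invert the logistic at the span edges, then sample on the dt grid
    t_lo = model.t0 + math.log(lo / (100.0 - lo)) / model.k
    t_hi = model.t0 + math.log(hi / (100.0 - hi)) / model.k
    start = max(0.0, t_lo)
    n = int(math.floor((t_hi - start) / model.dt)) + 1
    return start + model.dt * np.arange(n)


def simulate_trace(
    model: ClosureModel,
) -> tuple[TraceGroundTruth, list[AnnotatedFrame]]:
    """Simulate one dividing cell: ground truth plus annotated frames.

    The cell circle is fixed (center at the origin, radius ``R0``); the
    ring radius follows ``r(t) = R0 (1 - c(t)/100)`` with logistic
    closure ``c``, and the ring center drifts apically by
    ``alpha (R0 - r)``.  Annotation points sit at fixed angles on each
    circle with optional Gaussian jitter; identical seeds give identical
    output.  Frame times are emitted in seconds, matching the annotation
    file convention.
    """
    rng = np.random.default_rng(model.seed)
    t_min = _closure_times(model)
    closure = logistic_closure(t_min, model.k, model.t0)
    r = model.R0 * (1.0 - closure / 100.0)
    drift = model.alpha * (model.R0 - r)
    ax, ay = model.apical_axis.x, model.apical_axis.y
    centers = np.column_stack([drift * ax, drift * ay])

    frames: list[AnnotatedFrame] = []
    cell_angles = np.deg2rad(CELL_ANGLES_DEG)
    ring_angles = np.deg2rad(RING_ANGLES_DEG)
    for i, t in enumerate(t_min):
        cell_pts = np.column_stack(
            [model.R0 * np.cos(cell_angles), model.R0 * np.sin(cell_angles)]
        )
        ring_pts = centers[i] + np.column_stack(
            [r[i] * np.cos(ring_angles), r[i] * np.sin(ring_angles)]
        )
        if model.jitter_sigma_um > 0:
            cell_pts = cell_pts + rng.normal(0, model.jitter_sigma_um, (3, 2))
            ring_pts = ring_pts + rng.normal(0, model.jitter_sigma_um, (3, 2))
        frames.append(
            AnnotatedFrame(
                time=float(t * 60.0),
                cell_points=tuple(Point2D(float(x), float(y)) for x, y in cell_pts),
                ring_points=tuple(Point2D(float(x), float(y)) for x, y in ring_pts),
                apical_axis=model.apical_axis,
            )
        )
    truth = TraceGroundTruth(
        times_min=t_min,
        closure_pct=closure,
        ring_radius_um=r,
        asymmetry_pct=100.0 * drift / model.R0,
        cell_center=Point2D(0.0, 0.0),
        cell_radius_um=model.R0,
        ring_centers=centers,
    )
    return truth, frames


@dataclass(frozen=True)
class StageSpec:
    """One division stage of a simulated population."""

    label: str
    n_cells: int
    mean_length: float
    mean_height: float
    mean_thickness: float


@dataclass(frozen=True)
class PopulationModel:
    """Parameters of a simulated multi-stage cell population.

    With ``halving`` set, successive stage mean lengths are forced to
    halve (heights and thicknesses stay at their stated means), emulating
    reductional epithelial divisions.  Ring breadths follow the planted
    line ``breadth = slope * length + intercept`` plus Gaussian noise.
    """

    stages: tuple[StageSpec, ...]
    length_cv: float = 0.1
    dim_cv: float = 0.05
    halving: bool = True
    breadth_slope: float = 0.16
    breadth_intercept: float = 0.3
    breadth_sigma: float = 0.1
    z_step: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise SimulationError("population needs at least one stage")
        for s in self.stages:
            if min(s.mean_length, s.mean_height, s.mean_thickness) <= 0:
                raise SimulationError(f"stage {s.label}: non-positive dimensions")
            if s.n_cells < 1:
                raise SimulationError(f"stage {s.label}: n_cells must be >= 1")
        if self.length_cv < 0 or self.dim_cv < 0 or self.breadth_sigma < 0:
            raise SimulationError("noise parameters must be non-negative")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int
               ) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def simulate_population(model: PopulationModel) -> pd.DataFrame:
    """Simulate a table of cells across division stages.

    Returns a DataFrame with one row per cell: stage, length, height,
    z-step count, thickness, volume, and apical/basal ring breadths from
    the planted breadth-vs-length line.  Reproducible by seed.
    """
    rng = np.random.default_rng(model.seed)
    rows = []
    for si, stage in enumerate(model.stages):
        mean_len = (
            model.stages[0].mean_length / 2.0**si if model.halving
            else stage.mean_length
        )
        lengths = _lognormal(rng, mean_len, model.length_cv, stage.n_cells)
        heights = _lognormal(rng, stage.mean_height, model.dim_cv, stage.n_cells)
        thicks = _lognormal(rng, stage.mean_thickness, model.dim_cv, stage.n_cells)
        n_zsteps = np.maximum(1, np.rint(thicks / model.z_step).astype(int))
        line = model.breadth_slope * lengths + model.breadth_intercept
        noise_a = rng.normal(0, model.breadth_sigma, stage.n_cells)
        noise_b = rng.normal(0, model.breadth_sigma, stage.n_cells)
        apical = np.clip(line + noise_a, 0.0, lengths)
        basal = np.clip(line + noise_b, 0.0, lengths)
        for j in range(stage.n_cells):
            thickness = n_zsteps[j] * model.z_step
            rows.append(
                {
                    "cell_id": f"{stage.label}_{j:03d}",
                    "stage": stage.label,
                    "length_um": lengths[j],
                    "height_um": heights[j],
                    "n_zsteps": int(n_zsteps[j]),
                    "z_step_um": model.z_step,
                    "thickness_um": thickness,
                    "volume_um3": lengths[j] * heights[j] * thickness,
                    "apical_breadth_um": apical[j],
                    "basal_breadth_um": basal[j],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ImageModel:
    """Rendering parameters for synthetic division-plane movies."""

    voxel_size_um: float = 0.1
    shape: tuple[int, int] = (64, 64)  # (ny, nx) pixels
    sigma_r_um: float = 0.15
    ring_intensity: float = 300.0
    background: float = 100.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise SimulationError("voxel size must be positive")
        if self.ring_intensity < 0 or self.background < 0:
            raise SimulationError("intensities must be non-negative")


def render_division_plane_movie(
    ring_radii_um: np.ndarray,
    ring_centers_um: np.ndarray,
    model: ImageModel,
) -> np.ndarray:
    """Render a (t, y, x) stack of an annulus constricting over time.

    Each frame is ``background + ring_intensity * exp(-(rho - r)^2 /
    (2 sigma_r^2))`` with ``rho`` the distance to the ring center, plus
    optional Gaussian noise.  Centers are in µm relative to the frame
    center.  Rings extending outside the frame raise an error.
    """
    rng = np.random.default_rng(model.seed)
    ring_radii_um = np.asarray(ring_radii_um, dtype=float)
    ring_centers_um = np.asarray(ring_centers_um, dtype=float)
    ny, nx = model.shape
    # pixel-center coordinates in µm, origin at the frame center
    ys = (np.arange(ny) - (ny - 1) / 2.0) * model.voxel_size_um
    xs = (np.arange(nx) - (nx - 1) / 2.0) * model.voxel_size_um
    yy, xx = np.meshgrid(ys, xs, indexing="ij")

    half_y = ys[-1]
    half_x = xs[-1]
    stack = np.empty((len(ring_radii_um), ny, nx), dtype=float)
    for i, (r, (cx, cy)) in enumerate(zip(ring_radii_um, ring_centers_um)):
        if abs(cy) + r > half_y or abs(cx) + r > half_x:
            raise SimulationError(
                f"frame {i}: ring (r={r:.2f} µm at ({cx:.2f},{cy:.2f})) "
                "extends outside the frame"
            )
        rho = np.hypot(xx - cx, yy - cy)
        frame = model.background + model.ring_intensity * np.exp(
            -((rho - r) ** 2) / (2.0 * model.sigma_r_um**2)
        )
        if model.noise_sigma > 0:
            frame = frame + rng.normal(0, model.noise_sigma, frame.shape)
        stack[i] = frame
    return stack


def make_kymograph(
    stack: np.ndarray,
    axis: str = "horizontal",
    strip_halfwidth: int | None = None,
) -> np.ndarray:
    """Kymograph: per-frame maximum projection stacked over time.

    ``axis="horizontal"`` projects along x (rows keep the y position),
    ``axis="vertical"`` projects along y.  Output shape is
    ``(positions, time)``.

    With ``strip_halfwidth`` set, only a strip of ``2*strip_halfwidth+1``
    pixels centered on the projected axis is projected — the classic
    furrow kymograph, in which the ring's two edges appear as bright
    bands 2r apart that converge as the ring closes.  The default (full
    projection) instead yields a top-hat band spanning the ring
    diameter, since every line crossing the annulus reaches peak
    intensity somewhere.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise SimulationError("kymograph needs a non-empty (t, y, x) stack")
    if axis == "horizontal":
        proj_axis, size = 2, stack.shape[2]
    elif axis == "vertical":
        proj_axis, size = 1, stack.shape[1]
    else:
        raise SimulationError(f"unknown projection axis {axis!r}")
    if strip_halfwidth is not None:
        mid = size // 2
        lo = max(0, mid - strip_halfwidth)
        hi = min(size, mid + strip_halfwidth + 1)
        stack = stack[:, :, lo:hi] if proj_axis == 2 else stack[:, lo:hi, :]
    return stack.max(axis=proj_axis).T
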