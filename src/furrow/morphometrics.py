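"""Cell dimensions, ring breadth and scaling regressions.

Cells are measured as boxes: length (anterior–posterior) × height
(apical–basal) × thickness, where thickness is the number of occupied
0.6 µm z steps.  Contractile-ring breadth — how much of the cell's long
axis the equatorial myosin band occupies — is extracted from intensity
profiles along the apical and basal margins and averaged over the first
five timepoints with detectable enrichment.  Scaling relationships
(breadth vs cell length; furrowing speed vs division-plane perimeter)
are ordinary least-squares lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import MorphometricsError, NoEnrichmentError, ProfileTooShortError

__all__ = [
    "CellDimensions",
    "BreadthMeasurement",
    "ScalingFit",
    "cell_volume",
    "tissue_length",
    "ring_breadth",
    "breadth_time_average",
    "linear_scaling_fit",
    "division_plane_perimeter",
    "region_mean_intensity",
]

DEFAULT_Z_STEP_UM = 0.6
#: enrichment threshold in baseline SDs ("higher shades of grey" operationalized)
DEFAULT_ENRICHMENT_K = 2.0
#: number of earliest detected timepoints averaged for breadth
BREADTH_N_TIMEPOINTS = 5


@dataclass(frozen=True)
class CellDimensions:
    """Box-model cell dimensions in µm; volume = length·height·thickness."""

    cell_id: str
    length: float
    height: float
    n_zsteps: int
    z_step: float = DEFAULT_Z_STEP_UM
    stage: str = ""

    def __post_init__(self) -> None:
        if min(self.length, self.height, self.z_step) <= 0 or self.n_zsteps <= 0:
            raise MorphometricsError(
                f"cell {self.cell_id}: dimensions must be positive"
            )

    @property
    def thickness(self) -> float:
        return self.n_zsteps * self.z_step

    @property
    def volume(self) -> float:
        return self.length * self.height * self.thickness


@dataclass(frozen=True)
class BreadthMeasurement:
    """Apical and basal ring breadths (µm) for one cell, averaged over the
    first detected timepoints."""

    apical_breadth: float
    basal_breadth: float
    n_timepoints_averaged: int
    cell_length: float

    def __post_init__(self) -> None:
        if self.n_timepoints_averaged < 1:
            raise MorphometricsError("breadth must average >= 1 timepoint")
        for b in (self.apical_breadth, self.basal_breadth):
            if b < 0 or b > self.cell_length:
                raise MorphometricsError(
                    f"breadth {b} µm outside [0, cell length {self.cell_length} µm]"
                )


@dataclass(frozen=True)
class ScalingFit:
    """OLS line y = slope·x + intercept with standard errors and R²."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    slope_se: float
    intercept_se: float


def cell_volume(
    length: float, height: float, n_zsteps: int, z_step: float = DEFAULT_Z_STEP_UM
) -> float:
    """Box-model volume (µm³): length × height × (n z-steps × step size)."""
    if min(length, height, z_step) <= 0 or n_zsteps <= 0:
        raise MorphometricsError("cell dimensions must be positive")
    return length * height * n_zsteps * z_step


def tissue_length(cells: Sequence[CellDimensions]) -> float:
    """Longitudinal extent of a contiguous run of cells (µm).

    The summed lengths of a row of epithelial cells; conserved across
    reductional division rounds since daughters tile the mother's span.
    """
    if not cells:
        raise MorphometricsError("tissue_length needs at least one cell")
    return float(sum(c.length for c in cells))


def ring_breadth(
    positions: np.ndarray,
    intensities: np.ndarray,
    enrichment_k: float = DEFAULT_ENRICHMENT_K,
) -> tuple[float, bool]:
    """Breadth (µm) of the equatorial enrichment in an intensity profile.

    The profile runs along the cell's long axis.  The baseline is the
    profile outside the central 50% of the cell (the outer quarters,
    where the ring cannot be); positions whose intensity exceeds
    baseline mean + ``enrichment_k``·SD are enriched, and the breadth is
    the extent of the maximal contiguous enriched run.

    Returns ``(breadth_um, detected)``; ``(0.0, False)`` when no position
    clears the threshold.
    """
    positions = np.asarray(positions, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if len(positions) != len(intensities):
        raise MorphometricsError("positions and intensities differ in length")
    if len(positions) < 20:
        raise ProfileTooShortError(
            f"profile has {len(positions)} samples, needs >= 20"
        )
    lo, hi = positions.min(), positions.max()
    span = hi - lo
    central = (positions > lo + 0.25 * span) & (positions < hi - 0.25 * span)
    baseline = intensities[~central]
    base_mean = baseline.mean()
    base_sd = baseline.std(ddof=1)
    threshold = base_mean + enrichment_k * base_sd

    enriched = intensities > threshold
    if not enriched.any():
        return 0.0, False

    # maximal contiguous run of enriched samples
    best_len = 0.0
    start = None
    padded = np.concatenate([enriched, [False]])
    for i, flag in enumerate(padded):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            width = positions[i - 1] - positions[start]
            if width > best_len:
                best_len = width
            start = None
    return float(best_len), True


def breadth_time_average(
    apical_breadths: Sequence[tuple[float, bool]],
    basal_breadths: Sequence[tuple[float, bool]],
    cell_length: float,
    n_timepoints: int = BREADTH_N_TIMEPOINTS,
) -> BreadthMeasurement:
    """Average ring breadth over the earliest detected timepoints.

    Apical and basal series are filtered to frames with detected
    enrichment independently, then the first ``min(n_timepoints,
    available)`` detected values are averaged for each surface.
    """

    def first_detected(series: Sequence[tuple[float, bool]]) -> list[float]:
        vals = [b for b, det in series if det]
        if not vals:
            raise NoEnrichmentError("no timepoint with detectable enrichment")
        return vals[:n_timepoints]

    api = first_detected(apical_breadths)
    bas = first_detected(basal_breadths)
    return BreadthMeasurement(
        apical_breadth=float(np.mean(api)),
        basal_breadth=float(np.mean(bas)),
        n_timepoints_averaged=min(len(api), len(bas)),
        cell_length=cell_length,
    )


def linear_scaling_fit(x: Sequence[float], y: Sequence[float]) -> ScalingFit:
    """OLS line with slope/intercept standard errors and R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise MorphometricsError(f"regression needs >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise MorphometricsError("regression abscissa is degenerate (all x equal)")
    model = sm.OLS(y, sm.add_constant(x))
    res = model.fit()
    return ScalingFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n_points=len(x),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
    )


def division_plane_perimeter(height: float, thickness: float) -> float:
    """Perimeter (µm) of the elliptical division-plane cross-section.

    Semi-axes are height/2 and thickness/2; Ramanujan's approximation
    ``π[3(a+b) − √((3a+b)(a+3b))]`` is exact to ~1e-5 relative error for
    the aspect ratios of epithelial cells.
    """
    if height <= 0 or thickness <= 0:
        raise MorphometricsError("division-plane axes must be positive")
    a, b = height / 2.0, thickness / 2.0
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def region_mean_intensity(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int],
) -> float:
    """Background-normalized mean intensity of a rectangular ROI.

    ROIs are ``(x, y, width, height)`` in 0-based pixels, half-open.
    Returns mean(roi) / mean(background), the convention for reporting
    fluorescence relative to off-specimen background.
    """
    image = np.asarray(image, dtype=float)

    def crop(r: tuple[int, int, int, int]) -> np.ndarray:
        x, y, w, h = r
        if x < 0 or y < 0 or w <= 0 or h <= 0 or x + w > image.shape[1] or \
                y + h > image.shape[0]:
            raise MorphometricsError(f"ROI {r} outside image {image.shape}")
        return image[y : y + h, x : x + w]

    bg = float(crop(background_roi).mean())
    if bg <= 0:
        raise MorphometricsError("background mean is not positive")
    return float(crop(roi).mean()) / bg
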