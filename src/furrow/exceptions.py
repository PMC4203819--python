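"""Exception hierarchy for annotation, geometry and kinetics failures.

Every error raised by the package derives from :class:`FurrowError` so
pipeline drivers can distinguish per-trace analysis failures from
programming errors.
"""


class FurrowError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(FurrowError):
    """Degenerate point configurations or invalid circles."""


class CollinearPointsError(GeometryError):
    """Three annotation points are (near-)collinear; no circle fits."""


class DuplicatePointError(GeometryError):
    """Two annotation points coincide."""


class RingLargerThanCellError(GeometryError):
    """Ring radius exceeds cell radius beyond the jitter tolerance."""


class NonUnitAxisError(GeometryError):
    """The supplied apical axis is not a unit vector."""


class KineticsError(FurrowError):
    """Trace-level kinetics failures."""


class LevelNotReachedError(KineticsError):
    """Closure (or asymmetry abscissa) never crosses the requested level."""


class NonMonotoneTraceError(KineticsError):
    """Smoothed closure decreases by more than the monotonicity guard."""


class WindowError(KineticsError):
    """Smoothing window invalid for the trace length."""


class MorphometricsError(FurrowError):
    """Dimension, profile or regression input failures."""


class ProfileTooShortError(MorphometricsError):
    """Intensity profile has too few samples for breadth extraction."""


class NoEnrichmentError(MorphometricsError):
    """No frame with detectable equatorial enrichment."""


class StatsError(FurrowError):
    """Invalid inputs to the statistical layer."""


class SimulationError(FurrowError):
    """Invalid generator model parameters."""


class AnnotationIOError(FurrowError):
    """Schema or unit problems in annotation / dimension files."""
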