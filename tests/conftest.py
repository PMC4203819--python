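"""Shared fixtures and trace-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from furrow.geometry import CircleFit, FrameMetrics, Point2D
from furrow.kinetics import RingTrace
from furrow.simulate import logistic_closure


def trace_from_arrays(
    times,
    closure,
    asymmetry=None,
    trace_id: str = "t0",
    cell_radius: float = 1.0,
) -> RingTrace:
    """Build a RingTrace directly from closure/asymmetry arrays.

    Synthesizes consistent circle fits (cell at the origin, ring offset
    along +y by the asymmetry) so kinetics can be tested independently of
    the geometry stage.
    """
    times = np.asarray(times, dtype=float)
    closure = np.asarray(closure, dtype=float)
    if asymmetry is None:
        asymmetry = np.zeros_like(closure)
    asymmetry = np.asarray(asymmetry, dtype=float)
    frames = []
    for c, a in zip(closure, asymmetry):
        r = max(cell_radius * (1.0 - c / 100.0), 1e-9)
        d = cell_radius * a / 100.0
        frames.append(
            FrameMetrics(
                closure_pct=float(c),
                asymmetry_pct=float(a),
                apical_displacement=float(d),
                cell=CircleFit(Point2D(0.0, 0.0), cell_radius),
                ring=CircleFit(Point2D(0.0, d), r),
            )
        )
    return RingTrace(
        trace_id=trace_id, times=tuple(times), frames=tuple(frames)
    )


def logistic_trace(
    k: float,
    t0: float,
    dt: float,
    span: tuple[float, float] = (1.0, 99.0),
    alpha: float = 0.0,
    trace_id: str = "logi",
) -> RingTrace:
    """Noise-free logistic closure trace sampled on a regular grid."""
    t_lo = t0 + np.log(span[0] / (100 - span[0])) / k
    t_hi = t0 + np.log(span[1] / (100 - span[1])) / k
    start = max(0.0, t_lo)
    n = int(np.floor((t_hi - start) / dt)) + 1
    t = start + dt * np.arange(n)
    c = logistic_closure(t, k, t0)
    return trace_from_arrays(t, c, alpha * c, trace_id=trace_id)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
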