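"""File formats, configuration and the end-to-end pipeline driver.

Formats are plain CSV (comma-separated, UTF-8, '.' decimal) with a
commented header block ('#'-prefixed) echoing the configuration, so
every output records how it was produced.  Annotation coordinates are
stored 0-based in pixels and converted to µm on read using the
configured pixel size; times are stored in seconds and converted to
minutes for kinetics.  Kymographs are written as 16-bit grayscale TIFF
with a PNG preview.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import AnnotationIOError, FurrowError
from .geometry import AnnotatedFrame, Point2D
from .kinetics import PopulationCurve, RingTrace
from .models import ClosureKinetics, ScalingRegression

__all__ = [
    "RunConfig",
    "ANNOTATION_COLUMNS",
    "read_annotations",
    "write_annotations",
    "write_trace_csv",
    "write_summary_csv",
    "write_population_csv",
    "write_kymograph",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "trace_id", "time_s",
    "cx1", "cy1", "cx2", "cy2", "cx3", "cy3",
    "rx1", "ry1", "rx2", "ry2", "rx3", "ry3",
    "apical_x", "apical_y",
]


@dataclass
class RunConfig:
    """Physical calibration and analysis parameters for one run.

    Defaults match swept-field confocal acquisition of worm epithelia:
    0.6 µm z steps and 30-s frame intervals.
    """

    pixel_size_um: float = 0.1
    z_step_um: float = 0.6
    frame_interval_s: float = 30.0
    smooth_window: int = 3
    collinearity_tol: float = 1e-6
    enrichment_k: float = 2.0
    seed: int = 0
    input_path: str = ""
    output_dir: str = "."
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0 or \
                self.frame_interval_s <= 0:
            raise AnnotationIOError("physical scales must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def header_lines(self) -> list[str]:
        """Commented header block echoing the config verbatim."""
        cfg = json.dumps(asdict(self), sort_keys=True)
        digest = hashlib.sha256(cfg.encode()).hexdigest()[:12]
        return [
            f"# furrow {__version__}",
            f"# config {cfg}",
            f"# config_sha256 {digest}",
            f"# seed {self.seed}",
        ]


def _write_csv_with_header(df: pd.DataFrame, path: str | Path,
                           config: RunConfig | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if config is not None:
            for line in config.header_lines():
                fh.write(line + "\n")
        df.to_csv(fh, index=False)


def write_annotations(
    frames_by_trace: dict[str, Sequence[AnnotatedFrame]],
    path: str | Path,
    config: RunConfig,
) -> None:
    """Write annotation frames to CSV, converting µm back to pixels."""
    s = config.pixel_size_um
    rows = []
    for tid, frames in frames_by_trace.items():
        for f in frames:
            row = {"trace_id": tid, "time_s": f.time}
            for i, p in enumerate(f.cell_points, 1):
                row[f"cx{i}"], row[f"cy{i}"] = p.x / s, p.y / s
            for i, p in enumerate(f.ring_points, 1):
                row[f"rx{i}"], row[f"ry{i}"] = p.x / s, p.y / s
            row["apical_x"], row["apical_y"] = f.apical_axis.x, f.apical_axis.y
            rows.append(row)
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    _write_csv_with_header(df, path, config)


def read_annotations(
    path: str | Path, config: RunConfig
) -> dict[str, list[AnnotatedFrame]]:
    """Read an annotation CSV into per-trace frames in µm.

    Validates the schema, converts pixel coordinates to µm with the
    configured pixel size, and checks strictly increasing times within
    each trace.  Malformed rows are reported with their line numbers; a
    header-only file returns an empty result with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationIOError(f"annotation file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationIOError(
            f"{path}: missing annotation columns {missing}"
        )
    if df.empty:
        warnings.warn(f"{path}: no annotation rows", stacklevel=2)
        return {}

    bad = df[ANNOTATION_COLUMNS[1:]].apply(
        lambda col: pd.to_numeric(col, errors="coerce")
    ).isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad]]  # 1-based incl. header
        raise AnnotationIOError(
            f"{path}: non-numeric or missing values in rows {rows}"
        )

    s = config.pixel_size_um
    out: dict[str, list[AnnotatedFrame]] = {}
    for tid, group in df.groupby("trace_id", sort=False):
        times = group["time_s"].to_numpy(dtype=float)
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0)) + 1
            row_no = int(group.index[i]) + 2
            raise AnnotationIOError(
                f"{path}: trace {tid}: time not strictly increasing at row "
                f"{row_no} (t={times[i]} s)"
            )
        frames = []
        for row in group.itertuples():
            frames.append(
                AnnotatedFrame(
                    time=float(row.time_s),
                    cell_points=(
                        Point2D(row.cx1 * s, row.cy1 * s),
                        Point2D(row.cx2 * s, row.cy2 * s),
                        Point2D(row.cx3 * s, row.cy3 * s),
                    ),
                    ring_points=(
                        Point2D(row.rx1 * s, row.ry1 * s),
                        Point2D(row.rx2 * s, row.ry2 * s),
                        Point2D(row.rx3 * s, row.ry3 * s),
                    ),
                    apical_axis=Point2D(float(row.apical_x), float(row.apical_y)),
                )
            )
        out[str(tid)] = frames
    return out


def trace_frame(trace: RingTrace) -> pd.DataFrame:
    """Long-form per-frame metrics table for one quantified trace."""
    return pd.DataFrame(
        {
            "trace_id": trace.trace_id,
            "cell_label": trace.cell_label,
            "time_min": trace.times,
            "closure_pct": [f.closure_pct for f in trace.frames],
            "asymmetry_pct": [f.asymmetry_pct for f in trace.frames],
            "apical_displacement_um": [
                f.apical_displacement for f in trace.frames
            ],
            "r_um": [f.ring.radius for f in trace.frames],
            "R_um": [f.cell.radius for f in trace.frames],
        }
    )


def write_trace_csv(traces: Sequence[RingTrace], path: str | Path,
                    config: RunConfig | None = None) -> None:
    df = pd.concat([trace_frame(t) for t in traces], ignore_index=True)
    _write_csv_with_header(df, path, config)


def write_summary_csv(summary_frame: pd.DataFrame, path: str | Path,
                      config: RunConfig | None = None) -> None:
    _write_csv_with_header(summary_frame, path, config)


def write_population_csv(curve: PopulationCurve, path: str | Path,
                         config: RunConfig | None = None) -> None:
    df = pd.DataFrame(
        {"grid": curve.grid, "mean": curve.mean, "sem": curve.sem, "n": curve.n}
    )
    _write_csv_with_header(df, path, config)


def write_kymograph(kymo: np.ndarray, path: str | Path) -> None:
    """Write a kymograph as 16-bit grayscale TIFF plus a PNG preview."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lo, hi = float(kymo.min()), float(kymo.max())
    scaled = np.zeros_like(kymo) if hi == lo else (kymo - lo) / (hi - lo)
    img16 = (scaled * 65535).astype(np.uint16)
    tifffile.imwrite(path.with_suffix(".tif"), img16)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path.with_suffix(".png"), img16, cmap="gray")


def run_pipeline(config: RunConfig) -> dict:
    """quantify → summarize → scale over every trace in the input file.

    Writes the per-frame trace CSV, per-trace summary CSV, population
    curve CSVs (closure, speed, asymmetry) and, when two or more traces
    have distinct midpoint speeds and perimeters are unavailable, skips
    the scaling step.  Per-trace failures are logged and the trace
    dropped; the run fails only if no trace survives.

    Returns a manifest of output paths and counts.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotations = read_annotations(config.input_path, config)
    if not annotations:
        raise AnnotationIOError(f"{config.input_path}: no traces to analyze")

    from .models import quantify_trace

    traces = []
    failures = {}
    for tid, frames in annotations.items():
        try:
            traces.append(
                quantify_trace(tid, frames,
                               cell_label=config.labels.get(tid, ""))
            )
        except FurrowError as exc:
            logger.error("trace %s failed: %s", tid, exc)
            failures[tid] = str(exc)
    if not traces:
        raise AnnotationIOError("all traces failed quantification")

    model = ClosureKinetics(traces, smooth_window=config.smooth_window)
    results = model.fit()

    write_trace_csv(traces, out_dir / "traces.csv", config)
    write_summary_csv(results.summary_frame, out_dir / "summary.csv", config)
    for name, curve in results.curves.items():
        write_population_csv(curve, out_dir / f"population_{name}.csv", config)

    manifest = {
        "n_traces": len(traces),
        "n_failed": len(failures),
        "failures": failures,
        "outputs": [
            str(out_dir / "traces.csv"),
            str(out_dir / "summary.csv"),
        ]
        + [str(out_dir / f"population_{name}.csv") for name in results.curves],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def joint_scaling_fit(
    summaries: pd.DataFrame,
    reference_points: pd.DataFrame | None = None,
    x: str = "perimeter_um",
    y: str = "speed_um_per_min",
) -> ScalingRegression:
    """Assemble the speed-vs-perimeter scaling model, optionally pooling
    external reference points (published pairs from other cell types)."""
    model = ScalingRegression.from_dataframe(summaries, x, y)
    if reference_points is not None:
        model = model.with_reference_points(
            reference_points[x].to_numpy(), reference_points[y].to_numpy()
        )
    return model
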