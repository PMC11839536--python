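"""Reading and writing of image stacks, metadata sidecars and result tables.

An acquisition is stored as a 16-bit multi-page TIFF (one page per frame)
plus a JSON sidecar carrying the physical metadata that TIFF tags do not
express portably.  The sidecar schema requires:

* ``pixel_size_mm`` — pixel edge length, mm/px
* ``frame_interval_min`` — time between frames, min
* ``t0_offset_min`` — acquisition start relative to the end of tracer
  infusion, min

plus optional keys (``origin_mm``, ``injection_site_mm``, ``bregma_mm``,
``condition``, ``seed``, ``ground_truth``) that round-trip untouched.

Kinetic metrics are exported as a flat CSV with one row per (animal, ROI);
censored appearance times are written as an empty cell with an explicit
``censored`` flag, never a sentinel value.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "SidecarError",
    "StackFormatError",
    "read_stack",
    "write_stack",
    "sidecar_path",
    "METRICS_COLUMNS",
    "write_metrics_table",
    "read_metrics_table",
    "write_timeseries_table",
    "write_stats_table",
    "write_mask",
]

REQUIRED_SIDECAR_KEYS = ("pixel_size_mm", "frame_interval_min", "t0_offset_min")

METRICS_COLUMNS = [
    "animal_id",
    "condition",
    "roi_name",
    "slope",
    "slope_intercept",
    "appearance_time",
    "censored",
    "mean_normalized_intensity",
]


class SidecarError(ValueError):
    """Missing or malformed metadata sidecar."""


class StackFormatError(ValueError):
    """Image data violating the stack format contract."""


@dataclass
class ImageStack:
    """A time-ordered series of 2-D intensity frames with physical units.

    ``frames`` has shape (T, H, W) in arbitrary camera units; ``pixel_size``
    is mm/px, ``frame_interval`` min, and ``t0_offset`` the delay (min)
    between the end of tracer infusion and the first recorded frame.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    t0_offset: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise StackFormatError("frames must be a 3-D (time, row, col) array")
        if not np.isfinite(self.frames).all():
            raise StackFormatError("frames contain non-finite intensities")
        if (self.frames < 0).any():
            raise StackFormatError("frames contain negative intensities")
        if not (self.pixel_size > 0):
            raise StackFormatError("pixel_size must be > 0")
        if not (self.frame_interval > 0):
            raise StackFormatError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in minutes relative to the first frame (t0)."""
        return np.arange(self.n_frames, dtype=np.float64) * self.frame_interval

    @property
    def field_origin(self) -> tuple[float, float]:
        """(x, y) of the field corner in mm; (0, 0) when not recorded."""
        return tuple(self.metadata.get("origin_mm", (0.0, 0.0)))


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(stack: ImageStack, path) -> None:
    """Write a 16-bit multi-page TIFF plus its JSON sidecar.

    Intensities must lie in [0, 65535]; out-of-range values raise, they are
    never clipped.  Values are rounded to the nearest integer, so the
    round-trip is lossless for integer-valued data.
    """
    frames = stack.frames
    if frames.min() < 0 or frames.max() > np.iinfo(np.uint16).max:
        raise StackFormatError(
            f"intensities [{frames.min()}, {frames.max()}] exceed the 16-bit "
            "range [0, 65535]; rescale before writing"
        )
    path = Path(path)
    tifffile.imwrite(
        path, np.round(frames).astype(np.uint16), photometric="minisblack"
    )
    sidecar = dict(stack.metadata)
    sidecar["pixel_size_mm"] = stack.pixel_size
    sidecar["frame_interval_min"] = stack.frame_interval
    sidecar["t0_offset_min"] = stack.t0_offset
    _atomic_write_text(json.dumps(sidecar, indent=1, sort_keys=True), sidecar_path(path))


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF plus sidecar back into an :class:`ImageStack`."""
    path = Path(path)
    sc_path = sidecar_path(path)
    if not sc_path.exists():
        raise SidecarError(
            f"no metadata sidecar at {sc_path}; required keys: "
            f"{', '.join(REQUIRED_SIDECAR_KEYS)}"
        )
    with open(sc_path) as fh:
        sidecar = json.load(fh)
    missing = [k for k in REQUIRED_SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise SidecarError(f"sidecar {sc_path} lacks required keys: {missing}")
    try:
        frames = tifffile.imread(path)
    except (ValueError, tifffile.TiffFileError) as exc:
        raise StackFormatError(f"cannot read TIFF pages from {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    if frames.ndim != 3:
        raise StackFormatError(
            f"{path}: pages do not form a uniform (time, row, col) stack"
        )
    meta = {k: v for k, v in sidecar.items() if k not in REQUIRED_SIDECAR_KEYS}
    return ImageStack(
        frames=frames.astype(np.float64),
        pixel_size=float(sidecar["pixel_size_mm"]),
        frame_interval=float(sidecar["frame_interval_min"]),
        t0_offset=float(sidecar["t0_offset_min"]),
        metadata=meta,
    )


def write_mask(mask: np.ndarray, path) -> None:
    """Export a boolean mask as a single-page 8-bit TIFF (255 inside)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def _atomic_write_text(text: str, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_df(df: pd.DataFrame, path) -> None:
    path = Path(path)
    _atomic_write_text(df.to_csv(index=False), path)


def write_metrics_table(records: list[dict], path) -> None:
    """Write per-(animal, ROI) kinetic metrics as a flat CSV.

    Each record is a mapping with the :data:`METRICS_COLUMNS` keys; a
    censored appearance time is ``None`` and is written as an empty cell
    with ``censored=True``.  Duplicate (animal_id, roi_name) pairs raise.
    """
    if not records:
        raise ValueError("records must be non-empty")
    df = pd.DataFrame.from_records(records, columns=METRICS_COLUMNS)
    dup = df.duplicated(subset=["animal_id", "roi_name"])
    if dup.any():
        pairs = df.loc[dup, ["animal_id", "roi_name"]].to_records(index=False)
        raise ValueError(f"duplicate (animal, ROI) keys: {list(pairs)}")
    censored = df["censored"].astype(bool)
    if (censored & df["appearance_time"].notna()).any():
        raise ValueError("censored rows must not carry an appearance_time value")
    _atomic_write_df(df, path)


def read_metrics_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["censored"] = df["censored"].astype(bool)
    df["appearance_time"] = pd.to_numeric(df["appearance_time"], errors="coerce")
    return df


def write_timeseries_table(df: pd.DataFrame, path) -> None:
    """Long-format per-frame table: animal_id, condition, roi_name, time_min,
    mean_intensity, normalized_intensity."""
    required = {
        "animal_id",
        "condition",
        "roi_name",
        "time_min",
        "mean_intensity",
        "normalized_intensity",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"timeseries table lacks columns: {sorted(missing)}")
    _atomic_write_df(df, path)


def write_stats_table(results, path) -> None:
    """Write a list of :class:`~glymphkin.group_stats.TestResult` as CSV."""
    rows = []
    for r in results:
        rows.append(
            {
                "comparison": r.comparison,
                "statistic": r.statistic,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "adjust_method": r.adjust_method,
                "outliers_removed": ";".join(map(str, r.outliers_removed)),
                "n_per_group": json.dumps(r.n_per_group, sort_keys=True),
                "extra": json.dumps(r.extra, sort_keys=True),
            }
        )
    _atomic_write_df(pd.DataFrame(rows), path)
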