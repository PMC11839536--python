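"""ROI kinetic statistics for CSF tracer time-lapse stacks.

Three per-ROI statistics describe tracer kinetics in the extravascular
space:

1. **normalized intensity** — the ROI's mean intensity divided, frame by
   frame, by the mean intensity of the small background reference circle of
   the same animal;
2. **intensity/time** — the slope of an ordinary least-squares line fitted
   to the ROI's mean intensity over the whole acquisition window (AU/min),
   a perfusion-rate surrogate;
3. **appearance time** — the first sampled time at which the ROI's signal
   reaches 10% above its baseline (the ROI's own value at the first frame
   by default), an influx-latency statistic.  If the threshold is never
   reached within the window, the value is *censored* and reported as such
   rather than as any number.

No sub-frame interpolation is applied to the threshold crossing: with
1-min sampling, reporting the first qualifying frame matches the native
resolution of the measurement.  Slope and appearance time are computed on
the raw mean-intensity series; normalization enters only statistic (1)
(both choices are switchable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ImageStack
from .roi_geometry import ANALYSIS_ROIS, ROILayout, rasterize_roi

__all__ = [
    "APPEARANCE_THRESHOLD_FACTOR",
    "ROITimeSeries",
    "KineticMetrics",
    "extract_timeseries",
    "normalized_intensity",
    "intensity_rate",
    "appearance_time",
    "compute_all_metrics",
]

#: Appearance threshold: signal must reach this multiple of baseline (10% above).
APPEARANCE_THRESHOLD_FACTOR = 1.1


@dataclass(frozen=True)
class ROITimeSeries:
    """Mean intensity of one ROI over time (times in min, strictly increasing)."""

    roi_name: str
    times: np.ndarray
    mean_intensity: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        values = np.asarray(self.mean_intensity, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "mean_intensity", values)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValueError("times and mean_intensity must be 1-D, same length")
        if times.size < 2:
            raise ValueError("a kinetic series needs at least 2 frames")
        if not (np.diff(times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("intensities must be finite and >= 0")


@dataclass
class KineticMetrics:
    """Derived statistics for one ROI.

    ``appearance_time`` is ``None`` when censored (threshold never reached
    within the acquisition window); ``censored`` makes that explicit.
    """

    roi_name: str
    times: np.ndarray
    normalized_intensity: np.ndarray
    slope: float
    slope_intercept: float
    appearance_time: float | None
    censored: bool
    baseline_reference: float
    metadata: dict = field(default_factory=dict)

    @property
    def mean_normalized_intensity(self) -> float:
        return float(np.mean(self.normalized_intensity))


def extract_timeseries(
    stack: ImageStack, mask: np.ndarray, roi_name: str
) -> ROITimeSeries:
    """Mean intensity of the masked pixels in every frame.

    Times are minutes relative to the first frame (frame index times the
    frame interval).
    """
    mask = np.asarray(mask, bool)
    if mask.shape != stack.grid_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frames {stack.grid_shape}"
        )
    if not mask.any():
        raise ValueError(f"ROI {roi_name!r}: mask selects no pixels")
    values = stack.frames[:, mask].mean(axis=1)
    return ROITimeSeries(roi_name=roi_name, times=stack.times, mean_intensity=values)


def normalized_intensity(
    roi_ts: ROITimeSeries, background_ts: ROITimeSeries
) -> np.ndarray:
    """Frame-wise ratio of ROI to background mean intensity (dimensionless).

    Requires both series on the same time grid and a strictly positive
    background at every frame; a zero background raises rather than being
    patched with an epsilon.
    """
    if not np.array_equal(roi_ts.times, background_ts.times):
        raise ValueError("ROI and background series must share the same time grid")
    bg = background_ts.mean_intensity
    if (bg <= 0).any():
        bad = np.flatnonzero(bg <= 0)
        raise ValueError(
            f"background intensity is not positive at frame(s) {bad.tolist()}"
        )
    return roi_ts.mean_intensity / bg


def intensity_rate(values, times) -> tuple[float, float]:
    """Ordinary least-squares (slope, intercept) of intensity vs time.

    Fitted over the full window; slope in AU/min.
    """
    values = np.asarray(values, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if times.size < 2 or np.unique(times).size < 2:
        raise ValueError("need at least 2 distinct time points for a linear fit")
    slope, intercept = np.polyfit(times, values, 1)
    return float(slope), float(intercept)


def appearance_time(
    values,
    times,
    baseline_reference: float | None = None,
    threshold_factor: float = APPEARANCE_THRESHOLD_FACTOR,
) -> float | None:
    """Time of the first sample at or above ``threshold_factor * baseline``.

    ``baseline_reference`` defaults to the series' own first value.  The
    comparison is inclusive (a sample exactly at threshold qualifies).
    Returns ``None`` when no sample qualifies (censored).
    """
    values = np.asarray(values, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if baseline_reference is None:
        baseline_reference = float(values[0])
    if not (baseline_reference > 0):
        raise ValueError("baseline_reference must be > 0")
    # inclusive comparison; the tiny relative slack absorbs the representation
    # error of the threshold product so an exact 10%-above sample qualifies
    threshold = threshold_factor * baseline_reference
    hits = np.flatnonzero(values >= threshold * (1.0 - 1e-12))
    if hits.size == 0:
        return None
    return float(times[hits[0]])


def compute_all_metrics(
    stack: ImageStack,
    layout: ROILayout,
    baseline_mode: str = "roi",
    rate_on_normalized: bool = False,
) -> list[KineticMetrics]:
    """Compute all three statistics for every analysis ROI of a stack.

    ``baseline_mode`` selects the appearance-time reference: ``"roi"`` (the
    ROI's own first-frame intensity, default) or ``"background"`` (the
    background circle's first-frame intensity).  ``rate_on_normalized``
    switches the slope fit from the raw to the background-normalized
    series.
    """
    if baseline_mode not in ("roi", "background"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    origin = stack.field_origin
    shape = stack.grid_shape

    def series_for(name: str) -> ROITimeSeries:
        mask = rasterize_roi(layout[name], stack.pixel_size, shape, origin)
        return extract_timeseries(stack, mask, name)

    background_ts = series_for("background")
    results = []
    for name in ANALYSIS_ROIS:
        roi_ts = series_for(name)
        norm = normalized_intensity(roi_ts, background_ts)
        rate_series = norm if rate_on_normalized else roi_ts.mean_intensity
        slope, intercept = intensity_rate(rate_series, roi_ts.times)
        baseline = (
            float(roi_ts.mean_intensity[0])
            if baseline_mode == "roi"
            else float(background_ts.mean_intensity[0])
        )
        t_app = appearance_time(roi_ts.mean_intensity, roi_ts.times, baseline)
        results.append(
            KineticMetrics(
                roi_name=name,
                times=roi_ts.times.copy(),
                normalized_intensity=norm,
                slope=slope,
                slope_intercept=intercept,
                appearance_time=t_app,
                censored=t_app is None,
                baseline_reference=baseline,
                metadata={
                    "baseline_mode": baseline_mode,
                    "rate_on_normalized": rate_on_normalized,
                    "threshold_factor": APPEARANCE_THRESHOLD_FACTOR,
                    "raw_mean_intensity": roi_ts.mean_intensity.tolist(),
                },
            )
        )
    return results
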