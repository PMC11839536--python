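"""End-to-end orchestration: simulate -> extract -> quantify -> compare.

A full run writes, under one output directory:

* ``stacks/<animal>.tif`` + ``.json`` — simulated acquisitions and sidecars
  (simulate stage);
* ``metrics.csv`` — one row per (animal, ROI) with slope, appearance time
  (censored flag) and mean normalized intensity;
* ``timeseries.csv`` — long-format per-frame ROI series;
* ``stats.csv`` — per-ROI sham-vs-TBI Welch comparisons after ROUT
  screening, raw and Šídák-adjusted;
* ``manifest.json`` — config hash, seed, package version, per-stage wall
  times.

Everything except the timing block of the manifest is bit-reproducible for
a fixed config and seed.  Tables are written atomically (staged to a
temporary file, then renamed), so failures never leave half-written CSVs.

The master seed fans out to cohorts as ``default_rng(seed)`` draws, and
each cohort fans out to animals through ``(cohort seed, animal index)``
seed sequences, so adding animals or cohorts never perturbs existing data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .group_stats import compare_conditions
from .io_formats import (
    read_metrics_table,
    read_stack,
    write_metrics_table,
    write_stats_table,
    write_timeseries_table,
    _atomic_write_text,
)
from .kinetics import compute_all_metrics
from .roi_geometry import FieldGeometry, build_roi_layout
from .synthetic_data import (
    DEFAULT_INTER_ANIMAL_CV,
    DEFAULT_N_ANIMALS,
    DEFAULT_SEED,
    CohortConfig,
    make_condition_preset,
    simulate_cohort,
)

__all__ = [
    "RunConfig",
    "layout_for_stack",
    "run_simulate",
    "run_analyze",
    "run_stats",
    "run_full",
]

logger = logging.getLogger("glymphkin")

COMPARED_METRICS = ("appearance_time", "slope", "mean_normalized_intensity")
COMPARED_ROIS = ("FC", "APC", "LLV", "PPC")


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    output_dir: Path
    seed: int = DEFAULT_SEED
    n_sham: int = DEFAULT_N_ANIMALS["sham"]
    n_tbi: int = DEFAULT_N_ANIMALS["tbi"]
    inter_animal_cv: float = DEFAULT_INTER_ANIMAL_CV
    rout_q: float = 1.0
    adjust: str = "sidak"
    baseline_mode: str = "roi"
    rois: tuple = COMPARED_ROIS
    metrics: tuple = COMPARED_METRICS
    preset_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["output_dir"] = str(self.output_dir)
        d["rois"] = list(self.rois)
        d["metrics"] = list(self.metrics)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output path is excluded)."""
        d = self.to_dict()
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cohorts(config: RunConfig) -> list[CohortConfig]:
    rng = np.random.default_rng(config.seed)
    cohorts = []
    for condition, n in (("sham", config.n_sham), ("tbi", config.n_tbi)):
        base = make_condition_preset(condition)
        if config.preset_overrides:
            from dataclasses import replace

            base = replace(base, **config.preset_overrides)
        cohorts.append(
            CohortConfig(
                condition=condition,
                n_animals=n,
                base_config=base,
                inter_animal_cv=config.inter_animal_cv,
                seed=int(rng.integers(2**31)),
            )
        )
    return cohorts


def run_simulate(config: RunConfig) -> Path:
    """Simulate both cohorts and write stacks + sidecars. Returns the stack dir."""
    from .io_formats import write_stack

    stack_dir = Path(config.output_dir) / "stacks"
    stack_dir.mkdir(parents=True, exist_ok=True)
    for cohort in _cohorts(config):
        logger.info(
            "simulating cohort %s: n=%d cv=%.3g seed=%d",
            cohort.condition, cohort.n_animals, cohort.inter_animal_cv, cohort.seed,
        )
        for animal_id, stack, _cfg in simulate_cohort(cohort):
            write_stack(stack, stack_dir / f"{animal_id}.tif")
    return stack_dir


def layout_for_stack(stack):
    """Standard ROI layout for a stack, derived from its sidecar metadata."""
    origin = stack.field_origin
    fieldgeom = FieldGeometry(
        origin=origin, shape=stack.grid_shape, pixel_size=stack.pixel_size
    )
    injection = tuple(stack.metadata.get("injection_site_mm", (-1.6, -1.3)))
    bregma = tuple(stack.metadata.get("bregma_mm", (0.0, 0.0)))
    return build_roi_layout(injection, bregma, field=fieldgeom)


_layout_for = layout_for_stack


def run_analyze(stack_dir, output_dir, baseline_mode: str = "roi") -> tuple[Path, Path]:
    """Extract kinetic metrics from every stack in a directory.

    Returns (metrics_csv, timeseries_csv).
    """
    stack_dir = Path(stack_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(stack_dir.glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no .tif stacks under {stack_dir}")
    records = []
    ts_rows = []
    for path in paths:
        stack = read_stack(path)
        animal_id = stack.metadata.get("animal_id", path.stem)
        condition = stack.metadata.get("condition", "unknown")
        layout = _layout_for(stack)
        logger.info("analyzing %s (%s)", animal_id, condition)
        for m in compute_all_metrics(stack, layout, baseline_mode=baseline_mode):
            records.append(
                {
                    "animal_id": animal_id,
                    "condition": condition,
                    "roi_name": m.roi_name,
                    "slope": m.slope,
                    "slope_intercept": m.slope_intercept,
                    "appearance_time": m.appearance_time,
                    "censored": m.censored,
                    "mean_normalized_intensity": m.mean_normalized_intensity,
                }
            )
            raw = m.metadata["raw_mean_intensity"]
            for t, mi, ni in zip(m.times, raw, m.normalized_intensity):
                ts_rows.append(
                    {
                        "animal_id": animal_id,
                        "condition": condition,
                        "roi_name": m.roi_name,
                        "time_min": float(t),
                        "mean_intensity": float(mi),
                        "normalized_intensity": float(ni),
                    }
                )
    metrics_path = output_dir / "metrics.csv"
    ts_path = output_dir / "timeseries.csv"
    write_metrics_table(records, metrics_path)
    write_timeseries_table(pd.DataFrame(ts_rows), ts_path)
    return metrics_path, ts_path


def run_stats(metrics_csv, output_dir, rois=COMPARED_ROIS,
              metrics=COMPARED_METRICS, q: float | None = 1.0,
              adjust: str = "sidak") -> Path:
    """Run the per-ROI sham-vs-TBI comparisons on a metrics table."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    table = read_metrics_table(metrics_csv)
    results = []
    for metric in metrics:
        results.extend(
            compare_conditions(table, metric, list(rois), q=q, adjust=adjust)
        )
    stats_path = output_dir / "stats.csv"
    write_stats_table(results, stats_path)
    return stats_path


def run_full(config: RunConfig) -> dict:
    """Simulate, analyze and compare; write the run manifest.

    Returns the manifest dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timing = {}

    t0 = time.perf_counter()
    stack_dir = run_simulate(config)
    timing["simulate_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    metrics_path, ts_path = run_analyze(stack_dir, out, config.baseline_mode)
    timing["analyze_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stats_path = run_stats(
        metrics_path, out, rois=config.rois, metrics=config.metrics,
        q=config.rout_q, adjust=config.adjust,
    )
    timing["stats_s"] = time.perf_counter() - t0

    manifest = {
        "package": "glymphkin",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "outputs": {
            "stacks": str(stack_dir),
            "metrics": str(metrics_path),
            "timeseries": str(ts_path),
            "stats": str(stats_path),
        },
        "timing": timing,
    }
    _atomic_write_text(
        json.dumps(manifest, indent=1, sort_keys=True), out / "manifest.json"
    )
    return manifest
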