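"""Deterministic figures from the metrics and stats tables.

Two figure families, written with fixed file names and fixed DPI so a
report regenerated from the same CSVs is byte-identical:

* ``scatter_<metric>.png`` — per-ROI scatter of per-animal values with
  group mean +/- SEM and a significance bar where the adjusted p-value
  falls below 0.05 (suppressed, with a logged warning, when a group has
  fewer than 2 values);
* ``timecourse_normalized_intensity.png`` — group-mean normalized
  intensity over time per ROI.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pipeline import COMPARED_METRICS, COMPARED_ROIS

__all__ = ["make_report"]

logger = logging.getLogger("glymphkin")

_COLORS = {"sham": "0.3", "tbi": "#c23b6f"}


def _sig_label(p: float) -> str | None:
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return None


def make_report(
    metrics_csv,
    stats_csv,
    output_dir,
    timeseries_csv=None,
    metrics=COMPARED_METRICS,
    rois=COMPARED_ROIS,
) -> list[Path]:
    """Render the per-ROI scatter and time-course figures. Returns paths."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(metrics_csv)
    if table.empty:
        raise ValueError("metrics table is empty")
    stats = pd.read_csv(stats_csv) if stats_csv is not None else pd.DataFrame()
    written = []

    for metric in metrics:
        fig, axes = plt.subplots(
            1, len(rois), figsize=(3.0 * len(rois), 3.2), sharey=False
        )
        axes = np.atleast_1d(axes)
        for ax, roi in zip(axes, rois):
            sub = table[table["roi_name"] == roi]
            ymax = -np.inf
            for j, cond in enumerate(("sham", "tbi")):
                vals = pd.to_numeric(
                    sub.loc[sub["condition"] == cond, metric], errors="coerce"
                ).dropna()
                x = np.full(len(vals), float(j))
                ax.plot(x, vals, "o", ms=4, alpha=0.6, color=_COLORS[cond])
                if len(vals) >= 1:
                    mean = float(vals.mean())
                    sem = (
                        float(vals.std(ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1
                        else 0.0
                    )
                    ax.errorbar(
                        [j], [mean], yerr=[sem], fmt="_", ms=18,
                        color="k", capsize=5, lw=1.5,
                    )
                    ymax = max(ymax, float(vals.max()))
                if len(vals) < 2:
                    logger.warning(
                        "%s/%s/%s: fewer than 2 values; significance bar "
                        "suppressed", metric, roi, cond,
                    )
            label = None
            if not stats.empty:
                row = stats[
                    stats["comparison"] == f"{metric} {roi}: sham vs tbi"
                ]
                if len(row) == 1 and np.isfinite(row["p_adjusted"].iloc[0]):
                    n_groups = json.loads(row["n_per_group"].iloc[0] or "{}")
                    if all(n >= 2 for n in n_groups.values()):
                        label = _sig_label(float(row["p_adjusted"].iloc[0]))
            if label and np.isfinite(ymax):
                y = ymax * 1.08 if ymax != 0 else 1.0
                ax.plot([0, 1], [y, y], "k-", lw=1)
                ax.text(0.5, y, label, ha="center", va="bottom")
            ax.set_xticks([0, 1], ["sham", "TBI"])
            ax.set_xlim(-0.5, 1.5)
            ax.set_title(roi)
        axes[0].set_ylabel(metric.replace("_", " "))
        fig.tight_layout()
        path = output_dir / f"scatter_{metric}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    if timeseries_csv is not None and Path(timeseries_csv).exists():
        ts = pd.read_csv(timeseries_csv)
        fig, axes = plt.subplots(
            1, len(rois), figsize=(3.0 * len(rois), 3.0), sharex=True
        )
        axes = np.atleast_1d(axes)
        for ax, roi in zip(axes, rois):
            sub = ts[ts["roi_name"] == roi]
            for cond in ("sham", "tbi"):
                g = sub[sub["condition"] == cond]
                if g.empty:
                    continue
                mean = g.groupby("time_min")["normalized_intensity"].mean()
                ax.plot(mean.index, mean.values, color=_COLORS[cond], label=cond)
            ax.set_title(roi)
            ax.set_xlabel("time (min)")
        axes[0].set_ylabel("normalized intensity")
        axes[-1].legend(frameon=False)
        fig.tight_layout()
        path = output_dir / "timecourse_normalized_intensity.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
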