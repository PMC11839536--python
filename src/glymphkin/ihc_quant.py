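"""Corrected-total-fluorescence quantification of IHC images.

A region's fluorescence is summarised by the corrected total fluorescence

    CTF = integrated density - area * mean(background),

i.e. the summed intensity inside the region mask minus what a region of
that size would accumulate from background alone.  CTF is exactly
invariant to adding a constant offset to the whole image and exactly
linear in a global gain factor; negative values (regions dimmer than
background) are preserved, never clipped.

Left and right hemisphere measurements of the same (section, coronal
level, region) are averaged, giving one value per cortical region per
coronal section; per-animal means over sections are also provided for
analyses that treat the animal as the experimental unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceMeasurement",
    "corrected_total_fluorescence",
    "bilateral_average",
    "bilateral_average_table",
    "per_animal_means",
]

CORONAL_LEVELS = ("FC", "LLV", "PPC")
CORTICAL_REGIONS = ("DC", "LC", "VC")


@dataclass(frozen=True)
class FluorescenceMeasurement:
    """One region's fluorescence summary on one section side.

    ``ctf = integrated_density - area * background_mean`` holds exactly by
    construction.
    """

    section_id: str
    coronal_level: str
    region: str
    side: str
    integrated_density: float
    area: int
    background_mean: float
    ctf: float


def corrected_total_fluorescence(
    image: np.ndarray,
    region_mask: np.ndarray,
    background_mask: np.ndarray,
    section_id: str = "",
    coronal_level: str = "",
    region: str = "",
    side: str = "",
) -> FluorescenceMeasurement:
    """Measure a region's corrected total fluorescence.

    ``region_mask`` selects the pixels whose intensities are summed
    (integrated density); ``background_mask`` selects a disjoint reference
    area whose mean estimates the background level.  Masks must be
    non-empty, disjoint and shaped like the image.
    """
    image = np.asarray(image, dtype=np.float64)
    region_mask = np.asarray(region_mask, bool)
    background_mask = np.asarray(background_mask, bool)
    if region_mask.shape != image.shape or background_mask.shape != image.shape:
        raise ValueError("mask shapes must match the image")
    if not region_mask.any():
        raise ValueError("region mask selects no pixels")
    if not background_mask.any():
        raise ValueError("background mask selects no pixels")
    if (region_mask & background_mask).any():
        raise ValueError("region and background masks overlap")

    integrated = float(image[region_mask].sum())
    area = int(region_mask.sum())
    background_mean = float(image[background_mask].mean())
    ctf = integrated - area * background_mean
    return FluorescenceMeasurement(
        section_id=section_id,
        coronal_level=coronal_level,
        region=region,
        side=side,
        integrated_density=integrated,
        area=area,
        background_mean=background_mean,
        ctf=ctf,
    )


def bilateral_average(left: float | None, right: float | None) -> float:
    """Arithmetic mean of the left- and right-side CTF of one region.

    Both sides must be present; a missing side raises rather than silently
    passing the other through.
    """
    if left is None or right is None:
        raise ValueError("both left and right measurements are required")
    return (float(left) + float(right)) / 2.0


def bilateral_average_table(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long CTF table over hemispheres.

    Expects columns ``animal_id, section_id, coronal_level, region, side,
    ctf`` and returns one row per (animal, section, level, region) with the
    bilateral mean.  Every group must have exactly a left and a right
    measurement.
    """
    keys = ["animal_id", "section_id", "coronal_level", "region"]
    rows = []
    for group_keys, g in df.groupby(keys, sort=True):
        sides = set(g["side"])
        if sides != {"left", "right"}:
            raise ValueError(
                f"group {dict(zip(keys, group_keys))} has sides {sorted(sides)}; "
                "need exactly left and right"
            )
        left = float(g.loc[g["side"] == "left", "ctf"].mean())
        right = float(g.loc[g["side"] == "right", "ctf"].mean())
        rows.append(dict(zip(keys, group_keys)) | {"ctf": bilateral_average(left, right)})
    return pd.DataFrame(rows)


def per_animal_means(df: pd.DataFrame) -> pd.DataFrame:
    """Mean CTF per (animal, coronal level, region) across sections."""
    keys = ["animal_id", "coronal_level", "region"]
    return df.groupby(keys, sort=True, as_index=False)["ctf"].mean()
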