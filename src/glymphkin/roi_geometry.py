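"""Circular ROI layouts on the dorsal imaging field.

Coordinate convention used throughout the package: ``x`` increases toward
the anterior (rostral) direction, ``y`` increases toward the animal's left,
the origin sits at bregma, and all distances are in millimetres.  Images are
indexed ``(row, col)`` with the centre of pixel ``(r, c)`` at physical
position ``field_origin + ((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)``;
``field_origin`` is the physical position of the field's posterior-right
corner.

The standard layout places six circular regions on the exposed skull:

* ``IS`` — injection site (right lateral ventricle burr hole),
* ``LLV`` — left lateral ventricle, the contralateral mirror of IS,
* ``APC``/``PPC`` — anterior/posterior parietal cortex, 2.6 mm anterior and
  posterior of LLV along the rostro-caudal axis,
* ``FC`` — frontal cortex on the IS–LLV midline, +4.5 mm rostral of bregma,
* ``background`` — a small (0.1 mm) reference circle far from all analysis
  regions, used for noise normalisation.

Analysis circles default to 2 mm diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ANALYSIS_ROIS",
    "ROI_NAMES",
    "ROISpec",
    "FieldGeometry",
    "ROILayout",
    "build_roi_layout",
    "rasterize_roi",
    "layout_to_dict",
    "layout_from_dict",
    "save_layout",
    "load_layout",
]

ANALYSIS_ROIS = ("FC", "APC", "LLV", "IS", "PPC")
ROI_NAMES = ANALYSIS_ROIS + ("background",)

DEFAULT_ROI_DIAMETER_MM = 2.0
BACKGROUND_DIAMETER_MM = 0.1
ROI_SPACING_MM = 2.6
FC_ROSTRAL_MM = 4.5


class LayoutError(ValueError):
    """Raised when a ROI layout cannot be constructed or validated."""


@dataclass(frozen=True)
class ROISpec:
    """One named circular region: centre ``(x, y)`` in mm and diameter in mm."""

    name: str
    center: tuple[float, float]
    diameter: float

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise LayoutError(f"ROI {self.name!r}: diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class FieldGeometry:
    """Physical footprint of the imaging field.

    ``origin`` is the (x, y) position of the field corner that pixel (0, 0)
    touches; the field spans ``shape[1] * pixel_size`` mm along x and
    ``shape[0] * pixel_size`` mm along y.
    """

    origin: tuple[float, float]
    shape: tuple[int, int]
    pixel_size: float

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the field in mm."""
        x0, y0 = self.origin
        ny, nx = self.shape
        return (x0, x0 + nx * self.pixel_size, y0, y0 + ny * self.pixel_size)

    def contains_circle(self, roi: ROISpec) -> bool:
        x_min, x_max, y_min, y_max = self.extent
        x, y = roi.center
        r = roi.radius
        return (
            x - r >= x_min and x + r <= x_max and y - r >= y_min and y + r <= y_max
        )


@dataclass
class ROILayout:
    """The six named circles plus the anatomical anchors they derive from."""

    rois: dict[str, ROISpec]
    injection_site: tuple[float, float]
    bregma: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in ROI_NAMES if n not in self.rois]
        extra = [n for n in self.rois if n not in ROI_NAMES]
        if missing or extra:
            raise LayoutError(
                f"layout must contain exactly {ROI_NAMES}; "
                f"missing={missing} unexpected={extra}"
            )

    def __getitem__(self, name: str) -> ROISpec:
        return self.rois[name]

    @property
    def analysis_rois(self) -> list[ROISpec]:
        return [self.rois[n] for n in ANALYSIS_ROIS]


def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def build_roi_layout(
    injection_site: tuple[float, float],
    bregma: tuple[float, float] = (0.0, 0.0),
    field: FieldGeometry | None = None,
    roi_diameter: float = DEFAULT_ROI_DIAMETER_MM,
    background_diameter: float = BACKGROUND_DIAMETER_MM,
    spacing_mode: str = "center",
) -> ROILayout:
    """Derive the standard six-ROI layout from the injection site and bregma.

    Placement rules:

    * IS at the injection site.
    * LLV is the mirror of IS across the rostro-caudal midline through
      bregma (the contralateral homologue); with the stereotaxic 1.3-mm
      lateral offset this puts LLV 2.6 mm from IS.
    * APC = LLV + 2.6 mm anterior; PPC = LLV - 2.6 mm anterior.  With
      ``spacing_mode="edge"`` the 2.6 mm is measured between circle
      perimeters instead of centres.
    * FC on the IS–LLV midline (y = bregma_y) at +4.5 mm rostral of bregma.
    * background at whichever field corner maximises the clearance to the
      analysis circles (deterministic tie-break by corner order); if no
      field is given, a fixed fallback 2 mm posterior-right of the
      posterior-most/right-most analysis circle is used.

    Raises :class:`LayoutError`, naming the offending ROI, if any circle
    falls outside the imaging field.
    """
    if spacing_mode not in ("center", "edge"):
        raise LayoutError(f"unknown spacing_mode {spacing_mode!r}")
    is_x, is_y = float(injection_site[0]), float(injection_site[1])
    bx, by = float(bregma[0]), float(bregma[1])

    llv = (is_x, 2.0 * by - is_y)
    offset = ROI_SPACING_MM
    if spacing_mode == "edge":
        offset = ROI_SPACING_MM + roi_diameter  # gap between perimeters
    apc = (llv[0] + offset, llv[1])
    ppc = (llv[0] - offset, llv[1])
    fc = (bx + FC_ROSTRAL_MM, by)

    rois = {
        "FC": ROISpec("FC", fc, roi_diameter),
        "APC": ROISpec("APC", apc, roi_diameter),
        "LLV": ROISpec("LLV", llv, roi_diameter),
        "IS": ROISpec("IS", (is_x, is_y), roi_diameter),
        "PPC": ROISpec("PPC", ppc, roi_diameter),
    }

    if field is not None:
        for roi in rois.values():
            if not field.contains_circle(roi):
                raise LayoutError(
                    f"ROI {roi.name!r} at {roi.center} (d={roi.diameter} mm) "
                    f"does not fit inside the imaging field {field.extent}"
                )
        background = _place_background(rois.values(), field, background_diameter)
    else:
        x_min = min(r.center[0] for r in rois.values())
        y_min = min(r.center[1] for r in rois.values())
        background = ROISpec(
            "background", (x_min - 2.0, y_min - 2.0), background_diameter
        )

    clearance = min(
        _dist(background.center, r.center) - r.radius - background.radius
        for r in rois.values()
    )
    if clearance <= 0:
        raise LayoutError("background circle intersects an analysis ROI")
    rois["background"] = background
    return ROILayout(
        rois=rois,
        injection_site=(is_x, is_y),
        bregma=(bx, by),
        metadata={"spacing_mode": spacing_mode},
    )


def _place_background(
    rois, field: FieldGeometry, diameter: float
) -> ROISpec:
    """Pick the field corner (inset by the circle radius) farthest from all ROIs."""
    x_min, x_max, y_min, y_max = field.extent
    r = diameter / 2.0
    corners = [
        (x_min + r, y_min + r),
        (x_max - r, y_min + r),
        (x_min + r, y_max - r),
        (x_max - r, y_max - r),
    ]
    best = None
    best_clearance = -math.inf
    for c in corners:
        clearance = min(
            _dist(c, roi.center) - roi.radius - r for roi in rois
        )
        if clearance > best_clearance + 1e-12:
            best, best_clearance = c, clearance
    return ROISpec("background", best, diameter)


def rasterize_roi(
    roi: ROISpec,
    pixel_size: float,
    grid_shape: tuple[int, int],
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rasterize a circle to a boolean mask.

    A pixel belongs to the mask when its centre lies within the circle
    (distance to the ROI centre <= radius).  Pixel (r, c) has its centre at
    ``origin + ((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)``.

    Raises :class:`LayoutError` if no pixel centre falls inside the circle
    (the caller should use a finer pixel_size).
    """
    if pixel_size <= 0:
        raise LayoutError("pixel_size must be > 0")
    ny, nx = grid_shape
    xs = origin[0] + (np.arange(nx) + 0.5) * pixel_size
    ys = origin[1] + (np.arange(ny) + 0.5) * pixel_size
    dx = xs[np.newaxis, :] - roi.center[0]
    dy = ys[:, np.newaxis] - roi.center[1]
    mask = dx * dx + dy * dy <= roi.radius**2
    if not mask.any():
        raise LayoutError(
            f"ROI {roi.name!r} rasterizes to an empty mask at pixel_size "
            f"{pixel_size} mm/px; use a finer pixel_size"
        )
    return mask


def layout_to_dict(layout: ROILayout) -> dict:
    return {
        "injection_site_mm": list(layout.injection_site),
        "bregma_mm": list(layout.bregma),
        "rois": {
            name: {"center_mm": list(roi.center), "diameter_mm": roi.diameter}
            for name, roi in layout.rois.items()
        },
        "metadata": dict(layout.metadata),
    }


def layout_from_dict(d: dict) -> ROILayout:
    rois = {
        name: ROISpec(name, tuple(v["center_mm"]), float(v["diameter_mm"]))
        for name, v in d["rois"].items()
    }
    return ROILayout(
        rois=rois,
        injection_site=tuple(d["injection_site_mm"]),
        bregma=tuple(d["bregma_mm"]),
        metadata=dict(d.get("metadata", {})),
    )


def save_layout(layout: ROILayout, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout_to_dict(layout), fh, sort_keys=True)


def load_layout(path) -> ROILayout:
    with open(path) as fh:
        return layout_from_dict(yaml.safe_load(fh))
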