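"""Region-of-interest geometry for en-face OCTA scans.

Peripapillary and macular vessel metrics are computed inside an annulus
centered on the optic disc (outer diameter 1.375 mm, inner diameter 0.5 mm)
or on the foveal avascular zone (outer 1.375 mm, inner 0.75 mm), further
partitioned into four disc quadrants (S, N, I, T) or six macular sectors
(S, SN, ST, I, IN, IT).  This module converts between physical (mm) and
pixel coordinates and rasterizes those ROIs into boolean / integer label
masks.

Conventions
-----------
* Image row 0 is anatomically superior; the physical origin is the image
  center unless an explicit center is supplied; coordinates are 0-based.
* Distance and angle tests use pixel *centers*.
* The annulus interval is half-open, ``inner_radius <= d < outer_radius``,
  so concentric rings and adjacent sectors are disjoint.
* Angles are measured with 90 deg at image top (anatomically superior) and
  increase counter-clockwise in physical (x right, y up) coordinates.
* Nasal/temporal labels flip with eye laterality: for a right eye (OD) the
  nasal retina is displayed on image-left (180 deg), for a left eye (OS) on
  image-right (0 deg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ImageGrid",
    "AnnulusROI",
    "SectorPartition",
    "DISC_ANNULUS",
    "MACULA_ANNULUS",
    "make_annulus_mask",
    "partition_sectors",
    "mm_to_px",
    "pixel_coords_mm",
    "save_label_mask_png",
    "roi_from_json",
]

QUADRANT_LABELS = ("S", "N", "I", "T")
MACULA_LABELS = ("S", "SN", "ST", "I", "IN", "IT")


class EmptyROIError(ValueError):
    """Raised when an ROI rasterizes to an empty pixel set."""


@dataclass(frozen=True)
class ImageGrid:
    """Pixel grid of a square en-face scan with physical extent.

    Parameters
    ----------
    height_px, width_px
        Grid dimensions in pixels.  Standard scans are square.
    extent_mm
        Physical side length of the field of view; 3.0 mm for the
        3x3 mm^2 scans used throughout.
    """

    height_px: int
    width_px: int
    extent_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")

    @property
    def pixel_size_mm(self) -> float:
        return self.extent_mm / self.width_px

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass(frozen=True)
class AnnulusROI:
    """Annular ROI in physical coordinates (mm), origin at image center.

    ``center_mm`` is (x, y) with x to the right and y up (superior).
    ``inner_diameter_mm`` may be 0, degenerating to a filled disc.
    """

    inner_diameter_mm: float
    outer_diameter_mm: float
    center_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.inner_diameter_mm < 0:
            raise ValueError("inner diameter must be nonnegative")
        if self.outer_diameter_mm <= 0:
            raise ValueError("outer diameter must be positive")
        if self.inner_diameter_mm >= self.outer_diameter_mm:
            raise ValueError("inner diameter must be < outer diameter")


#: Disc ROI: outer diameter 1.375 mm, inner 0.5 mm, centered on the disc.
DISC_ANNULUS = AnnulusROI(inner_diameter_mm=0.5, outer_diameter_mm=1.375)
#: Macular ROI: outer diameter 1.375 mm, inner 0.75 mm, centered on the FAZ.
MACULA_ANNULUS = AnnulusROI(inner_diameter_mm=0.75, outer_diameter_mm=1.375)


def _quadrant_bounds(laterality: str) -> dict[str, tuple[float, float]]:
    # S/I on the 45-deg diagonals; N/T sides depend on laterality.
    nasal_left = laterality == "OD"
    side_left, side_right = ("N", "T") if nasal_left else ("T", "N")
    return {
        "S": (45.0, 135.0),
        side_left: (135.0, 225.0),
        "I": (225.0, 315.0),
        side_right: (315.0, 405.0),  # wraps through 0
    }


def _macula_bounds(laterality: str) -> dict[str, tuple[float, float]]:
    # Superior and inferior hemifields each split into three 60-deg sectors;
    # S and I occupy the vertical middle, flanked nasally and temporally.
    nasal_left = laterality == "OD"
    if nasal_left:
        st, sn = (0.0, 60.0), (120.0, 180.0)
        in_, it = (180.0, 240.0), (300.0, 360.0)
    else:
        sn, st = (0.0, 60.0), (120.0, 180.0)
        it, in_ = (180.0, 240.0), (300.0, 360.0)
    return {
        "S": (60.0, 120.0),
        "SN": sn,
        "ST": st,
        "I": (240.0, 300.0),
        "IN": in_,
        "IT": it,
    }


@dataclass(frozen=True)
class SectorPartition:
    """Angular partition of an annulus into labeled sectors.

    ``scheme`` is ``"quadrants_4"`` (disc: S, N, I, T) or ``"macula_6"``
    (S, SN, ST, I, IN, IT).  Intervals are half-open ``[lo, hi)`` degrees
    and tile [0, 360) exactly once; nasal/temporal assignment follows
    ``laterality`` (OD or OS).
    """

    scheme: str = "quadrants_4"
    laterality: str = "OD"
    labels: tuple[str, ...] = field(init=False)
    angular_bounds_deg: dict[str, tuple[float, float]] = field(init=False)

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.scheme == "quadrants_4":
            bounds = _quadrant_bounds(self.laterality)
            labels = QUADRANT_LABELS
        elif self.scheme == "macula_6":
            bounds = _macula_bounds(self.laterality)
            labels = MACULA_LABELS
        else:
            raise ValueError(f"unknown sector scheme {self.scheme!r}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "angular_bounds_deg", bounds)

    def flipped(self) -> "SectorPartition":
        """Return the same partition for the fellow eye."""
        other = "OS" if self.laterality == "OD" else "OD"
        return SectorPartition(scheme=self.scheme, laterality=other)


def mm_to_px(grid: ImageGrid, length_mm: float) -> float:
    """Convert a physical length to pixels on ``grid``."""
    if length_mm < 0:
        raise ValueError("length_mm must be nonnegative")
    return length_mm / grid.pixel_size_mm


def pixel_coords_mm(grid: ImageGrid) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates of every pixel center, origin at image
    center, y increasing toward the superior (row 0) edge."""
    px = grid.pixel_size_mm
    rows, cols = np.mgrid[0 : grid.height_px, 0 : grid.width_px]
    x = (cols + 0.5) * px - grid.extent_mm / 2.0
    y = grid.height_px * px / 2.0 - (rows + 0.5) * px
    return x, y


def make_annulus_mask(
    grid: ImageGrid, roi: AnnulusROI
) -> tuple[np.ndarray, bool]:
    """Rasterize an annulus into a boolean mask.

    Returns ``(mask, clipped)`` where ``clipped`` is True when the outer
    circle extends beyond the image extent.  A pixel is in-mask iff its
    center's distance d from the ROI center satisfies
    ``inner_radius <= d < outer_radius``.

    Raises
    ------
    EmptyROIError
        If the annulus lies entirely outside the image.
    """
    x, y = pixel_coords_mm(grid)
    cx, cy = roi.center_mm
    d = np.hypot(x - cx, y - cy)
    r_in = roi.inner_diameter_mm / 2.0
    r_out = roi.outer_diameter_mm / 2.0
    mask = (d >= r_in) & (d < r_out)
    if not mask.any():
        raise EmptyROIError("annulus lies entirely outside the image")
    half_w = grid.extent_mm / 2.0
    half_h = grid.height_px * grid.pixel_size_mm / 2.0
    clipped = (
        cx - r_out < -half_w
        or cx + r_out > half_w
        or cy - r_out < -half_h
        or cy + r_out > half_h
    )
    return mask, clipped


def partition_sectors(
    grid: ImageGrid, roi: AnnulusROI, scheme: SectorPartition
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Label every in-annulus pixel with its sector.

    Returns ``(label_mask, labels)``: an int array where 0 means outside
    the annulus and value k (1-based) means sector ``labels[k-1]``.  The
    sectors are a disjoint exact cover of the annulus mask.
    """
    mask, _ = make_annulus_mask(grid, roi)
    x, y = pixel_coords_mm(grid)
    cx, cy = roi.center_mm
    theta = np.degrees(np.arctan2(y - cy, x - cx)) % 360.0
    out = np.zeros(grid.shape, dtype=np.uint8)
    for k, label in enumerate(scheme.labels, start=1):
        lo, hi = scheme.angular_bounds_deg[label]
        if hi <= 360.0:
            sel = (theta >= lo) & (theta < hi)
        else:  # interval wraps through 0 deg
            sel = (theta >= lo) | (theta < hi - 360.0)
        out[mask & sel] = k
    return out, scheme.labels


def roi_from_json(payload: str | dict) -> tuple[AnnulusROI, SectorPartition]:
    """Build an ROI from a JSON config.

    Schema: ``{"scheme", "center_mm", "inner_diameter_mm",
    "outer_diameter_mm", "laterality"}``.
    """
    cfg = json.loads(payload) if isinstance(payload, str) else dict(payload)
    roi = AnnulusROI(
        inner_diameter_mm=float(cfg["inner_diameter_mm"]),
        outer_diameter_mm=float(cfg["outer_diameter_mm"]),
        center_mm=tuple(cfg.get("center_mm", (0.0, 0.0))),
    )
    part = SectorPartition(
        scheme=cfg.get("scheme", "quadrants_4"),
        laterality=cfg.get("laterality", "OD"),
    )
    return roi, part


def save_label_mask_png(label_mask: np.ndarray, path) -> None:
    """Write a sector label mask as an 8-bit palette-style PNG (labels map
    to fixed gray levels, 0 = background)."""
    import imageio.v3 as iio

    scaled = (label_mask.astype(np.uint16) * 36).clip(0, 255).astype(np.uint8)
    iio.imwrite(path, scaled)
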