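"""Synthetic OCTA phantoms and diabetic-retinopathy cohorts.

Two generators make the whole pipeline testable without patient data:

* **Vessel-network phantoms** — procedural branching vessel trees
  (random-walk centerlines with per-branch widths) rendered over a dark
  background with optional Gaussian speckle, returned together with their
  noise-free ground-truth vessel and large-vessel masks.  A grade series
  emulates progressive capillary dropout: higher retinopathy grades delete
  a larger (nested) fraction of capillary branches, so measured vessel
  area density is monotone nonincreasing across the series.

* **Synthetic cohorts** — per-eye records sampled from grade-conditional
  Gaussian marginals whose means/sds are the published per-grade lab and
  OCT thickness summaries (see ``LAB_DISTRIBUTIONS`` and
  ``OCT_DISTRIBUTIONS``), truncated at physiologic floors.  A per-eye
  latent vascular factor couples RNFL thickness and the disc OCTA metrics
  at a configurable level, so correlation-recovery is testable against a
  known ground truth; renal analytes (Cr, BUN, EGFR) share a renal latent
  factor.  Baseline acuity is sampled on the Snellen chart with a
  grade-dependent spread, and follow-up acuity worsens by two or more
  chart lines with a per-grade probability.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clinical_metrics import DEFAULT_CHART, LAB_ANALYTES
from .octa_quant import FlowImage, VesselMaps, perimeter_map, skeletonize
from .roi_geometry import ImageGrid

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "CohortConfig",
    "LAB_DISTRIBUTIONS",
    "OCT_DISTRIBUTIONS",
    "GRADES",
    "generate_phantom",
    "generate_grade_series",
    "generate_cohort",
    "implied_spearman_rho",
    "write_phantom",
]

GRADES = ("Ctrl", "DR0", "DR1", "DR2", "DR3", "DR4")

# Per-grade lab summaries, mean (sd), used as sampling parameters.
# Columns: Control, DR0..DR4.
LAB_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "Glucose":      {"Ctrl": (118.60, 63.41), "DR0": (140.80, 39.41), "DR1": (143.08, 35.91), "DR2": (156.14, 45.73), "DR3": (180.50, 16.45), "DR4": (147.30, 38.59)},
    "A1c":          {"Ctrl": (6.04, 1.42),    "DR0": (6.91, 1.15),    "DR1": (7.60, 1.62),    "DR2": (7.60, 1.30),    "DR3": (9.53, 0.12),    "DR4": (7.65, 1.44)},
    "Albumin":      {"Ctrl": (4.18, 0.33),    "DR0": (4.10, 0.34),    "DR1": (3.96, 0.41),    "DR2": (3.79, 0.53),    "DR3": (4.10, 0.35),    "DR4": (3.87, 0.27)},
    "Cr":           {"Ctrl": (0.81, 0.19),    "DR0": (0.95, 0.30),    "DR1": (0.90, 0.29),    "DR2": (0.95, 0.26),    "DR3": (1.03, 0.40),    "DR4": (2.54, 2.54)},
    "EGFR":         {"Ctrl": (101.26, 25.30), "DR0": (87.56, 23.54),  "DR1": (89.62, 18.76),  "DR2": (81.36, 21.80),  "DR3": (80.67, 28.00),  "DR4": (41.80, 27.18)},
    "BUN":          {"Ctrl": (14.66, 4.29),   "DR0": (18.30, 7.57),   "DR1": (19.00, 7.15),   "DR2": (18.77, 3.10),   "DR3": (25.00, 5.20),   "DR4": (39.60, 14.38)},
    "Protein":      {"Ctrl": (7.32, 0.56),    "DR0": (7.45, 0.35),    "DR1": (7.32, 0.36),    "DR2": (7.34, 0.43),    "DR3": (6.77, 0.29),    "DR4": (7.24, 0.47)},
    "Globulin":     {"Ctrl": (3.14, 0.65),    "DR0": (3.40, 0.58),    "DR1": (3.40, 0.65),    "DR2": (3.54, 0.78),    "DR3": (2.73, 0.58),    "DR4": (3.30, 0.58)},
    "Alk Phos":     {"Ctrl": (74.26, 23.74),  "DR0": (76.51, 19.39),  "DR1": (77.58, 32.13),  "DR2": (86.64, 24.54),  "DR3": (98.00, 38.11),  "DR4": (80.40, 23.54)},
    "ALT":          {"Ctrl": (31.96, 16.23),  "DR0": (30.79, 11.88),  "DR1": (31.08, 15.04),  "DR2": (22.00, 8.23),   "DR3": (25.17, 12.41),  "DR4": (32.60, 17.67)},
    "AST":          {"Ctrl": (25.14, 8.47),   "DR0": (24.03, 6.01),   "DR1": (24.58, 7.32),   "DR2": (22.64, 4.79),   "DR3": (16.83, 3.18),   "DR4": (28.10, 12.28)},
    "Bili":         {"Ctrl": (0.53, 0.22),    "DR0": (0.50, 0.28),    "DR1": (0.51, 0.27),    "DR2": (0.45, 0.32),    "DR3": (0.50, 0.01),    "DR4": (0.40, 0.12)},
    "K":            {"Ctrl": (4.16, 0.35),    "DR0": (4.40, 0.36),    "DR1": (4.36, 0.21),    "DR2": (4.27, 0.38),    "DR3": (4.43, 0.46),    "DR4": (4.86, 0.46)},
    "Ca":           {"Ctrl": (9.23, 0.34),    "DR0": (9.44, 0.38),    "DR1": (9.30, 0.35),    "DR2": (9.16, 0.43),    "DR3": (9.30, 0.17),    "DR4": (9.48, 0.48)},
    "Cl":           {"Ctrl": (102.06, 2.73),  "DR0": (102.08, 2.49),  "DR1": (102.12, 2.00),  "DR2": (102.36, 2.51),  "DR3": (104.17, 0.29),  "DR4": (102.20, 4.31)},
    "Na":           {"Ctrl": (138.64, 2.48),  "DR0": (138.57, 1.96),  "DR1": (138.85, 1.51),  "DR2": (138.50, 1.32),  "DR3": (140.33, 1.15),  "DR4": (138.90, 1.67)},
    "CO2":          {"Ctrl": (28.22, 1.71),   "DR0": (27.04, 2.17),   "DR1": (28.15, 2.22),   "DR2": (27.73, 3.24),   "DR3": (30.00, 1.73),   "DR4": (27.38, 3.35)},
    "Hgb":          {"Ctrl": (13.53, 0.95),   "DR0": (12.85, 1.90),   "DR1": (13.47, 0.94),   "DR2": (13.18, 1.73),   "DR3": (13.57, 0.23),   "DR4": (12.37, 0.85)},
    "RDW":          {"Ctrl": (13.35, 0.86),   "DR0": (13.92, 1.28),   "DR1": (13.68, 1.27),   "DR2": (14.61, 1.41),   "DR3": (14.53, 0.29),   "DR4": (13.32, 0.29)},
    "Hct":          {"Ctrl": (40.40, 2.80),   "DR0": (39.67, 4.63),   "DR1": (41.58, 2.71),   "DR2": (39.59, 4.78),   "DR3": (42.75, 2.42),   "DR4": (37.19, 2.63)},
    "Chol-HDL":     {"Ctrl": (40.57, 14.00),  "DR0": (31.36, 12.69),  "DR1": (29.48, 14.32),  "DR2": (26.05, 10.61),  "DR3": (41.33, 1.15),   "DR4": (31.10, 9.34)},
    "Chol-LDL":     {"Ctrl": (97.37, 25.15),  "DR0": (75.92, 28.82),  "DR1": (69.92, 22.46),  "DR2": (90.41, 43.48),  "DR3": (85.33, 21.36),  "DR4": (87.80, 30.47)},
    "Chol-Non-HDL": {"Ctrl": (125.94, 32.09), "DR0": (104.37, 29.73), "DR1": (85.69, 13.06),  "DR2": (114.86, 38.62), "DR3": (113.67, 6.35),  "DR4": (111.20, 29.41)},
    "Chol":         {"Ctrl": (182.32, 39.06), "DR0": (146.16, 34.23), "DR1": (127.19, 29.85), "DR2": (143.55, 36.49), "DR3": (153.83, 13.28), "DR4": (147.60, 22.19)},
}

# Per-grade OCT thickness summaries (um), mean (sd); controls reuse DR0
# values (the published table covers DR0-DR4 only).
_RNFL = {
    "T":     {"DR0": (64.52, 12.44), "DR1": (59.61, 13.42), "DR2": (59.79, 13.09), "DR3": (67.18, 16.35), "DR4": (62.03, 9.46)},
    "S":     {"DR0": (115.37, 18.50), "DR1": (111.39, 17.06), "DR2": (101.77, 25.72), "DR3": (106.75, 22.40), "DR4": (106.44, 21.60)},
    "N":     {"DR0": (77.50, 59.55), "DR1": (68.83, 12.36), "DR2": (63.59, 8.47), "DR3": (76.17, 23.25), "DR4": (61.35, 11.05)},
    "I":     {"DR0": (119.56, 18.65), "DR1": (114.78, 11.97), "DR2": (109.08, 18.13), "DR3": (106.03, 27.96), "DR4": (106.57, 25.19)},
    "whole": {"DR0": (92.19, 13.80), "DR1": (88.61, 10.08), "DR2": (84.37, 13.79), "DR3": (93.87, 18.65), "DR4": (84.52, 14.98)},
}
_GCC = {
    "ST":    {"DR0": (84.51, 10.57), "DR1": (82.20, 11.50), "DR2": (83.94, 10.21), "DR3": (95.75, 5.12), "DR4": (74.53, 23.07)},
    "S":     {"DR0": (81.36, 9.02), "DR1": (77.20, 9.46), "DR2": (74.62, 16.25), "DR3": (85.38, 9.62), "DR4": (68.20, 22.84)},
    "SN":    {"DR0": (85.69, 11.51), "DR1": (82.05, 11.84), "DR2": (75.71, 26.83), "DR3": (90.38, 9.35), "DR4": (73.53, 26.91)},
    "IT":    {"DR0": (82.29, 10.83), "DR1": (79.95, 10.88), "DR2": (82.12, 11.36), "DR3": (97.00, 11.88), "DR4": (71.47, 22.56)},
    "I":     {"DR0": (79.69, 10.08), "DR1": (76.35, 9.80), "DR2": (76.31, 17.24), "DR3": (78.75, 10.26), "DR4": (65.60, 25.25)},
    "IN":    {"DR0": (82.16, 11.70), "DR1": (76.70, 10.55), "DR2": (72.41, 24.40), "DR3": (85.38, 8.11), "DR4": (69.87, 22.12)},
    "whole": {"DR0": (80.74, 7.87), "DR1": (77.95, 5.93), "DR2": (73.71, 20.93), "DR3": (87.50, 6.57), "DR4": (70.87, 20.95)},
}

OCT_DISTRIBUTIONS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "rnfl": {
        region: {**{"Ctrl": grades["DR0"]}, **grades} for region, grades in _RNFL.items()
    },
    "gcc": {
        region: {**{"Ctrl": grades["DR0"]}, **grades} for region, grades in _GCC.items()
    },
}

# Baseline OCTA metric levels for the synthetic cohort (not published
# summaries; chosen as realistic capillary-bed values at 10 um/px, with a
# multiplicative per-grade decline emulating microvascular dropout).
_OCTA_BASE = {"vad": 0.42, "vsd": 0.16, "vdi": 2.6, "vpi": 0.30, "vci": 1.9, "flux": 0.45}
_OCTA_REL_SD = 0.10
_OCTA_GRADE_DECLINE = 0.04  # fractional drop per DR grade step

DISC_REGIONS = ("whole", "S", "N", "I", "T")
MACULA_REGIONS = ("whole", "S", "SN", "ST", "I", "IN", "IT")

_ANALYTE_FLOORS = {"EGFR": 5.0}
_RENAL_BLOCK = {"Cr": +1.0, "BUN": +1.0, "EGFR": -1.0}


# --------------------------------------------------------------------------
# Phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a procedural vessel-network phantom."""

    grid: ImageGrid = ImageGrid(300, 300, 3.0)
    n_trunks: int = 3
    trunk_width_px: int = 10
    branch_width_px: int = 2
    branching_probability: float = 0.03
    capillary_density: float = 0.25
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trunk_width_px < 1 or self.branch_width_px < 1:
            raise ValueError("vessel widths must be >= 1 px")
        if not (0.0 <= self.capillary_density <= 1.0):
            raise ValueError("capillary_density must lie in [0, 1]")
        if self.capillary_density > 0.9:
            raise ValueError("capillary_density > 0.9 is unsatisfiable")


@dataclass(frozen=True)
class PhantomResult:
    """A rendered phantom with its noise-free ground truth."""

    image: FlowImage
    truth: VesselMaps
    spec: PhantomSpec
    capillary_branches: tuple[np.ndarray, ...] = ()  # (n_px, 2) index arrays


def _walk(rng, start, direction, length, shape, turn_sd=0.25):
    """Random-walk centerline with direction persistence; returns (n,2)
    integer row/col coordinates clipped to the grid."""
    pos = np.array(start, dtype=float)
    theta = float(direction)
    pts = []
    for _ in range(length):
        pts.append((pos[0], pos[1]))
        theta += rng.normal(0.0, turn_sd)
        pos += np.array([math.sin(theta), math.cos(theta)])
        if not (0 <= pos[0] < shape[0] and 0 <= pos[1] < shape[1]):
            break
    pts = np.asarray(pts)
    return np.round(pts).astype(int)


def _stamp(canvas: np.ndarray, pts: np.ndarray, width: int) -> None:
    """Draw a path of the given width onto a boolean canvas."""
    r = max(0, (width - 1) // 2)
    extra = width - 1 - 2 * r  # widths are matched exactly for odd widths
    h, w = canvas.shape
    for row, col in pts:
        canvas[max(0, row - r) : min(h, row + r + 1 + extra),
               max(0, col - r) : min(w, col + r + 1 + extra)] = True


def _render_network(spec: PhantomSpec, rng: np.random.Generator):
    """Render trunks + branches (large vessels) and capillaries; returns
    (large_mask, list-of-capillary-pixel-index-arrays)."""
    shape = spec.grid.shape
    large = np.zeros(shape, dtype=bool)
    h, w = shape
    # large trunks: enter from the top edge and cross the field with
    # gentle meandering (disc trunks run roughly vertically)
    for _ in range(spec.n_trunks):
        start_rc = (0.0, float(rng.integers(w // 6, 5 * w // 6)))
        heading = math.atan2(1.0, rng.normal(0, 0.4))  # downward-ish
        pts = _walk(rng, start_rc, heading, int(1.5 * max(shape)), shape, turn_sd=0.08)
        _stamp(large, pts, spec.trunk_width_px)
    # capillary branches: seeded along trunks and at random, added until
    # the requested capillary density is reached (calibration loop)
    branches: list[np.ndarray] = []
    cap = np.zeros(shape, dtype=bool)
    target_px = spec.capillary_density * cap.size
    max_branches = 100_000
    while len(branches) < max_branches:
        realized = (cap & ~large).sum()
        if realized >= target_px:
            break
        start = (float(rng.integers(0, h)), float(rng.integers(0, w)))
        heading = rng.uniform(0, 2 * math.pi)
        length = int(rng.integers(max(shape) // 8, max(shape) // 2))
        pts = _walk(rng, start, heading, length, shape, turn_sd=0.3)
        if len(pts) < 3:
            continue
        sub = np.zeros(shape, dtype=bool)
        _stamp(sub, pts, spec.branch_width_px)
        # secondary branching off this capillary
        for i in range(len(pts)):
            if rng.random() < spec.branching_probability:
                side = heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.2)
                bpts = _walk(rng, tuple(pts[i].astype(float)), side,
                             length // 2, shape, turn_sd=0.3)
                if len(bpts) >= 3:
                    _stamp(sub, bpts, spec.branch_width_px)
        branches.append(np.argwhere(sub))
        cap |= sub
    return large, branches


def _compose(
    spec: PhantomSpec,
    large: np.ndarray,
    branches: Sequence[np.ndarray],
    rng: np.random.Generator,
    intensity_rng: np.random.Generator | None = None,
) -> PhantomResult:
    """Compose flow image + ground truth from a rendered network."""
    shape = spec.grid.shape
    cap = np.zeros(shape, dtype=bool)
    for idx in branches:
        cap[idx[:, 0], idx[:, 1]] = True
    cap &= ~large
    img = np.full(shape, 0.10)
    irng = intensity_rng if intensity_rng is not None else rng
    img[cap] = 0.55 + 0.08 * irng.standard_normal(int(cap.sum()))
    img[large] = 0.85 + 0.05 * irng.standard_normal(int(large.sum()))
    if spec.noise_sd > 0:
        img = img + irng.normal(0.0, spec.noise_sd, shape)
    img = np.clip(img, 0.0, 1.0)
    flow = FlowImage(
        intensities=img, grid=spec.grid, signal_strength_index=9.0,
        eye="OD", target="disc", subject_id=f"phantom-{spec.seed}",
    )
    truth = VesselMaps(
        vessel_mask=cap,
        large_vessel_mask=large,
        skeleton=skeletonize(cap),
        perimeter=perimeter_map(cap),
    )
    return PhantomResult(image=flow, truth=truth, spec=spec,
                         capillary_branches=tuple(np.asarray(b) for b in branches))


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render a branching vessel-network phantom with ground truth.

    Deterministic per ``spec.seed``; realized ground-truth capillary
    density tracks ``spec.capillary_density`` (calibrated by adding
    branches until the target pixel fraction is met).
    """
    rng = np.random.default_rng(spec.seed)
    large, branches = _render_network(spec, rng)
    return _compose(spec, large, branches, rng)


def generate_grade_series(
    base: PhantomSpec, dropout_per_grade: Sequence[float]
) -> list[PhantomResult]:
    """Phantoms for DR0..DRk by nested capillary-branch deletion.

    ``dropout_per_grade`` lists nondecreasing dropout fractions in [0, 1];
    grade g deletes the first ``round(fraction * n_branches)`` branches of
    a fixed random permutation, so deletions are nested and measured
    vessel area density is monotone nonincreasing across the series.
    """
    fr = [float(f) for f in dropout_per_grade]
    if any(f < 0 or f > 1 for f in fr):
        raise ValueError("dropout fractions must lie in [0, 1]")
    if any(b < a for a, b in zip(fr, fr[1:])):
        raise ValueError("dropout fractions must be nondecreasing over grades")
    rng = np.random.default_rng(base.seed)
    large, branches = _render_network(base, rng)
    order = np.random.default_rng(base.seed + 1).permutation(len(branches))
    out = []
    for fraction in fr:
        k = int(round(fraction * len(branches)))
        keep = [branches[i] for i in order[k:]]
        irng = np.random.default_rng(base.seed + 2)  # same speckle each grade
        out.append(_compose(base, large, keep, rng, intensity_rng=irng))
    return out


def write_phantom(result: PhantomResult, out_dir: str | Path) -> dict[str, Path]:
    """Write a phantom as TIFF image + sidecar JSON, with ground-truth
    PNG masks under a ``truth/`` subdirectory (kept apart so the image
    directory can be fed straight to quantification).  The seed is
    embedded in every artifact name and the JSON."""
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    stem = f"phantom_seed{result.spec.seed}"
    paths = {
        "image": out_dir / f"{stem}.tiff",
        "metadata": out_dir / f"{stem}.json",
        "vessel_mask": out_dir / "truth" / f"{stem}_vessels.png",
        "large_vessel_mask": out_dir / "truth" / f"{stem}_large.png",
    }
    tifffile.imwrite(
        paths["image"], (result.image.intensities * 65535).astype(np.uint16)
    )
    iio.imwrite(paths["vessel_mask"],
                (result.truth.vessel_mask * 255).astype(np.uint8))
    iio.imwrite(paths["large_vessel_mask"],
                (result.truth.large_vessel_mask * 255).astype(np.uint8))
    spec = result.spec
    paths["metadata"].write_text(json.dumps({
        "ssi": result.image.signal_strength_index,
        "eye": result.image.eye,
        "target": result.image.target,
        "extent_mm": spec.grid.extent_mm,
        "subject": result.image.subject_id,
        "seed": spec.seed,
        "n_trunks": spec.n_trunks,
        "trunk_width_px": spec.trunk_width_px,
        "branch_width_px": spec.branch_width_px,
        "capillary_density": spec.capillary_density,
        "noise_sd": spec.noise_sd,
    }, indent=2))
    return paths


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Sampling parameters for a synthetic per-eye cohort.

    Defaults mirror the study scale: 95 control eyes and 218 DM eyes
    (split across grades; the per-grade split is a modeling choice since
    per-grade eye counts are not published).  ``latent_coupling`` is the
    loading of the shared per-eye vascular factor on both RNFL thickness
    and disc OCTA metrics; the implied Pearson correlation between any
    coupled pair is ``latent_coupling**2``.
    """

    n_per_grade: dict[str, int] = field(default_factory=lambda: {
        "Ctrl": 95, "DR0": 80, "DR1": 52, "DR2": 44, "DR3": 12, "DR4": 30,
    })
    latent_coupling: float = 0.632  # implied Pearson rho ~ 0.4
    renal_coupling: float = 0.6
    va_worsening_probability: dict[str, float] = field(default_factory=lambda: {
        "Ctrl": 0.0, "DR0": 0.0, "DR1": 0.0, "DR2": 0.0, "DR3": 0.2, "DR4": 0.3,
    })
    followup_years_range: tuple[float, float] = (4.0, 7.0)
    lab_overrides: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    oct_overrides: dict[str, dict[str, dict[str, tuple[float, float]]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for analyte in self.lab_overrides:
            if analyte not in LAB_DISTRIBUTIONS:
                raise ValueError(f"unknown analyte in overrides: {analyte!r}")
        if not (0.0 <= abs(self.latent_coupling) <= 1.0):
            raise ValueError("latent_coupling must lie in [-1, 1]")
        for g, p in self.va_worsening_probability.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"worsening probability for {g} outside [0, 1]")


def implied_spearman_rho(coupling: float) -> float:
    """Spearman rho implied by a latent coupling for bivariate-normal
    margins: rho_s = (6/pi) asin(r/2) with Pearson r = coupling^2."""
    r = coupling**2
    return 6.0 / math.pi * math.asin(r / 2.0)


def _sample_latent_pair(rng, n, coupling):
    """Shared latent z plus two conditionally independent unit-normal
    outputs each loading on z with the given coupling."""
    z = rng.standard_normal(n)
    lam = coupling
    resid = math.sqrt(max(0.0, 1.0 - lam**2))
    return z, lam, resid


_BASELINE_LINE_Q = {"Ctrl": 0.22, "DR0": 0.28, "DR1": 0.38, "DR2": 0.45,
                    "DR3": 0.52, "DR4": 0.60}
_DME_P = {"Ctrl": (1.0, 0.0, 0.0), "DR0": (0.95, 0.03, 0.02),
          "DR1": (0.85, 0.10, 0.05), "DR2": (0.75, 0.15, 0.10),
          "DR3": (0.60, 0.25, 0.15), "DR4": (0.50, 0.30, 0.20)}
_BEST_LINE = DEFAULT_CHART.index("20/20")
_WORST_LINE = len(DEFAULT_CHART) - 1


def _sample_chart_line(rng, grade: str) -> int:
    """Baseline Snellen line: 20/20 plus a geometric number of lines down,
    with a grade-dependent step probability."""
    q = _BASELINE_LINE_Q[grade]
    steps = rng.geometric(1.0 - q) - 1  # support 0, 1, 2, ...
    return min(_BEST_LINE + int(steps), _WORST_LINE)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Sample a synthetic per-eye cohort as a wide DataFrame.

    Columns: subject_id, eye, grade, dr_grade (numeric, NaN for controls),
    dme_grade, va_baseline, va_followup, followup_years, rnfl_* and gcc_*
    thicknesses (um), octa_disc_<metric>_<region> and
    octa_mac_<metric>_<region> vessel metrics, lab_<analyte> values.

    Grade-conditional Gaussians are truncated (clipped) at physiologic
    floors; a per-eye latent factor couples RNFL and disc OCTA metrics at
    ``config.latent_coupling``; Cr/BUN/EGFR share a renal factor.
    Deterministic per ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lab_dists = {**LAB_DISTRIBUTIONS, **config.lab_overrides}
    oct_dists = {
        kind: {**OCT_DISTRIBUTIONS[kind], **config.oct_overrides.get(kind, {})}
        for kind in OCT_DISTRIBUTIONS
    }
    rows = []
    eye_counter = 0
    for grade in GRADES:
        n = int(config.n_per_grade.get(grade, 0))
        if n == 0:
            continue
        z_vasc, lam, resid = _sample_latent_pair(rng, n, config.latent_coupling)
        z_renal = rng.standard_normal(n)
        dr_numeric = float(grade[2:]) if grade.startswith("DR") else np.nan
        grade_step = 0.0 if grade == "Ctrl" else float(grade[2:])
        for i in range(n):
            eye_counter += 1
            rec: dict = {
                "subject_id": f"SYN{eye_counter:04d}",
                "eye": "OD" if rng.random() < 0.5 else "OS",
                "grade": grade,
                "dr_grade": dr_numeric,
            }
            p0, p1, p2 = _DME_P[grade]
            rec["dme_grade"] = int(rng.choice(3, p=[p0, p1, p2]))
            # visual acuity on the Snellen chart
            base_line = _sample_chart_line(rng, grade)
            p_worse = config.va_worsening_probability.get(grade, 0.0)
            if rng.random() < p_worse:
                drop = 2 + int(rng.geometric(0.6) - 1)
                fu_line = min(base_line + drop, _WORST_LINE)
            else:
                fu_line = base_line + int(rng.choice([-1, 0, 1], p=[0.15, 0.7, 0.15]))
                fu_line = int(np.clip(fu_line, 0, _WORST_LINE))
            rec["va_baseline"] = DEFAULT_CHART[base_line]
            rec["va_followup"] = DEFAULT_CHART[fu_line]
            rec["followup_years"] = float(rng.uniform(*config.followup_years_range))
            # OCT thickness: RNFL loads on the vascular latent factor
            for region, grades in oct_dists["rnfl"].items():
                mean, sd = grades[grade]
                val = mean + sd * (lam * z_vasc[i] + resid * rng.standard_normal())
                rec[f"rnfl_{region}"] = max(1.0, val)
            for region, grades in oct_dists["gcc"].items():
                mean, sd = grades[grade]
                rec[f"gcc_{region}"] = max(1.0, mean + sd * rng.standard_normal())
            # OCTA metrics: disc metrics load on the same latent factor
            decline = 1.0 - _OCTA_GRADE_DECLINE * grade_step
            for metric, base in _OCTA_BASE.items():
                mean = base * decline
                sd = _OCTA_REL_SD * mean
                for region in DISC_REGIONS:
                    val = mean + sd * (lam * z_vasc[i] + resid * rng.standard_normal())
                    rec[f"octa_disc_{metric}_{region}"] = max(0.0, val)
                for region in MACULA_REGIONS:
                    val = mean + sd * rng.standard_normal()
                    rec[f"octa_mac_{metric}_{region}"] = max(0.0, val)
            # blood panel: renal block shares a renal latent factor
            for analyte, grades in lab_dists.items():
                mean, sd = grades[grade]
                if analyte in _RENAL_BLOCK:
                    sign = _RENAL_BLOCK[analyte]
                    rc = config.renal_coupling
                    eps = math.sqrt(max(0.0, 1.0 - rc**2))
                    draw = mean + sd * (sign * rc * z_renal[i]
                                        + eps * rng.standard_normal())
                else:
                    draw = mean + sd * rng.standard_normal()
                floor = _ANALYTE_FLOORS.get(analyte, 0.0)
                rec[f"lab_{analyte}"] = max(floor, draw)
            rows.append(rec)
    return pd.DataFrame(rows)
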