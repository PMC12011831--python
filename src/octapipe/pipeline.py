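"""End-to-end orchestration: images -> metrics -> cohort statistics.

A :class:`RunConfig` captures everything a run needs (inputs or a
synthetic spec, ROI and segmentation settings, statistics family, output
directory and the single seed from which all per-stage randomness is
derived).  :func:`run_quantify` turns a directory of flow images into a
tidy metrics CSV plus a QC report; :func:`run_analysis` turns a cohort
table into the report bundle: visual-acuity stability and category
tables, control-standardized lab z-scores, and OCT x OCTA correlation
matrices with Bonferroni-adjusted significance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical_metrics as cm
from . import octa_quant as oq
from . import stats_analysis as sa
from . import synthetic_data as sd
from .roi_geometry import (
    DISC_ANNULUS,
    MACULA_ANNULUS,
    AnnulusROI,
    SectorPartition,
)

__all__ = ["RunConfig", "ConfigError", "run_quantify", "run_analysis", "run_demo"]

log = logging.getLogger("octapipe")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one pipeline run.

    Exactly one of ``image_dir``/``cohort_csv`` (real inputs) or
    ``synthetic`` (generate inputs) must be active.  All randomness flows
    from ``seed``; per-stage seeds are derived deterministically.
    """

    output_dir: str = "octapipe_out"
    image_dir: str | None = None
    cohort_csv: str | None = None
    synthetic: bool = False
    n_phantoms: int = 3
    phantom_size_px: int = 300
    disc_inner_mm: float = DISC_ANNULUS.inner_diameter_mm
    disc_outer_mm: float = DISC_ANNULUS.outer_diameter_mm
    macula_inner_mm: float = MACULA_ANNULUS.inner_diameter_mm
    macula_outer_mm: float = MACULA_ANNULUS.outer_diameter_mm
    binarization: str = "global_otsu"
    binarization_level: float | None = None
    large_vessel_cutoff_px: int = oq.DEFAULT_LARGE_VESSEL_CUTOFF_PX
    ssi_threshold: float = 7.0
    bonferroni_family: str = "per_matrix"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        real = self.image_dir is not None or self.cohort_csv is not None
        if real and self.synthetic:
            raise ConfigError("choose real inputs or synthetic, not both")
        if not real and not self.synthetic:
            raise ConfigError("no inputs: set image_dir/cohort_csv or synthetic")
        if self.binarization == "fixed" and self.binarization_level is None:
            raise ConfigError("fixed binarization requires binarization_level")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        import zlib

        tag = zlib.crc32(stage.encode()) % 2**31
        return int(
            np.random.SeedSequence([self.seed, tag]).generate_state(1)[0] % 2**31
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str | dict) -> "RunConfig":
        data = json.loads(payload) if isinstance(payload, str) else dict(payload)
        if "macula_inner_mm" in data and data.get("macula_inner_mm") is not None:
            data["macula_inner_mm"] = float(data["macula_inner_mm"])
        return cls(**data)


def _roi_bundle(config: RunConfig, image: oq.FlowImage):
    if image.target == "macula":
        roi = AnnulusROI(config.macula_inner_mm, config.macula_outer_mm)
        part = SectorPartition("macula_6", image.eye)
    else:
        roi = AnnulusROI(config.disc_inner_mm, config.disc_outer_mm)
        part = SectorPartition("quadrants_4", image.eye)
    return [(roi, part)]


def _collect_images(config: RunConfig):
    """Yield (name, FlowImage | error-string)."""
    if config.synthetic:
        for k in range(config.n_phantoms):
            spec = sd.PhantomSpec(
                grid=sd.ImageGrid(config.phantom_size_px, config.phantom_size_px),
                seed=config.stage_seed("phantoms") + k,
            )
            yield spec_name(spec), sd.generate_phantom(spec).image
        return
    image_dir = Path(config.image_dir)
    if not image_dir.is_dir():
        raise FileNotFoundError(f"image directory {image_dir} not found")
    for path in sorted(image_dir.glob("*")):
        if path.suffix.lower() not in (".tif", ".tiff", ".png"):
            continue
        try:
            yield path.name, oq.load_flow_image(path)
        except (FileNotFoundError, ValueError, OSError) as exc:
            yield path.name, f"load error: {exc}"


def spec_name(spec: sd.PhantomSpec) -> str:
    return f"phantom_seed{spec.seed}"


def run_quantify(config: RunConfig) -> pd.DataFrame:
    """Quantify all input images; write metrics CSV and QC report.

    Images failing QC (SSI <= threshold, missing metadata, unreadable) are
    excluded and listed with reasons in ``qc_report.csv``.  Fails if no
    image passes QC.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames: list[pd.DataFrame] = []
    qc_rows: list[dict] = []
    for name, item in _collect_images(config):
        if isinstance(item, str):
            qc_rows.append({"image": name, "status": "excluded", "reason": item})
            log.warning("excluding %s: %s", name, item)
            continue
        try:
            if not oq.qc_filter(item, config.ssi_threshold):
                qc_rows.append({
                    "image": name, "status": "excluded",
                    "reason": f"SSI {item.signal_strength_index} <= {config.ssi_threshold}",
                })
                continue
            rows = oq.quantify_image(
                item, _roi_bundle(config, item),
                binarization=config.binarization,
                level=config.binarization_level,
                large_vessel_cutoff_px=config.large_vessel_cutoff_px,
                ssi_threshold=config.ssi_threshold,
            )
        except (oq.QCError, ValueError) as exc:
            qc_rows.append({"image": name, "status": "excluded", "reason": str(exc)})
            continue
        frames.append(oq.metrics_to_frame(
            rows, subject=item.subject_id, eye=item.eye, target=item.target
        ))
        qc_rows.append({"image": name, "status": "included", "reason": ""})
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "qc_report.csv", index=False)
    if not frames:
        raise oq.QCError("no image passed quality control; see qc_report.csv")
    metrics = pd.concat(frames, ignore_index=True)
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.6f")
    return metrics


_REQUIRED_COHORT_COLS = ("grade", "va_baseline", "va_followup")


def run_analysis(config: RunConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Cohort statistics report bundle.

    Emits (under ``output_dir``): ``va_stability.csv`` (per-grade
    stability), ``va_categories.csv`` (Snellen category percentages at
    baseline/follow-up), ``lab_zscores.csv`` + ``lab_heatmap.png``
    (control-standardized panels), ``correlation_disc.csv`` /
    ``correlation_macula.csv`` + heatmap PNGs, and ``summary.json`` with
    headline numbers.  Returns the summary dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        if config.synthetic:
            cohort = sd.generate_cohort(
                sd.CohortConfig(seed=config.stage_seed("cohort"))
            )
        else:
            cohort = pd.read_csv(config.cohort_csv)
    missing = [c for c in _REQUIRED_COHORT_COLS if c not in cohort.columns]
    if missing:
        raise ConfigError(f"cohort table missing required columns: {missing}")
    dm = cohort[cohort["grade"] != "Ctrl"]
    if dm.empty:
        raise ConfigError("cohort contains no DM eyes")

    # --- visual acuity stability (per grade and overall DM) -------------
    stab_rows = []
    for grade, sub in cohort.groupby("grade", sort=True):
        pairs = list(zip(sub["va_baseline"], sub["va_followup"]))
        summary = cm.stability_summary(pairs)
        stab_rows.append({"grade": grade, **summary.to_dict()})
    dm_summary = cm.stability_summary(
        list(zip(dm["va_baseline"], dm["va_followup"]))
    )
    stab_rows.append({"grade": "DM_all", **dm_summary.to_dict()})
    stability = pd.DataFrame(stab_rows)
    stability.to_csv(out / "va_stability.csv", index=False)

    # --- Snellen category percentages at baseline and follow-up ---------
    cat_rows = []
    for visit in ("va_baseline", "va_followup"):
        for grade, sub in cohort.groupby("grade", sort=True):
            cats = sub[visit].map(cm.categorize_va)
            counts = cats.value_counts(normalize=True) * 100.0
            for label, _ in cm.DEFAULT_VA_BINS:
                cat_rows.append({
                    "visit": visit.replace("va_", ""), "grade": grade,
                    "category": label,
                    "percent": round(float(counts.get(label, 0.0)), 2),
                })
    pd.DataFrame(cat_rows).to_csv(out / "va_categories.csv", index=False)

    # --- control-standardized lab z-scores ------------------------------
    lab_cols = [c for c in cohort.columns if c.startswith("lab_")]
    summary: dict = {}
    if lab_cols:
        ctrl = cohort[cohort["grade"] == "Ctrl"][lab_cols]
        if len(ctrl) >= 2:
            z, flagged = cm.standardize_labs(cohort[lab_cols], ctrl)
            z.insert(0, "grade", cohort["grade"].to_numpy())
            z.to_csv(out / "lab_zscores.csv", index=False, float_format="%.4f")
            grade_means = z.groupby("grade").mean()
            _render_lab_heatmap(grade_means, out / "lab_heatmap.png")
            summary["lab_flagged_analytes"] = flagged
            summary["lab_max_abs_z_grade_mean"] = float(
                np.nanmax(np.abs(grade_means.to_numpy()))
            )

    # --- OCT x OCTA correlation matrices --------------------------------
    for panel, oct_prefix, octa_prefix in (
        ("disc", "rnfl_", "octa_disc_"),
        ("macula", "gcc_", "octa_mac_"),
    ):
        oct_cols = [c for c in dm.columns if c.startswith(oct_prefix)]
        octa_cols = [c for c in dm.columns if c.startswith(octa_prefix)]
        if not oct_cols or not octa_cols:
            continue
        family_size = None
        if config.bonferroni_family == "global":
            family_size = sum(
                len([c for c in dm.columns if c.startswith(p1)])
                * len([c for c in dm.columns if c.startswith(p2)])
                for _, p1, p2 in (
                    ("disc", "rnfl_", "octa_disc_"),
                    ("macula", "gcc_", "octa_mac_"),
                )
            )
        matrix = sa.correlation_matrix(
            dm[oct_cols], dm[octa_cols],
            family=config.bonferroni_family, family_size=family_size,
        )
        matrix.to_csv(out / f"correlation_{panel}.csv", index=False,
                      float_format="%.4f")
        sa.render_correlation_heatmap(matrix, out / f"correlation_{panel}_heatmap.png")
        sig = matrix[matrix["significant"]]
        summary[f"{panel}_n_cells"] = int(len(matrix))
        summary[f"{panel}_n_significant"] = int(len(sig))
        summary[f"{panel}_max_abs_rho"] = (
            float(matrix["rho"].abs().max()) if len(matrix) else float("nan")
        )

    summary["dm_pct_stable"] = float(dm_summary["pct_stable"])
    summary["dm_pct_worsened"] = float(dm_summary["pct_worsened"])
    summary["n_eyes"] = int(len(cohort))
    summary["n_dm_eyes"] = int(len(dm))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run_config.json").write_text(config.to_json())
    return summary


def _render_lab_heatmap(grade_means: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    data = grade_means.to_numpy(dtype=float)
    vmax = max(1.0, np.nanmax(np.abs(data)))
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(grade_means.columns)),
                  [c.replace("lab_", "") for c in grade_means.columns],
                  rotation=90, fontsize=7)
    ax.set_yticks(range(len(grade_means.index)), grade_means.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="mean z (vs controls)")
    ax.set_title("Blood panel standardized by the control distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_demo(config: RunConfig) -> dict:
    """End-to-end synthetic run: phantoms -> metrics, cohort -> reports."""
    metrics = run_quantify(config)
    summary = run_analysis(config)
    summary["n_metric_rows"] = int(len(metrics))
    return summary
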