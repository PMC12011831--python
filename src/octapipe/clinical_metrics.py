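"""Per-eye clinical observations: visual acuity, grades, blood panels.

Snellen acuities convert to LogMAR as ``-log10(numerator/denominator)``
(20/20 -> 0.0, 20/200 -> 1.0; larger is worse).  Visual-acuity stability
over follow-up is classified on the Snellen chart line sequence: a change
of fewer than two chart lines is *stable*, a drop of two or more lines is
*worsened*, a gain of two or more lines is *improved*.

Blood panels (24 analytes) are standardized against the control group:
z = (x - mean_ctrl) / sd_ctrl per analyte, so control z-scores have mean 0
and sd 1 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnellenVA",
    "DEFAULT_CHART",
    "LOW_VISION_LOGMAR",
    "LAB_ANALYTES",
    "DEFAULT_VA_BINS",
    "snellen_to_logmar",
    "chart_line_index",
    "classify_stability",
    "stability_summary",
    "standardize_labs",
    "unstandardize_labs",
    "categorize_va",
]

#: Conventional LogMAR values for low-vision categories (flagged as imputed).
LOW_VISION_LOGMAR = {"CF": 1.9, "HM": 2.3, "LP": 2.7, "NLP": 3.0}

#: Default Snellen chart line sequence, best to worst.  The low-vision
#: codes occupy the worst lines.  Configurable wherever a chart is taken.
DEFAULT_CHART: tuple[str, ...] = (
    "20/10", "20/15", "20/20", "20/25", "20/30", "20/40", "20/50",
    "20/60", "20/70", "20/80", "20/100", "20/200", "20/400",
    "CF", "HM", "LP", "NLP",
)

#: The 24 blood-panel analytes (units: Glucose mg/dL, A1c %, Albumin g/dL,
#: Cr mg/dL, EGFR mL/min/1.73m^2, BUN mg/dL, electrolytes mmol/L, ...).
LAB_ANALYTES: tuple[str, ...] = (
    "Glucose", "A1c", "Albumin", "Cr", "EGFR", "BUN", "Protein",
    "Globulin", "Alk Phos", "ALT", "AST", "Bili", "K", "Ca", "Cl", "Na",
    "CO2", "Hgb", "RDW", "Hct", "Chol-HDL", "Chol-LDL", "Chol-Non-HDL",
    "Chol",
)

#: Default visual-acuity category bins (best denominator bound per bin).
DEFAULT_VA_BINS: tuple[tuple[str, int], ...] = (
    ("20/20-20/30", 30),
    ("20/40-20/60", 60),
    ("20/70-20/100", 100),
    ("20/200 or worse", 10**9),
)


@dataclass(frozen=True)
class SnellenVA:
    """A Snellen visual acuity: a 20/x ratio or a low-vision code.

    Ratio acuities carry ``numerator`` (test distance, conventionally 20)
    and ``denominator``; low-vision acuities carry ``code`` in
    {CF, HM, LP, NLP} with a conventional imputed LogMAR.
    """

    numerator: int | None = None
    denominator: int | None = None
    code: str | None = None

    def __post_init__(self) -> None:
        if self.code is not None:
            if self.code not in LOW_VISION_LOGMAR:
                raise ValueError(f"unknown low-vision code {self.code!r}")
            if self.numerator is not None or self.denominator is not None:
                raise ValueError("give either a ratio or a code, not both")
        else:
            if self.numerator is None or self.denominator is None:
                raise ValueError("ratio acuity requires numerator and denominator")
            if self.numerator <= 0 or self.denominator <= 0:
                raise ValueError("Snellen numerator/denominator must be positive")

    @classmethod
    def parse(cls, text: str) -> "SnellenVA":
        text = text.strip()
        if text in LOW_VISION_LOGMAR:
            return cls(code=text)
        num, den = text.split("/")
        return cls(numerator=int(num), denominator=int(den))

    @property
    def is_low_vision(self) -> bool:
        return self.code is not None

    @property
    def logmar(self) -> float:
        if self.code is not None:
            return LOW_VISION_LOGMAR[self.code]
        return -math.log10(self.numerator / self.denominator)

    def __str__(self) -> str:
        return self.code if self.code else f"{self.numerator}/{self.denominator}"


def snellen_to_logmar(va: SnellenVA | str) -> float:
    """LogMAR = -log10(Snellen numerator / Snellen denominator)."""
    if isinstance(va, str):
        va = SnellenVA.parse(va)
    return va.logmar


def chart_line_index(
    va: SnellenVA | str, chart: Sequence[str] = DEFAULT_CHART
) -> tuple[int, bool]:
    """Index of an acuity on the chart (0 = best line).

    An acuity not on the chart maps to the line with the nearest LogMAR;
    the second return value flags that approximation.
    """
    if isinstance(va, str):
        va = SnellenVA.parse(va)
    text = str(va)
    if text in chart:
        return chart.index(text), False
    target = va.logmar
    logmars = [snellen_to_logmar(line) for line in chart]
    nearest = int(np.argmin([abs(lm - target) for lm in logmars]))
    return nearest, True


def classify_stability(
    baseline: SnellenVA | str,
    followup: SnellenVA | str,
    chart: Sequence[str] = DEFAULT_CHART,
    line_threshold: int = 2,
) -> str:
    """Classify follow-up acuity as stable / worsened / improved.

    Worsened iff the follow-up is ``line_threshold`` (default 2) or more
    chart lines below baseline; improved iff that many lines above; a
    change of fewer lines is stable.
    """
    b, _ = chart_line_index(baseline, chart)
    f, _ = chart_line_index(followup, chart)
    delta = f - b  # positive = moved down the chart = worse
    if delta >= line_threshold:
        return "worsened"
    if delta <= -line_threshold:
        return "improved"
    return "stable"


def stability_summary(
    pairs: Sequence[tuple[SnellenVA | str, SnellenVA | str]],
    chart: Sequence[str] = DEFAULT_CHART,
) -> pd.Series:
    """Counts and percentages (2 decimals) of stability classes over a
    cohort of (baseline, follow-up) acuity pairs."""
    classes = [classify_stability(b, f, chart) for b, f in pairs]
    counts = pd.Series(classes).value_counts()
    out = {}
    for label in ("stable", "worsened", "improved"):
        n = int(counts.get(label, 0))
        out[f"n_{label}"] = n
        out[f"pct_{label}"] = round(100.0 * n / len(classes), 2)
    out["n_total"] = len(classes)
    return pd.Series(out)


def categorize_va(
    va: SnellenVA | str,
    bins: Sequence[tuple[str, int]] = DEFAULT_VA_BINS,
) -> str:
    """Assign an acuity to a Snellen category bin.

    Default bins: 20/20-20/30, 20/40-20/60, 20/70-20/100, 20/200 or worse.
    Low-vision codes map to the worst bin.
    """
    if isinstance(va, str):
        va = SnellenVA.parse(va)
    if va.is_low_vision:
        return bins[-1][0]
    # compare on the 20-ft-equivalent denominator
    den_equiv = va.denominator * 20 / va.numerator
    for label, upper in bins:
        if den_equiv <= upper:
            return label
    return bins[-1][0]


def standardize_labs(
    dm_panels: pd.DataFrame,
    ctrl_panels: pd.DataFrame,
    analytes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Standardize analyte values by the control-group distribution.

    Both inputs are wide tables (one row per panel, one column per
    analyte).  Per analyte: z = (x - mean_ctrl) / sd_ctrl.  Analytes with
    zero control sd (or fewer than two control values) are excluded and
    returned in the flagged list.

    Returns ``(z_table, flagged_analytes)``; the z-table has the same rows
    as ``dm_panels``.
    """
    if analytes is None:
        analytes = [c for c in dm_panels.columns if c in ctrl_panels.columns]
    z = pd.DataFrame(index=dm_panels.index)
    flagged: list[str] = []
    for analyte in analytes:
        ctrl = ctrl_panels[analyte].dropna()
        if len(ctrl) < 2 or ctrl.std(ddof=1) == 0:
            flagged.append(analyte)
            continue
        z[analyte] = (dm_panels[analyte] - ctrl.mean()) / ctrl.std(ddof=1)
    return z, flagged


def unstandardize_labs(
    z_table: pd.DataFrame, ctrl_panels: pd.DataFrame
) -> pd.DataFrame:
    """Invert :func:`standardize_labs` using the same control table."""
    out = pd.DataFrame(index=z_table.index)
    for analyte in z_table.columns:
        ctrl = ctrl_panels[analyte].dropna()
        out[analyte] = z_table[analyte] * ctrl.std(ddof=1) + ctrl.mean()
    return out
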