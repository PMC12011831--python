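"""Cohort statistics: nonparametric group comparisons and OCT x OCTA
Spearman correlation matrices with Bonferroni correction.

Group comparisons follow the usual nonparametric battery: two-tailed
Mann-Whitney U for two groups (exact enumeration for small samples,
tie-corrected normal approximation otherwise), Kruskal-Wallis H for three
or more, Pearson chi-square for categorical frequencies, and Welch's
t-test from summary statistics for demographics reported as mean +/- sd.

Correlation matrices cross OCT thickness variables (RNFL quadrants, GCC
sectors) with OCTA vessel metrics per region; each cell is a Spearman rho
with Bonferroni-adjusted p (family = all cells of one panel by default)
and a strength label: |rho| in [0, 0.3) weak, [0.3, 0.7) moderate,
[0.7, 1] high (boundary values go to the upper category).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult",
    "CorrelationCell",
    "mann_whitney",
    "kruskal_wallis",
    "chi_square",
    "welch_t",
    "spearman",
    "strength_label",
    "correlation_matrix",
    "render_correlation_heatmap",
]

EXACT_MW_MAX_N = 12  # exact Mann-Whitney enumeration up to this total n


@dataclass(frozen=True)
class StatResult:
    """One hypothesis-test result."""

    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    n_per_group: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class CorrelationCell:
    """One OCT x OCTA Spearman correlation with adjusted significance."""

    oct_variable: str
    octa_variable: str
    rho: float
    p_value: float
    p_adjusted: float
    significant_after_bonferroni: bool
    strength: str
    n: int


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-tailed Mann-Whitney U test.

    Uses exact enumeration when n_a + n_b <= 12 and the pooled sample is
    tie-free; otherwise the tie-corrected, continuity-corrected normal
    approximation (the continuity correction keeps the approximation
    within 0.02 of the exact p at small n).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if a.size + b.size <= EXACT_MW_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return StatResult(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_per_group=(a.size, b.size),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Tie-corrected Kruskal-Wallis H with chi-square reference (df = k-1)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    if all(np.array_equal(g, arrays[0]) for g in arrays[1:]) and np.unique(
        arrays[0]
    ).size == 1:
        # all observations identical: H is 0 by convention
        return StatResult("kruskal_wallis", 0.0, 1.0, df=len(groups) - 1,
                          n_per_group=tuple(g.size for g in arrays))
    h, p = stats.kruskal(*arrays)
    return StatResult(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        df=len(groups) - 1,
        n_per_group=tuple(g.size for g in arrays),
    )


def chi_square(table: Sequence[Sequence[float]] | np.ndarray) -> StatResult:
    """Pearson chi-square on a 2-way contingency table, no continuity
    correction, df = (r-1)(c-1)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return StatResult(
        test_name="chi_square", statistic=float(chi2), p_value=float(p), df=float(dof)
    )


def welch_t(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> StatResult:
    """Welch's t-test from summary statistics, with Welch-Satterthwaite df."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return StatResult(
        test_name="welch_t", statistic=float(t), p_value=float(p), df=float(df),
        n_per_group=(n_a, n_b),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Tie-handled Spearman rank correlation (Pearson on mid-ranks), p from
    the t approximation with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: rho undefined")
    rho, p = stats.spearmanr(x, y)
    return StatResult(
        test_name="spearman", statistic=float(rho), p_value=float(p),
        df=float(x.size - 2), n_per_group=(x.size,),
    )


def strength_label(rho: float) -> str:
    """Correlation strength category by |rho|: [0,0.3) weak, [0.3,0.7)
    moderate, [0.7,1] high."""
    r = abs(rho)
    if r > 1.0:
        raise ValueError("|rho| cannot exceed 1")
    if r >= 0.7:
        return "high"
    if r >= 0.3:
        return "moderate"
    return "weak"


def correlation_matrix(
    oct_table: pd.DataFrame,
    octa_table: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "per_matrix",
    family_size: int | None = None,
) -> pd.DataFrame:
    """Spearman correlation matrix between OCT and OCTA variables.

    Rows of the two tables are aligned eye-level observations; every
    (OCT column x OCTA column) pair yields one cell, computed on
    pairwise-complete observations.  Bonferroni family size m is the
    number of cells in this matrix (``family="per_matrix"``, the default)
    or an explicit ``family_size`` (``family="global"``, for correcting
    across several panels at once); p_adjusted = min(1, p * m).

    Returns a tidy DataFrame with columns oct_var, octa_var, rho, p, p_adj,
    significant, strength, n.  Cells with fewer than 3 complete pairs are
    flagged missing (NaN rho, significant=False, strength="missing").
    """
    if len(oct_table) != len(octa_table):
        raise ValueError("tables must have aligned rows")
    if family == "per_matrix":
        m = len(oct_table.columns) * len(octa_table.columns)
    elif family == "global":
        if family_size is None:
            raise ValueError("global family requires family_size")
        m = family_size
    else:
        raise ValueError(f"unknown family {family!r}")
    rows = []
    for oct_var in oct_table.columns:
        for octa_var in octa_table.columns:
            x = oct_table[oct_var].to_numpy(dtype=float)
            y = octa_table[octa_var].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            cell: dict
            if ok.sum() < 3 or np.unique(x[ok]).size == 1 or np.unique(y[ok]).size == 1:
                cell = dict(rho=np.nan, p=np.nan, p_adj=np.nan,
                            significant=False, strength="missing", n=int(ok.sum()))
            else:
                rho, p = stats.spearmanr(x[ok], y[ok])
                p_adj = min(1.0, p * m)
                cell = dict(
                    rho=float(rho), p=float(p), p_adj=float(p_adj),
                    significant=bool(p_adj < alpha),
                    strength=strength_label(rho), n=int(ok.sum()),
                )
            rows.append({"oct_var": oct_var, "octa_var": octa_var, **cell})
    return pd.DataFrame(rows)


def average_eyes_per_subject(
    cohort: pd.DataFrame, subject_col: str = "subject_id"
) -> pd.DataFrame:
    """Collapse a per-eye table to one row per subject for sensitivity
    analysis: numeric columns are averaged over fellow eyes, non-numeric
    columns take the first eye's value."""
    if subject_col not in cohort.columns:
        raise ValueError(f"missing subject column {subject_col!r}")
    numeric = cohort.select_dtypes("number").columns
    agg = {c: ("mean" if c in numeric else "first")
           for c in cohort.columns if c != subject_col}
    return cohort.groupby(subject_col, as_index=False).agg(agg)


def render_correlation_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render a correlation matrix as a heatmap PNG: red cells are
    significant after Bonferroni, blue cells are not; color intensity
    tracks |rho|."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot_rho = matrix.pivot(index="oct_var", columns="octa_var", values="rho")
    pivot_sig = matrix.pivot(index="oct_var", columns="octa_var", values="significant")
    rgb = np.ones((*pivot_rho.shape, 3))
    mag = np.abs(pivot_rho.to_numpy())
    sig = pivot_sig.to_numpy().astype(bool)
    # significant: red channel dominant; non-significant: blue dominant
    rgb[..., 0] = np.where(sig, 1.0, 1.0 - mag)
    rgb[..., 1] = 1.0 - mag
    rgb[..., 2] = np.where(sig, 1.0 - mag, 1.0)
    rgb = np.nan_to_num(rgb, nan=1.0)
    fig, ax = plt.subplots(figsize=(0.5 * len(pivot_rho.columns) + 2,
                                    0.4 * len(pivot_rho.index) + 2))
    ax.imshow(rgb, aspect="auto")
    ax.set_xticks(range(len(pivot_rho.columns)), pivot_rho.columns,
                  rotation=90, fontsize=7)
    ax.set_yticks(range(len(pivot_rho.index)), pivot_rho.index, fontsize=7)
    ax.set_title("Spearman rho (red = significant after Bonferroni)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
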