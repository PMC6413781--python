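"""Grader-panel aggregation and intergrader reliability for the 8-point
iris transillumination scale.

A panel of graders (18 in the reference design) scores each of 2 images
per eye per visit on a 0–8 photographic standard scale, to one decimal
place. Aggregation is two-stage: each grader's grades are first averaged
over the images of an eye-visit, then those per-grader means are averaged
across graders.

Reliability is quantified per eye and visit with the intraclass
correlation coefficient under a two-way random-effects, absolute-agreement
model (graders treated as a random sample): from the participants x
graders matrix of per-grader image means, ANOVA mean squares give

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the between-participant, between-grader and residual
mean squares, n participants and k graders. ICC = 1 is perfect agreement,
0 only chance agreement, negative values systematic disagreement. The
95% CI follows the F-distribution construction of McGraw & Wong; the
average-measure variant ICC(A,k) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GRADE_COLUMNS = ["participant", "eye", "visit_month", "grader_id", "image_index", "grade"]


class GradeValidationError(ValueError):
    """Grade table violates the 0–8 one-decimal convention."""


class ICCError(ValueError):
    """ICC cannot be computed for the requested stratum."""


@dataclass(frozen=True)
class ICCResult:
    """Single- and average-measure absolute-agreement ICC for one stratum."""

    icc: float
    ci_low: float
    ci_high: float
    icc_avg: float
    ci_low_avg: float
    ci_high_avg: float
    model_label: str
    eye: str
    visit_month: int
    n_participants: int
    n_graders: int


def validate_grades(grades: pd.DataFrame) -> pd.DataFrame:
    """Check grade-table schema, 0–8 range and one-decimal resolution."""
    missing = set(GRADE_COLUMNS) - set(grades.columns)
    if missing:
        raise GradeValidationError(f"grade table missing columns: {sorted(missing)}")
    if grades.empty:
        raise GradeValidationError("grade table is empty")
    g = grades["grade"].to_numpy(float)
    if np.any(~np.isfinite(g)) or np.any(g < 0) or np.any(g > 8):
        raise GradeValidationError("grades must be finite and within [0, 8]")
    if np.max(np.abs(g * 10 - np.round(g * 10))) > 1e-9:
        raise GradeValidationError("grades must have at most one decimal place")
    return grades


def per_grader_means(grades: pd.DataFrame) -> pd.DataFrame:
    """Stage one: each grader's mean over the images of an eye-visit."""
    validate_grades(grades)
    return (
        grades.groupby(["participant", "eye", "visit_month", "grader_id"], sort=True)["grade"]
        .mean()
        .reset_index(name="grader_mean")
    )


def panel_scores(grades: pd.DataFrame) -> pd.DataFrame:
    """Two-stage panel mean per participant x eye x visit.

    Grader-level image means are averaged across graders, so a grader who
    scored only one of the two images still contributes a single vote.
    """
    gm = per_grader_means(grades)
    return (
        gm.groupby(["participant", "eye", "visit_month"], sort=True)
        .agg(panel_score=("grader_mean", "mean"), n_graders_used=("grader_mean", "size"))
        .reset_index()
    )


def _anova_mean_squares(matrix: np.ndarray) -> tuple[float, float, float]:
    """Two-way (targets x raters) ANOVA mean squares, no replication."""
    n, k = matrix.shape
    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    col_means = matrix.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = (
        np.sum((matrix - grand) ** 2)
        - k * np.sum((row_means - grand) ** 2)
        - n * np.sum((col_means - grand) ** 2)
    )
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way_random(
    matrix: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float, float, float, float]:
    """Absolute-agreement ICC from a complete targets x raters matrix.

    Returns (icc1, lo1, hi1, icck, lok, hik): single-measure ICC(A,1) with
    its McGraw–Wong F-based CI, and average-measure ICC(A,k) with the
    Spearman–Brown transform of those bounds.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ICCError("need at least 2 targets and 2 raters")
    if np.isnan(matrix).any():
        raise ICCError("matrix contains missing cells")
    n, k = matrix.shape
    msr, msc, mse = _anova_mean_squares(matrix)
    denom1 = msr + (k - 1) * mse + (k / n) * (msc - mse)
    denomk = msr + (msc - mse) / n
    if denom1 <= 0 or (msr == 0 and msc == 0 and mse == 0):
        raise ICCError("ICC undefined for constant grades")
    icc1 = (msr - mse) / denom1
    icck = (msr - mse) / denomk

    # McGraw & Wong (1996) CI for ICC(A,1), Satterthwaite df for the
    # grader term
    a = (k * icc1) / (n * (1 - icc1)) if icc1 < 1 else np.inf
    b = 1 + (k * icc1 * (n - 1)) / (n * (1 - icc1)) if icc1 < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:  # perfect agreement: degenerate interval
        lo1 = hi1 = icc1

    def sb(x: float) -> float:
        return k * x / (1 + (k - 1) * x) if np.isfinite(x) else x

    return icc1, float(lo1), float(hi1), icck, sb(float(lo1)), sb(float(hi1))


def intergrader_icc(
    grades: pd.DataFrame,
    eye: str,
    visit_month: int,
    alpha: float = 0.05,
    allow_missing: bool = False,
) -> ICCResult:
    """ICC of the grader panel for one eye at one visit.

    Builds the participants x graders matrix of per-grader image means.
    Incomplete panels raise unless ``allow_missing`` selects complete-case
    analysis (participants graded by every grader).
    """
    gm = per_grader_means(grades)
    sel = gm[(gm["eye"] == eye) & (gm["visit_month"] == visit_month)]
    if sel.empty:
        raise ICCError(f"no grades for eye={eye}, visit_month={visit_month}")
    matrix = sel.pivot(index="participant", columns="grader_id", values="grader_mean")
    if matrix.isna().any().any():
        if not allow_missing:
            raise ICCError(
                "incomplete grader panel; pass allow_missing=True for "
                "complete-case analysis"
            )
        matrix = matrix.dropna(axis=0)
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ICCError("need >=2 participants and >=2 graders after filtering")
    icc1, lo1, hi1, icck, lok, hik = icc_two_way_random(matrix.to_numpy(), alpha=alpha)
    return ICCResult(
        icc=icc1, ci_low=lo1, ci_high=hi1,
        icc_avg=icck, ci_low_avg=lok, ci_high_avg=hik,
        model_label="two-way random effects, absolute agreement",
        eye=eye, visit_month=int(visit_month),
        n_participants=matrix.shape[0], n_graders=matrix.shape[1],
    )


def icc_by_visit(grades: pd.DataFrame, alpha: float = 0.05, allow_missing: bool = False) -> pd.DataFrame:
    """ICC for every eye x visit stratum present in the grade table."""
    validate_grades(grades)
    strata = grades[["eye", "visit_month"]].drop_duplicates().sort_values(["eye", "visit_month"])
    rows = []
    for _, (eye, visit) in strata.iterrows():
        res = intergrader_icc(grades, eye, int(visit), alpha=alpha, allow_missing=allow_missing)
        rows.append(
            {
                "eye": res.eye,
                "visit_month": res.visit_month,
                "icc": res.icc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "icc_avg": res.icc_avg,
                "ci_low_avg": res.ci_low_avg,
                "ci_high_avg": res.ci_high_avg,
                "n_participants": res.n_participants,
                "n_graders": res.n_graders,
            }
        )
    return pd.DataFrame(rows)


def method_correlation(panel: pd.DataFrame, semiquant: pd.DataFrame) -> float:
    """Spearman rank correlation between panel means and automated scores.

    Eye-visit observations are pooled across eyes and visits; ties receive
    midranks. Requires at least 3 paired observations.
    """
    merged = panel.merge(
        semiquant, on=["participant", "eye", "visit_month"], how="inner"
    )
    if len(merged) < 3:
        raise ValueError("need >=3 paired eye-visit observations")
    rho = stats.spearmanr(merged["panel_score"], merged["semiquant_score"]).statistic
    return float(rho)
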