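"""Change-from-baseline descriptives and longitudinal mixed models.

The analysis conventions implemented here are those of a small open-label
ophthalmic trial with repeated visits on both eyes:

* Change from baseline uses each unit's earliest visit with data as the
  baseline. Two summaries are reported: the directional mean (signed
  changes) and the absolute mean (magnitudes, regardless of direction) —
  the latter was the reference design's primary endpoint form. Eye-level
  outcomes are summarized per eye (OD, OS) and pooled over both (OU).

* Longitudinal models are linear mixed models with visit as a categorical
  fixed effect (baseline as reference), a participant random intercept and
  optionally a random slope in months, and an exchangeable (compound
  symmetry) within-unit correlation: equal variance at every visit and
  equal correlation between any two visits, which is exactly the marginal
  structure induced by the random intercepts. When both eyes contribute,
  eyes are nested within participants through an eye-level variance
  component. Estimation is by restricted maximum likelihood; fixed-effect
  CIs and p-values use the normal approximation.

* If the intercept+slope model fails to converge or its random-effect
  covariance is degenerate, the model is automatically refit with a
  random intercept only and the fallback is flagged and logged.

* Visit-level p-values are labeled "significant" below 0.05 and
  "moderately significant" below 0.10; no multiplicity adjustment is
  applied (the design treats all analyses as exploratory).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

ALPHA_SIGNIFICANT = 0.05
ALPHA_MODERATE = 0.10


class FitError(RuntimeError):
    """Mixed model failed to produce usable estimates."""


def significance_label(p: float) -> str:
    """Classify a p-value per the 0.05 / 0.10 convention (no adjustment)."""
    if not (0 < p <= 1):
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    if p < ALPHA_SIGNIFICANT:
        return "significant"
    if p < ALPHA_MODERATE:
        return "moderately significant"
    return "not significant"


# ---------------------------------------------------------------------------
# Descriptive change from baseline

@dataclass(frozen=True)
class ChangeSummary:
    changes: pd.DataFrame   # per-unit changes
    summary: pd.DataFrame   # per-group directional and absolute summaries
    baseline_month: int
    target_visit: int


def _unit_columns(ds: pd.DataFrame) -> list[str]:
    cols = ["participant"]
    if "eye" in ds.columns and ds["eye"].notna().any():
        cols.append("eye")
    return cols


def change_from_baseline(ds: pd.DataFrame, target_visit: int) -> ChangeSummary:
    """Per-unit change from the earliest baseline, with group summaries.

    ``ds`` is tidy: participant, optional eye, visit_month, value. For each
    unit (participant or participant x eye) the change is value at
    ``target_visit`` minus value at the unit's earliest visit. Summaries
    give directional mean (SD) and absolute mean (SD); with eye-level data
    rows for OD, OS and the pooled OU are produced.
    """
    unit_cols = _unit_columns(ds)
    changes = []
    for key, grp in ds.groupby(unit_cols, sort=True):
        grp = grp.sort_values("visit_month")
        tgt = grp[grp["visit_month"] == target_visit]
        base_month = grp["visit_month"].iloc[0]
        if tgt.empty or base_month == target_visit:
            continue
        baseline = grp["value"].iloc[0]
        rec = dict(zip(unit_cols, key if isinstance(key, tuple) else (key,)))
        rec["baseline_month"] = base_month
        rec["change"] = float(tgt["value"].iloc[0] - baseline)
        changes.append(rec)
    if not changes:
        raise ValueError(f"no unit has both a baseline and visit month {target_visit}")
    changes_df = pd.DataFrame(changes)

    def _summarize(vals: np.ndarray, group: str) -> dict:
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        abs_sd = float(np.std(np.abs(vals), ddof=1)) if len(vals) > 1 else np.nan
        return {
            "group": group,
            "n": len(vals),
            "directional_mean": float(np.mean(vals)),
            "directional_sd": sd,
            "absolute_mean": float(np.mean(np.abs(vals))),
            "absolute_sd": abs_sd,
        }

    rows = []
    vals_all = changes_df["change"].to_numpy()
    if "eye" in changes_df.columns:
        for eye in sorted(changes_df["eye"].unique()):
            vals = changes_df.loc[changes_df["eye"] == eye, "change"].to_numpy()
            rows.append(_summarize(vals, eye))
        rows.append(_summarize(vals_all, "OU"))
    else:
        rows.append(_summarize(vals_all, "all"))
    earliest = int(changes_df["baseline_month"].min())
    return ChangeSummary(
        changes=changes_df,
        summary=pd.DataFrame(rows),
        baseline_month=earliest,
        target_visit=int(target_visit),
    )


# ---------------------------------------------------------------------------
# Mixed models

@dataclass(frozen=True)
class ModelSpec:
    """Longitudinal model configuration.

    random: participant-level random effects; ``intercept_and_slope`` adds
    a random slope in months on top of the random intercept.
    nest_eyes: add an eye-within-participant variance component when both
    eyes contribute observations.
    """

    random: Literal["intercept_only", "intercept_and_slope"] = "intercept_and_slope"
    covariance: Literal["compound_symmetry"] = "compound_symmetry"
    nest_eyes: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.random not in ("intercept_only", "intercept_and_slope"):
            raise ValueError(f"unknown random-effects spec {self.random!r}")
        if self.covariance != "compound_symmetry":
            raise ValueError(f"unknown covariance structure {self.covariance!r}")


@dataclass
class ModelFitResult:
    effects: pd.DataFrame          # visit_month, estimate, ci_low, ci_high, p_value, label
    variance_components: dict[str, float]
    converged: bool
    fallback_applied: bool
    model_label: str
    baseline_month: int
    n_observations: int
    result: object = field(repr=False, default=None)


def _is_degenerate(result, has_slope: bool, slope_var_floor: float = 0.0) -> bool:
    """Convergence/boundary check on a fitted MixedLM result.

    A random-slope variance is treated as on the boundary when it falls
    below ``slope_var_floor``, the sampling variance of a single
    participant's individually estimated slope (residual variance over the
    within-participant spread of months): below that resolution the data
    cannot distinguish the estimate from zero.
    """
    if result is None or not getattr(result, "converged", False):
        return True
    # fixed-effect SEs must be finite; random-effect-parameter SEs may be
    # NaN at a legitimate zero-variance boundary
    if np.isnan(np.asarray(result.fe_params, float)).any() or np.isnan(
        np.asarray(result.bse_fe, float)
    ).any():
        return True
    if has_slope:
        cov = np.asarray(result.cov_re, dtype=float)
        if cov.shape[0] >= 2:
            eig = np.linalg.eigvalsh(cov)
            if eig[0] <= 0 or eig[0] / max(eig[-1], 1e-300) < 1e-8:
                return True
            if cov[1, 1] < slope_var_floor:
                return True
    return False


def _slope_var_floor(df: pd.DataFrame, residual_var: float) -> float:
    sxx = df.groupby("participant")["month"].apply(lambda m: ((m - m.mean()) ** 2).sum())
    mean_sxx = float(sxx.mean())
    return residual_var / mean_sxx if mean_sxx > 0 else np.inf


def _fit_once(df: pd.DataFrame, baseline: int, random: str, nest: bool):
    formula = f"value ~ C(visit_month, Treatment(reference={baseline}))"
    re_formula = "1 + month" if random == "intercept_and_slope" else "1"
    vc_formula = {"eye_cs": "0 + C(eye)"} if nest else None
    model = sm.MixedLM.from_formula(
        formula, groups="participant", re_formula=re_formula,
        vc_formula=vc_formula, data=df,
    )
    # lbfgs first for speed; powell rescues ill-scaled or boundary cases
    # (e.g. a variance orders of magnitude below the others), where the
    # gradient-based optimizers stall or raise
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "powell"):
            try:
                result = model.fit(reml=True, method=method, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError) as exc:
                logger.warning("mixed model fit (%s) raised %s", method, exc)
                continue
            if result.converged:
                break
    return result


def fit_longitudinal(ds: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> ModelFitResult:
    """Fit the longitudinal change model and extract per-visit effects.

    ``ds`` is tidy (participant, optional eye, visit_month, value). The
    fixed-effect coefficient of each post-baseline visit is the modeled
    mean change from baseline at that visit.
    """
    df = ds.dropna(subset=["value"]).copy()
    if df["participant"].nunique() < 2:
        raise FitError("need at least 2 participants")
    visits = np.sort(df["visit_month"].unique())
    if len(visits) < 2:
        raise FitError("need at least 2 visits")
    baseline = int(visits[0])
    df["month"] = df["visit_month"].astype(float)

    nest = spec.nest_eyes and "eye" in df.columns and df["eye"].nunique() > 1
    if spec.nest_eyes and not nest:
        logger.warning("eye nesting requested but <2 eyes present; ignoring")
    if not nest and "eye" in df.columns:
        df = df.drop(columns=["eye"])

    random = spec.random
    fallback_applied = False
    result = _fit_once(df, baseline, random, nest)
    floor = _slope_var_floor(df, float(result.scale)) if result is not None else np.inf
    if random == "intercept_and_slope" and _is_degenerate(
        result, has_slope=True, slope_var_floor=floor
    ):
        logger.warning(
            "random intercept+slope model failed to converge or is degenerate; "
            "refitting with random intercept only"
        )
        random = "intercept_only"
        fallback_applied = True
        result = _fit_once(df, baseline, random, nest)
    if _is_degenerate(result, has_slope=(random == "intercept_and_slope")):
        raise FitError(
            "mixed model failed to converge even with random intercept only; "
            f"optimizer converged flag={getattr(result, 'converged', None)}"
        )

    z = float(norm.ppf(1 - spec.alpha / 2))
    rows = []
    prefix = f"C(visit_month, Treatment(reference={baseline}))"
    for visit in visits[1:]:
        name = f"{prefix}[T.{visit}]"
        if name not in result.params.index:
            name = f"{prefix}[T.{float(visit)}]"
        est = float(result.params[name])
        se = float(result.bse[name])
        # z-based p-values underflow to 0.0 for very large effects
        p = max(float(result.pvalues[name]), float(np.finfo(float).tiny))
        rows.append(
            {
                "visit_month": int(visit),
                "estimate": est,
                "ci_low": est - z * se,
                "ci_high": est + z * se,
                "p_value": p,
                "label": significance_label(p),
            }
        )

    vcomp: dict[str, float] = {"residual": float(result.scale)}
    cov_re = np.asarray(result.cov_re, dtype=float)
    if cov_re.size:
        vcomp["participant_intercept"] = float(cov_re[0, 0])
        if cov_re.shape[0] > 1:
            vcomp["participant_slope"] = float(cov_re[1, 1])
            vcomp["intercept_slope_cov"] = float(cov_re[0, 1])
    if nest:
        vcomp["eye_within_participant"] = float(result.vcomp[0])

    label = (
        f"linear mixed model: visit fixed effects (baseline={baseline}), "
        f"random {random.replace('_', ' ')}, compound symmetry"
        + (", eyes nested within participants" if nest else "")
    )
    return ModelFitResult(
        effects=pd.DataFrame(rows),
        variance_components=vcomp,
        converged=bool(result.converged),
        fallback_applied=fallback_applied,
        model_label=label,
        baseline_month=baseline,
        n_observations=len(df),
        result=result,
    )
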