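"""Treatment-effect estimation for binary trial outcomes.

Benefit ratios (risk ratios where the event is a favorable outcome) with
Wald log-scale confidence intervals, Wilson score intervals for stratum
rates, stratified rate differences, heterogeneity-of-treatment-effect tests
comparing nested logistic models by an analysis-of-deviance F test with
Benjamini-Hochberg correction, and counterfactual per-participant predicted
odds ratios from the fitted interaction model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)


@dataclass
class TwoByTwo:
    """Successes and totals per arm (arm1 = treatment, arm2 = comparator)."""

    successes_arm1: int
    n_arm1: int
    successes_arm2: int
    n_arm2: int

    def __post_init__(self) -> None:
        for k, n in ((self.successes_arm1, self.n_arm1),
                     (self.successes_arm2, self.n_arm2)):
            if n < 1:
                raise ValueError("each arm needs n >= 1")
            if not 0 <= k <= n:
                raise ValueError("successes must lie in [0, n]")


@dataclass
class EffectEstimate:
    ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "wald"


@dataclass
class HeterogeneityResult:
    deviance_null: float
    deviance_full: float
    df_diff: int
    df_resid: int
    dispersion: float
    f_statistic: float
    p_value: float
    model: object = None
    notes: list[str] = field(default_factory=list)


def benefit_ratio(table: TwoByTwo, conf: float = 0.95) -> EffectEstimate:
    """Wald-method benefit ratio with log-scale confidence interval.

    ratio = (a/n1) / (b/n2); CI = exp(log ratio +/- z * SE) with
    SE = sqrt(1/a - 1/n1 + 1/b - 1/n2); the two-sided p comes from the
    Wald z statistic on the log scale.  A comparator arm with zero
    successes has an infinite ratio, signaled explicitly.
    """
    a, n1 = table.successes_arm1, table.n_arm1
    b, n2 = table.successes_arm2, table.n_arm2
    if a == 0 and b == 0:
        raise ValueError("benefit ratio undefined: zero successes in both "
                         "arms")
    if b == 0:
        raise ZeroDivisionError("comparator arm has zero successes: "
                                "benefit ratio is infinite")
    ratio = (a / n1) / (b / n2)
    if a == 0:
        return EffectEstimate(0.0, 0.0, np.nan, np.nan, "wald")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    se = np.sqrt(1.0 / a - 1.0 / n1 + 1.0 / b - 1.0 / n2)
    log_ratio = np.log(ratio)
    lo, hi = np.exp(log_ratio - z * se), np.exp(log_ratio + z * se)
    p = 2.0 * stats.norm.sf(abs(log_ratio) / se)
    return EffectEstimate(float(ratio), float(lo), float(hi), float(p),
                          "wald")


def arm_percentages(table: TwoByTwo) -> tuple[int, int]:
    """Success percentages per arm, rounded half-even to integers."""
    p1 = round(100.0 * table.successes_arm1 / table.n_arm1)
    p2 = round(100.0 * table.successes_arm2 / table.n_arm2)
    return int(p1), int(p2)


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion; always in [0, 1]."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    # the Wilson formula hits the boundary exactly at k=0 and k=n;
    # clamp float noise so it does here too
    lo = 0.0 if k == 0 else max(float(lo), 0.0)
    hi = 1.0 if k == n else min(float(hi), 1.0)
    return float(lo), float(hi)


def stratified_rates(
    outcome: pd.Series,
    arm: pd.Series,
    stratum: pd.Series,
    treatment_label: str = "LBP",
    min_per_arm: int = 2,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-stratum, per-arm success rates with Wilson CIs and differences.

    Strata with fewer than ``min_per_arm`` participants in either arm are
    excluded (and logged).  The rate difference is treatment minus
    comparator, with a Wilson-based CI obtained by combining the two
    intervals in quadrature around the point difference.
    """
    df = pd.DataFrame({"y": outcome.astype(int), "arm": arm,
                       "stratum": stratum}).dropna()
    rows = []
    for s, grp in df.groupby("stratum", sort=False):
        sizes = grp.groupby("arm")["y"].size()
        if len(sizes) < 2 or (sizes < min_per_arm).any():
            logger.info("excluding stratum %r (fewer than %d participants "
                        "in an arm)", s, min_per_arm)
            continue
        per_arm = {}
        for a, sub in grp.groupby("arm"):
            k, n = int(sub["y"].sum()), len(sub)
            lo, hi = wilson_ci(k, n, conf)
            per_arm[a] = (k, n, k / n, lo, hi)
        trt = per_arm[treatment_label]
        (cmp_label,) = [a for a in per_arm if a != treatment_label]
        cmp_ = per_arm[cmp_label]
        diff = trt[2] - cmp_[2]
        half = np.sqrt(((trt[4] - trt[3]) / 2) ** 2
                       + ((cmp_[4] - cmp_[3]) / 2) ** 2)
        rows.append({
            "stratum": s,
            "k_treatment": trt[0], "n_treatment": trt[1],
            "rate_treatment": trt[2],
            "ci_low_treatment": trt[3], "ci_high_treatment": trt[4],
            "k_comparator": cmp_[0], "n_comparator": cmp_[1],
            "rate_comparator": cmp_[2],
            "ci_low_comparator": cmp_[3], "ci_high_comparator": cmp_[4],
            "rate_difference": diff,
            "diff_ci_low": diff - half, "diff_ci_high": diff + half,
        })
    if not rows:
        raise ValueError("all strata excluded")
    return pd.DataFrame(rows).set_index("stratum")


def _design_matrices(arm: pd.Series,
                     covariates: pd.DataFrame) -> tuple[np.ndarray,
                                                        np.ndarray]:
    # treatment indicator: code the lexicographically first label as 1 so
    # "LBP" vs "placebo" yields LBP = 1 deterministically
    labels = sorted(arm.unique())
    a = (arm == labels[0]).astype(float).values
    if covariates.shape[1] == 0:
        C = np.empty((len(arm), 0))
    else:
        C = covariates.values.astype(float)
    X_null = np.column_stack([np.ones(len(a)), a])
    inter = C * a[:, None]
    X_full = np.column_stack([np.ones(len(a)), a, C, inter])
    return X_null, X_full


def heterogeneity_test(
    outcome: pd.Series,
    arm: pd.Series,
    baseline_covariates: pd.DataFrame,
) -> HeterogeneityResult:
    """Nested-logistic analysis-of-deviance F test for effect heterogeneity.

    The null model predicts the binary outcome from the intervention arm
    alone; the full model adds the baseline covariates and their
    arm interactions.  F = (deviance difference / df difference) /
    dispersion, with the dispersion estimated from the full model's Pearson
    chi-square over its residual degrees of freedom, and the p-value from
    F(df_diff, n - p_full).  Categorical covariates should arrive one-hot
    encoded (drop-first); quantitative covariates are used as-is.
    """
    y = outcome.astype(float).values
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    X0, X1 = _design_matrices(arm, baseline_covariates)
    notes: list[str] = []
    try:
        m0 = sm.GLM(y, X0, family=sm.families.Binomial()).fit()
        m1 = sm.GLM(y, X1, family=sm.families.Binomial()).fit()
    except Exception as err:  # non-convergence / separation
        raise RuntimeError(f"logistic fit failed: {err}") from err
    fitted = m1.fittedvalues
    if np.any(fitted < 1e-8) or np.any(fitted > 1 - 1e-8):
        notes.append("possible separation: fitted probabilities at the "
                     "boundary; interpret the model p-value cautiously "
                     "and report stratum rates")
    df_diff = X1.shape[1] - X0.shape[1]
    df_resid = len(y) - X1.shape[1]
    if df_diff <= 0 or df_resid <= 0:
        return HeterogeneityResult(m0.deviance, m1.deviance, df_diff,
                                   df_resid, np.nan, np.nan, np.nan,
                                   model=m1,
                                   notes=notes + ["F undefined: no usable "
                                                  "degrees of freedom"])
    dispersion = m1.pearson_chi2 / df_resid
    f_stat = ((m0.deviance - m1.deviance) / df_diff) / dispersion
    p = float(stats.f.sf(f_stat, df_diff, df_resid))
    return HeterogeneityResult(
        deviance_null=float(m0.deviance), deviance_full=float(m1.deviance),
        df_diff=df_diff, df_resid=df_resid, dispersion=float(dispersion),
        f_statistic=float(f_stat), p_value=p, model=m1, notes=notes)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def counterfactual_predictions(
    result: HeterogeneityResult,
    arm: pd.Series,
    baseline_covariates: pd.DataFrame,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-participant predicted success probabilities under each arm.

    Uses the fitted full interaction model to predict each participant's
    outcome probability with the arm set to treatment and to comparator,
    the participant-level odds ratio between the two, and delta-method CIs
    computed on the linear-predictor scale and mapped through the inverse
    logit.
    """
    model = result.model
    if model is None or not np.all(np.isfinite(model.params)):
        raise ValueError("model not converged; cannot predict")
    C = (baseline_covariates.values.astype(float)
         if baseline_covariates.shape[1] else np.empty((len(arm), 0)))
    n = len(arm)
    z = stats.norm.ppf(0.5 + conf / 2.0)
    cov = model.cov_params()
    out = {}
    for label, a_val in (("treatment", 1.0), ("comparator", 0.0)):
        a = np.full(n, a_val)
        X = np.column_stack([np.ones(n), a, C, C * a[:, None]])
        eta = X @ model.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
        out[label] = (1 / (1 + np.exp(-eta)),
                      1 / (1 + np.exp(-(eta - z * se))),
                      1 / (1 + np.exp(-(eta + z * se))))
    p_t, lo_t, hi_t = out["treatment"]
    p_c, lo_c, hi_c = out["comparator"]
    odds = lambda p: p / (1 - p)  # noqa: E731
    return pd.DataFrame({
        "p_treatment": p_t, "p_treatment_low": lo_t, "p_treatment_high": hi_t,
        "p_comparator": p_c, "p_comparator_low": lo_c,
        "p_comparator_high": hi_c,
        "odds_ratio": odds(p_t) / odds(p_c),
    }, index=arm.index)
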