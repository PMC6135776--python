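"""Interquartile-scaled logistic and Cox effect estimates with validation AUCs.

Effects of continuous features are reported as the odds- or hazard-ratio
factor for moving the feature from its 1st to its 3rd quartile,
exp(beta * (Q3 - Q1)); categorical features are reported for the level
change itself.  Logistic models are tested with the likelihood-ratio
test; Cox models with Rao's score test (univariate; equivalent to the
log-rank test for a single categorical feature) or the Wald test
(multivariate).  Survival discrimination is internally validated by a
bootstrap optimism correction of Somers' Dxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import statsmodels.api as sm

logger = logging.getLogger(__name__)


class FitFailure(RuntimeError):
    """A model fit did not produce trustworthy numbers (separation,
    non-convergence, or too many bootstrap refit failures)."""


@dataclass
class EffectEstimate:
    """One feature's effect in one analysis."""

    feature: str
    baseline_value: float | str
    changed_value: float | str
    ratio_factor: float
    ci_low: float
    ci_high: float
    p_value: float
    p_type: str  # likelihood_ratio | score | wald | log_rank
    auc: float
    adjusted: bool
    adjusters: tuple[str, ...] = ()
    n: int = 0
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "feature": self.feature,
            "baseline_value": self.baseline_value,
            "changed_value": self.changed_value,
            "ratio_factor": self.ratio_factor,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "p_type": self.p_type,
            "auc": self.auc,
            "adjusted": self.adjusted,
            "adjusters": "+".join(self.adjusters),
            "n": self.n,
        }
        row.update(self.extra)
        return row


def _design(table: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    """Numeric design matrix: categoricals one-hot encoded (first level dropped)."""
    parts = []
    for col in columns:
        s = table[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _feature_change(s: pd.Series) -> tuple[float | str, float | str, float, str]:
    """Baseline/changed values and the coefficient scale for the report.

    Continuous: Q1 -> Q3 with scale Q3 - Q1.  Binary categorical: first
    level -> second level with scale 1 (the dummy step).
    """
    if pd.api.types.is_numeric_dtype(s):
        q1, q3 = s.quantile([0.25, 0.75])
        return float(q1), float(q3), float(q3 - q1), s.name
    levels = sorted(s.dropna().unique())
    if len(levels) != 2:
        raise ValueError(
            f"categorical feature {s.name!r} must be binary, has levels {levels}"
        )
    return levels[0], levels[1], 1.0, f"{s.name}_{levels[1]}"


def logistic_iqr_effect(
    table: pd.DataFrame,
    feature: str,
    adjusters: tuple[str, ...] = (),
    outcome: str = "metastasis_5yr",
) -> EffectEstimate:
    """Interquartile odds-ratio factor of one feature for a binary outcome.

    Fits a maximum-likelihood logistic model of ``outcome`` on the
    feature (plus any adjusters), reports exp(beta * (Q3 - Q1)) with its
    95% CI, the likelihood-ratio p-value for dropping the feature, and
    an AUC: the rank AUC of the feature itself in the univariate case,
    the model AUC in the multivariate case.
    """
    cols = [feature, *adjusters, outcome]
    data = table[cols].dropna()
    y = data[outcome].astype(float)
    if set(y.unique()) - {0.0, 1.0} or y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} must be binary and non-degenerate")
    baseline, changed, scale, coef_name = _feature_change(data[feature])
    x_full = sm.add_constant(_design(data, (feature, *adjusters)))
    x_red = sm.add_constant(_design(data, adjusters)) if adjusters else None
    try:
        full = sm.Logit(y, x_full).fit(disp=0, maxiter=200)
        if x_red is not None:
            reduced = sm.Logit(y, x_red).fit(disp=0, maxiter=200)
            llf_reduced = reduced.llf
        else:
            llf_reduced = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as err:
        raise FitFailure(f"logistic fit failed for {feature!r}: {err}") from err
    if not full.mle_retvals.get("converged", False):
        raise FitFailure(f"logistic fit did not converge for {feature!r}")
    beta = full.params[coef_name]
    se = full.bse[coef_name]
    lr_stat = 2.0 * (full.llf - llf_reduced)
    p = float(sps.chi2.sf(max(lr_stat, 0.0), df=1))
    if adjusters:
        auc = float(roc_auc_score(y, full.predict(x_full)))
    else:
        xv = _design(data, (feature,)).iloc[:, 0]
        auc = float(roc_auc_score(y, xv))
        auc = max(auc, 1.0 - auc)
    return EffectEstimate(
        feature=feature,
        baseline_value=baseline,
        changed_value=changed,
        ratio_factor=float(np.exp(beta * scale)),
        ci_low=float(np.exp((beta - 1.959963984540054 * se) * scale)),
        ci_high=float(np.exp((beta + 1.959963984540054 * se) * scale)),
        p_value=p,
        p_type="likelihood_ratio",
        auc=auc,
        adjusted=bool(adjusters),
        adjusters=tuple(adjusters),
        n=len(data),
        extra={"beta": float(beta), "se": float(se), "scale": float(scale)},
    )


def cox_score_test(x, time, event) -> tuple[float, float]:
    """Rao's score test of a single covariate in a Cox model at beta = 0.

    Uses the Breslow risk-set convention: at each event time the score
    accumulates x_i minus the risk-set mean of x, and the information
    accumulates the risk-set variance of x.  For a single binary
    covariate with no tied event times this is exactly the (unweighted)
    log-rank test.  Returns (chi-squared statistic, p-value).
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("score test requires at least one event")
    order = np.argsort(time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    u = 0.0
    info = 0.0
    n = len(x)
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = [t for t in range(i, j) if event[t] == 1]
        if d_idx:
            risk = x[i:]  # risk set: everyone with time >= time[i]
            mean = risk.mean()
            var = ((risk - mean) ** 2).mean()
            for t in d_idx:
                u += x[t] - mean
                info += var
        i = j
    if info <= 0:
        raise ValueError("covariate is constant over the risk sets")
    stat = u * u / info
    return float(stat), float(sps.chi2.sf(stat, df=1))


def _fit_cox(data: pd.DataFrame, time: str, event: str) -> CoxPHFitter:
    fitter = CoxPHFitter()
    try:
        fitter.fit(data, duration_col=time, event_col=event)
    except Exception as err:  # lifelines raises ConvergenceError subclasses
        raise FitFailure(f"Cox fit failed: {err}") from err
    return fitter


def cox_iqr_effect(
    table: pd.DataFrame,
    feature: str,
    adjusters: tuple[str, ...] = (),
    time: str = "dmfs_time_years",
    event: str = "dmfs_event",
    n_boot: int = 0,
    seed: int | None = None,
) -> EffectEstimate:
    """Interquartile hazard-ratio factor of one feature for survival.

    Univariate effects are tested with Rao's score test at beta = 0;
    multivariate (adjusted) effects with the Wald test of the fitted
    partial-likelihood model.  With ``n_boot`` > 0 the reported AUC is
    the bootstrap optimism-corrected value from :func:`bootstrap_auc`,
    otherwise the apparent AUC (Dxy + 1) / 2.
    """
    cols = [feature, *adjusters, time, event]
    data = table[cols].dropna().reset_index(drop=True)
    if data[event].sum() == 0:
        raise ValueError("all observations censored: survival effect undefined")
    if (data[time] <= 0).any():
        raise ValueError("event/censoring times must be positive")
    baseline, changed, scale, coef_name = _feature_change(data[feature])
    design = _design(data, (feature, *adjusters))
    fit_data = pd.concat([design, data[[time, event]]], axis=1)
    fitter = _fit_cox(fit_data, time, event)
    beta = float(fitter.params_[coef_name])
    se = float(fitter.standard_errors_[coef_name])
    if adjusters:
        p = float(fitter.summary.loc[coef_name, "p"])
        p_type = "wald"
    else:
        _, p = cox_score_test(design[coef_name], data[time], data[event])
        p_type = "score"
    apparent_auc = float(fitter.concordance_index_)
    if n_boot > 0:
        auc = bootstrap_auc(fit_data, time, event, n_boot=n_boot, seed=seed)
    else:
        auc = apparent_auc
    return EffectEstimate(
        feature=feature,
        baseline_value=baseline,
        changed_value=changed,
        ratio_factor=float(np.exp(beta * scale)),
        ci_low=float(np.exp((beta - 1.959963984540054 * se) * scale)),
        ci_high=float(np.exp((beta + 1.959963984540054 * se) * scale)),
        p_value=p,
        p_type=p_type,
        auc=auc,
        adjusted=bool(adjusters),
        adjusters=tuple(adjusters),
        n=len(data),
        extra={
            "beta": beta,
            "se": se,
            "scale": float(scale),
            "apparent_auc": apparent_auc,
        },
    )


def bootstrap_auc(
    fit_data: pd.DataFrame,
    time: str,
    event: str,
    n_boot: int = 100,
    seed: int | None = None,
) -> float:
    """Optimism-corrected survival AUC by the Harrell bootstrap.

    The apparent Somers' Dxy of the model fitted to the full data is
    reduced by the mean bootstrap optimism — for each resample, the Dxy
    of a model refitted on the resample evaluated on the resample minus
    its Dxy evaluated on the original data — and mapped back to the AUC
    scale via AUC = (Dxy + 1) / 2.  Resamples whose refit fails are
    skipped with a logged count; more than 50% failures abort.
    """
    rng = np.random.default_rng(seed)
    n = len(fit_data)
    covariates = [c for c in fit_data.columns if c not in (time, event)]

    def dxy(fitter: CoxPHFitter, data: pd.DataFrame) -> float:
        risk = -fitter.predict_partial_hazard(data[covariates])
        c = concordance_index(data[time], risk, data[event])
        return 2.0 * (c - 0.5)

    base = _fit_cox(fit_data, time, event)
    apparent = dxy(base, fit_data)
    optimism = []
    failures = 0
    for _ in range(n_boot):
        sample = fit_data.iloc[rng.integers(n, size=n)].reset_index(drop=True)
        try:
            boot = _fit_cox(sample, time, event)
            optimism.append(dxy(boot, sample) - dxy(boot, fit_data))
        except (FitFailure, ValueError):
            failures += 1
    if failures:
        logger.warning("bootstrap_auc: %d of %d refits failed", failures, n_boot)
    if failures > n_boot / 2:
        raise FitFailure(f"bootstrap_auc: {failures}/{n_boot} refits failed")
    corrected = apparent - float(np.mean(optimism))
    return (corrected + 1.0) / 2.0
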