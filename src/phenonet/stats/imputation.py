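"""Multiple imputation and Rubin pooling.

Missing values (completely at random in this package's synthetic
cohorts) are filled in m times: continuous columns by predictive-mean
matching against a Bayesian linear predictor built from the other
columns, categorical columns by a draw from the fitted category
frequencies.  Analyses run on every completed table and are combined by
Rubin's rules — pooled mean, total variance = within + (1 + 1/m) x
between, and a t reference with Rubin's degrees of freedom.  For
rank-test outputs (which have no variance on a coefficient scale) the
pooled report is the median p-value and median r^2 across imputations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

_PMM_DONORS = 5


_MAX_CATEGORICAL_LEVELS = 10


def _predictor_matrix(table: pd.DataFrame, exclude: str) -> np.ndarray:
    """Numeric predictor matrix from the other columns (mean/mode filled).

    High-cardinality categoricals (identifiers and the like) are left
    out; they would one-hot into near-singular designs.
    """
    cols = []
    for col in table.columns:
        if col == exclude:
            continue
        s = table[col]
        if pd.api.types.is_numeric_dtype(s):
            filled = s.astype(float).fillna(s.astype(float).mean())
            cols.append(filled.to_numpy())
        elif s.nunique(dropna=True) <= _MAX_CATEGORICAL_LEVELS:
            mode = s.mode()
            filled = s.fillna(mode.iloc[0] if len(mode) else "NA")
            dummies = pd.get_dummies(filled, drop_first=True, dtype=float)
            cols.extend(dummies[c].to_numpy() for c in dummies.columns)
    if not cols:
        return np.ones((len(table), 1))
    return np.column_stack([np.ones(len(table)), *cols])


def _impute_continuous(
    table: pd.DataFrame, col: str, rng: np.random.Generator
) -> np.ndarray:
    """One predictive-mean-matching draw for a continuous column."""
    y = table[col].to_numpy(dtype=float)
    miss = ~np.isfinite(y)
    x = _predictor_matrix(table, exclude=col)
    x_obs, y_obs = x[~miss], y[~miss]
    beta, *_ = np.linalg.lstsq(x_obs, y_obs, rcond=None)
    resid = y_obs - x_obs @ beta
    dof = max(len(y_obs) - x_obs.shape[1], 1)
    sigma2 = float(resid @ resid) / max(sps.chi2.rvs(dof, random_state=rng), 1e-12)
    p = x_obs.shape[1]
    xtx = x_obs.T @ x_obs + 1e-8 * np.eye(p)
    cov = sigma2 * np.linalg.inv(xtx)
    cov = (cov + cov.T) / 2.0 + 1e-12 * np.eye(p)  # enforce symmetric PSD
    beta_star = rng.multivariate_normal(beta, cov, method="eigh")
    pred_obs = x_obs @ beta  # donors matched on the ML predictor
    pred_miss = x[miss] @ beta_star
    out = y.copy()
    fill = np.empty(miss.sum())
    for i, pm in enumerate(pred_miss):
        nearest = np.argsort(np.abs(pred_obs - pm), kind="stable")[:_PMM_DONORS]
        fill[i] = y_obs[nearest[rng.integers(len(nearest))]]
    out[miss] = fill
    return out


def _impute_categorical(
    table: pd.DataFrame, col: str, rng: np.random.Generator
) -> pd.Series:
    """One draw from the fitted category frequencies for a categorical column."""
    s = table[col]
    miss = s.isna()
    freq = s.value_counts(normalize=True)
    draws = rng.choice(freq.index.to_numpy(), size=int(miss.sum()), p=freq.to_numpy())
    out = s.copy()
    out.loc[miss] = draws
    return out


def impute(
    table: pd.DataFrame,
    m: int = 100,
    seed: int | None = None,
    columns: list[str] | None = None,
) -> list[pd.DataFrame]:
    """m completed copies of a table with missing values filled in.

    ``columns`` limits which columns may be imputed (default: every
    column with missing values).  A fully missing column is rejected.
    With no missing values the m copies are identical to the input.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    targets = [c for c in (columns or table.columns) if table[c].isna().any()]
    for col in targets:
        if table[col].isna().all():
            raise ValueError(f"column {col!r} is fully missing; cannot impute")
    rng = np.random.default_rng(seed)
    completed = []
    for _ in range(m):
        filled = table.copy()
        for col in targets:
            if pd.api.types.is_numeric_dtype(table[col]):
                filled[col] = _impute_continuous(filled, col, rng)
            else:
                filled[col] = _impute_categorical(filled, col, rng)
        completed.append(filled)
    return completed


@dataclass
class PooledEstimate:
    estimate: float
    variance: float  # total variance: within + (1 + 1/m) * between
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    within_variance: float
    between_variance: float
    m: int


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules.

    Estimates must be on the coefficient (e.g. log-odds) scale.  The
    pooled estimate is the mean; total variance is the within-imputation
    mean plus (1 + 1/m) times the between-imputation variance; the CI
    and p-value use the t reference with Rubin's degrees of freedom
    (normal when the between-variance is zero).
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape or q.ndim != 1 or len(q) == 0:
        raise ValueError("estimates and variances must be equal-length 1-D arrays")
    m = len(q)
    qbar = float(q.mean())
    wbar = float(w.mean())
    between = float(q.var(ddof=1)) if m > 1 else 0.0
    total = wbar + (1.0 + 1.0 / m) * between
    if between > 0 and m > 1:
        df = (m - 1) * (1.0 + wbar / ((1.0 + 1.0 / m) * between)) ** 2
        tcrit = float(sps.t.ppf(0.975, df))
        p = float(2.0 * sps.t.sf(abs(qbar) / np.sqrt(total), df))
    else:
        df = np.inf
        tcrit = float(sps.norm.ppf(0.975))
        p = float(2.0 * sps.norm.sf(abs(qbar) / np.sqrt(total)))
    half = tcrit * float(np.sqrt(total))
    return PooledEstimate(
        estimate=qbar,
        variance=total,
        ci_low=qbar - half,
        ci_high=qbar + half,
        p_value=p,
        df=df,
        within_variance=wbar,
        between_variance=between,
        m=m,
    )


def pool_median(p_values, r_squared_values) -> tuple[float, float]:
    """Median p-value and median r^2 across imputations (rank-test pooling)."""
    return float(np.median(p_values)), float(np.median(r_squared_values))
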