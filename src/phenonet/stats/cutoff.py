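"""Minimum-p-value survival stratification with Altman's correction.

Dichotomising a continuous feature at the cutoff that minimises the
log-rank p-value inflates significance; the minimum p is therefore
reported alongside the corrected value

    P_cor = -1.63 * P_min * (1 + 2.35 * ln P_min),

which is valid for P_min < 0.1 and is clipped to [P_min, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


def altman_correction(p_min: float) -> float:
    """Corrected p-value for a minimum-p cutoff scan (valid for P_min < 0.1)."""
    if not 0 < p_min < 0.1:
        raise ValueError("Altman's correction is defined for 0 < P_min < 0.1")
    p_cor = -1.63 * p_min * (1.0 + 2.35 * np.log(p_min))
    return float(np.clip(p_cor, p_min, 1.0))


@dataclass
class CutoffResult:
    cutoff: float
    n_low: int
    n_high: int
    p_min: float
    p_corrected: float  # NaN when p_min >= 0.1 (correction undefined)
    scan: pd.DataFrame = field(repr=False)


def minp_cutoff(
    feature,
    time,
    event,
    quantile_window: tuple[float, float] = (0.1, 0.9),
) -> CutoffResult:
    """Scan observed feature values for the minimum log-rank p cutoff.

    Candidate cutoffs are the distinct observed values inside the inner
    quantile window (default 10-90%); each splits the cases into
    feature <= cutoff vs > cutoff, compared by the two-group log-rank
    test.  Ties on p are broken by the smallest cutoff.
    """
    feature = np.asarray(feature, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ok = np.isfinite(feature) & np.isfinite(time)
    feature, time, event = feature[ok], time[ok], event[ok]
    lo, hi = np.quantile(feature, quantile_window)
    candidates = [
        v for v in np.unique(feature) if lo <= v <= hi and (feature > v).any()
    ]
    if not candidates:
        raise ValueError("no admissible cutoff: too few distinct values in window")
    rows = []
    for v in candidates:
        high = feature > v
        res = logrank_test(time[~high], time[high], event[~high], event[high])
        rows.append({"cutoff": v, "p": float(res.p_value),
                     "n_low": int((~high).sum()), "n_high": int(high.sum())})
    scan = pd.DataFrame(rows)
    best = scan.sort_values(["p", "cutoff"]).iloc[0]
    p_min = float(best["p"])
    p_cor = altman_correction(p_min) if p_min < 0.1 else np.nan
    return CutoffResult(
        cutoff=float(best["cutoff"]),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        p_min=p_min,
        p_corrected=p_cor,
        scan=scan,
    )


def km_table(time, event, groups) -> pd.DataFrame:
    """Kaplan-Meier survival coordinates per group, exportable for plotting."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    frames = []
    for g in np.unique(groups):
        sel = groups == g
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel], label=str(g))
        ci = km.confidence_interval_survival_function_
        df = pd.DataFrame(
            {
                "group": str(g),
                "time": km.survival_function_.index,
                "survival": km.survival_function_.iloc[:, 0].to_numpy(),
                "ci_low": ci.iloc[:, 0].to_numpy(),
                "ci_high": ci.iloc[:, 1].to_numpy(),
            }
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
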