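"""Cohort filtering and rank-based association testing."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Exclusion-rule flag columns of a recruitment manifest, in report order.
EXCLUSION_FLAGS = (
    "missing_5yr_status",
    "metastasis_at_diagnosis",
    "no_tumor_in_section",
)


def filter_cohort(
    manifest: pd.DataFrame, flags: tuple[str, ...] = EXCLUSION_FLAGS
) -> pd.DataFrame:
    """Apply the cohort exclusion rules to a recruitment manifest.

    Rows flagged for a missing 5-year metastasis status, clinical
    metastasis at diagnosis, or a tumor-free tissue section are removed;
    the count removed under each rule is logged.  Flag columns absent
    from the manifest are ignored.
    """
    if len(manifest) == 0:
        return manifest.copy()
    present = [f for f in flags if f in manifest.columns]
    keep = np.ones(len(manifest), dtype=bool)
    for flag in present:
        col = manifest[flag].fillna(False).astype(bool).to_numpy()
        logger.info("exclusion rule %s: %d cases flagged", flag, int(col.sum()))
        keep &= ~col
    logger.info(
        "cohort filter: retained %d of %d cases", int(keep.sum()), len(manifest)
    )
    return manifest.loc[keep].reset_index(drop=True)


def mann_whitney_assoc(values, groups) -> tuple[float, float]:
    """Mann-Whitney association between a feature and a binary grouping.

    Returns the two-sided rank-sum p-value (exact for small tie-free
    samples, tie-corrected normal approximation otherwise) and the
    effect size r^2 = Z^2 / N, with Z recovered from the two-sided
    p-value of the test.

    Missing values are dropped pairwise; both groups must be non-empty.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values) & ~pd.isna(groups)
    values, groups = values[ok], groups[ok]
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly 2 non-empty levels, got {levels}")
    x = values[groups == levels[0]]
    y = values[groups == levels[1]]
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    n = len(values)
    z = sps.norm.isf(min(p, 1.0) / 2.0)
    r_squared = float(z**2 / n) if np.isfinite(z) else 1.0
    return p, r_squared
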