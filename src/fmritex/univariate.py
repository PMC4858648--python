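"""Univariate group comparisons, feature correlation, and t-test power.

Group differences use the pooled-variance (Student) two-sample t-test with
df = n_a + n_b - 2, two-sided, reproducible from either raw samples or the
printed summary statistics (mean/SD/n per group). No multiple-testing
correction is applied across the 20 features: p-values are reported raw.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.power import TTestIndPower

from fmritex.texture import FEATURE_NAMES
from fmritex.volumes import E, NE


@dataclasses.dataclass
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    group_ns: tuple[int, int]
    degenerate: bool = False  # zero pooled variance with unequal means


def ttest_from_summary(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int) -> TTestResult:
    """Two-sided pooled-variance t-test from summary statistics only."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n_a + n_b - 2
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return TTestResult(0.0, df, 1.0, (mean_a, mean_b), (sd_a, sd_b),
                               (n_a, n_b))
        return TTestResult(np.inf if mean_a > mean_b else -np.inf, df, 0.0,
                           (mean_a, mean_b), (sd_a, sd_b), (n_a, n_b),
                           degenerate=True)
    t, p = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                      equal_var=True)
    return TTestResult(float(t), float(df), float(p), (mean_a, mean_b),
                       (sd_a, sd_b), (n_a, n_b))


def ttest_pooled(sample_a, sample_b) -> TTestResult:
    """Two-sided pooled-variance t-test from raw samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    return ttest_from_summary(float(a.mean()), float(a.std(ddof=1)), a.size,
                              float(b.mean()), float(b.std(ddof=1)), b.size)


def group_comparison_table(table: pd.DataFrame,
                           features: tuple[str, ...] = FEATURE_NAMES
                           ) -> pd.DataFrame:
    """Per-feature E vs NE means, SDs and pooled t-test p (one row each)."""
    a = table[table["label"] == E]
    b = table[table["label"] == NE]
    rows = []
    for feat in features:
        res = ttest_pooled(a[feat], b[feat])
        rows.append({"feature": feat,
                     "mean_e": res.group_means[0], "sd_e": res.group_sds[0],
                     "mean_ne": res.group_means[1], "sd_ne": res.group_sds[1],
                     "t_stat": res.t_stat, "p_value": res.p_value})
    return pd.DataFrame(rows)


def feature_correlations(table: pd.DataFrame, features) -> pd.DataFrame:
    """Pearson correlation matrix of a feature subset.

    Zero-variance features produce NaN rows/columns (flagged, not raised).
    """
    sub = table[list(features)].astype(float)
    corr = sub.corr(method="pearson")
    zero_var = sub.std(ddof=1) == 0
    if zero_var.any():
        corr.loc[zero_var, :] = np.nan
        corr.loc[:, zero_var] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def power_curve(effect: float, sd: float, alpha: float,
                sample_sizes) -> pd.DataFrame:
    """Two-sample t-test power versus total sample size (equal group split).

    ``effect`` is the raw mean difference and ``sd`` the common standard
    deviation; power follows the noncentral-t formulation. At zero effect
    the power equals alpha (the type-I rate) for every n.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    d = effect / sd
    solver = TTestIndPower()
    rows = []
    for n_total in sample_sizes:
        n1 = n_total / 2.0
        power = float(solver.power(effect_size=d, nobs1=n1, ratio=1.0,
                                   alpha=alpha, alternative="two-sided"))
        rows.append({"n_total": int(n_total), "power": power})
    return pd.DataFrame(rows)
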