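"""Group statistics, longitudinal aggregation, and synergy detection.

Statistics follow the conventions used for the underlying experiments:
two-tailed unpaired Student's t-tests with pooled (equal) variance, and
box-plot summaries whose whiskers extend to Q3 + 1.5*IQR / Q1 - 1.5*IQR but
are clamped to the most extreme non-outlier data points.

"Synergy" between a combination arm and its monotherapies is operationalized
per day and per metric as: combination mean exceeds the best (largest)
monotherapy mean with a t-test p below ``alpha`` against that best
monotherapy.  No multiple-testing correction is applied by default,
matching pairwise reporting practice; a Bonferroni option is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "DegenerateVarianceError",
    "GroupSummary",
    "ttest_two_sample",
    "summarize_group",
    "synergy_table",
]


class DegenerateVarianceError(ValueError):
    """Zero pooled variance with unequal means: t is undefined."""


def ttest_two_sample(group_a, group_b) -> tuple[float, float]:
    """Two-tailed, unpaired, equal-variance Student's t-test.

    Pooled variance with ``df = n_a + n_b - 2``.  If the pooled variance is
    zero and the means are equal the test is vacuous and ``(0.0, 1.0)`` is
    returned by convention; zero variance with unequal means raises
    :class:`DegenerateVarianceError`.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    df = na + nb - 2
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled == 0:
        if diff == 0:
            return 0.0, 1.0
        raise DegenerateVarianceError("zero pooled variance with unequal means")
    t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * _sstats.t.sf(abs(t), df)
    return float(t), float(p)


@dataclass
class GroupSummary:
    """Box-plot style five-number summary plus whiskers and outliers."""

    group_label: str
    n: int
    mean: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)
    quantile_method: str = "hinges"


def _quantiles(values: np.ndarray, method: str) -> tuple[float, float, float]:
    if method == "hinges":
        q = np.quantile(values, [0.25, 0.5, 0.75], method="averaged_inverted_cdf")
    elif method == "linear":
        q = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    else:
        raise ValueError("quantile method must be 'hinges' or 'linear'")
    return tuple(float(x) for x in q)


def summarize_group(
    values, group_label: str = "", quantile_method: str = "hinges"
) -> GroupSummary:
    """Five-number summary with 1.5*IQR whiskers clamped to the data.

    The default quantile convention ("hinges", numpy's
    ``averaged_inverted_cdf``) gives Q1=2.5/Q3=6.5 on {1..8}; ``"linear"``
    (type-7 interpolation) is available as an alternative and the choice is
    recorded on the summary.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = _quantiles(v, quantile_method)
    iqr = q3 - q1
    fence_low = q1 - 1.5 * iqr
    fence_high = q3 + 1.5 * iqr
    inliers = v[(v >= fence_low) & (v <= fence_high)]
    # whiskers never extend beyond actual data points
    w_low = float(inliers.min()) if inliers.size else float(v.min())
    w_high = float(inliers.max()) if inliers.size else float(v.max())
    outliers = sorted(float(x) for x in v[(v < fence_low) | (v > fence_high)])
    return GroupSummary(
        group_label=group_label,
        n=int(v.size),
        mean=float(v.mean()),
        q1=q1,
        median=med,
        q3=q3,
        whisker_low=w_low,
        whisker_high=w_high,
        outliers=outliers,
        quantile_method=quantile_method,
    )


def synergy_table(
    data: pd.DataFrame,
    metric_columns: tuple[str, ...] = ("disruption_index", "apoptotic_density"),
    combination_arm: str = "combination",
    monotherapy_arms: tuple[str, ...] = ("PDT", "carboplatin"),
    arm_column: str = "treatment",
    day_column: str = "day",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-day, per-metric comparison of combination vs best monotherapy.

    ``data`` is a tidy replicate-level table (one row per well) with arm and
    day columns plus the metric columns.  For each day and metric the row
    reports the combination mean, the best monotherapy mean and arm, their
    difference, the t-test against the best monotherapy, and a ``synergy``
    flag: combination mean strictly above *both* monotherapy means with
    p < alpha.
    """
    required = set(monotherapy_arms) | {combination_arm}
    days = sorted(data[day_column].unique())
    rows = []
    n_tests = len(days) * len(metric_columns) if bonferroni else 1
    for day in days:
        sub = data[data[day_column] == day]
        present = set(sub[arm_column].unique())
        missing = sorted(required - present)
        if missing:
            raise ValueError(f"day {day}: missing arms {missing}")
        combo = sub[sub[arm_column] == combination_arm]
        for metric in metric_columns:
            combo_vals = combo[metric].dropna().to_numpy(dtype=float)
            mono_means = {
                arm: float(sub.loc[sub[arm_column] == arm, metric].dropna().mean())
                for arm in monotherapy_arms
            }
            best_arm = max(mono_means, key=mono_means.get)
            best_vals = (
                sub.loc[sub[arm_column] == best_arm, metric].dropna().to_numpy(dtype=float)
            )
            combo_mean = float(combo_vals.mean()) if combo_vals.size else np.nan
            diff = combo_mean - mono_means[best_arm]
            if combo_vals.size >= 2 and best_vals.size >= 2:
                try:
                    t, p = ttest_two_sample(combo_vals, best_vals)
                except DegenerateVarianceError:
                    t, p = np.inf * np.sign(diff), 0.0
            else:
                t, p = np.nan, np.nan
            threshold = alpha / n_tests
            exceeds_all = all(combo_mean > m for m in mono_means.values())
            flag = bool(exceeds_all and np.isfinite(p) and p < threshold)
            rows.append(
                {
                    day_column: day,
                    "metric": metric,
                    "combination_mean": combo_mean,
                    "best_monotherapy": best_arm,
                    "best_monotherapy_mean": mono_means[best_arm],
                    "difference": diff,
                    "t": t,
                    "p": p,
                    "synergy": flag,
                }
            )
    return pd.DataFrame(rows)
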