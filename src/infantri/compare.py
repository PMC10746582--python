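"""Feeding-group comparison: Wilcoxon rank-sum on censoring-aware ranks.

Breastfed and formula-fed infants are compared per analyte × age with the
two-sided Wilcoxon rank-sum (Mann–Whitney) test.  Left-censored results at a
common LOQ form one tied block ranked below every observed value, which the
rank test absorbs through its usual midrank tie correction — no imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import Limit, _rank_limit, rank_values, sort_series
from .preprocess import InfantRecord, Measurement, extract_series
from .screening import dixon_screen

EXACT = "exact"
NORMAL = "normal_approximation"

#: Largest min(group size) for which the exact null distribution is used
#: (ties force the normal approximation regardless).
EXACT_N_MAX = 10


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one breastfed vs not-breastfed contrast."""

    analyte: str
    age_months: int
    median_breastfed: Limit
    median_not_breastfed: Limit
    p_value: float
    test: str
    statistic: float
    n_breastfed: int
    n_not_breastfed: int


def wilcoxon_rank_sum(
    group_a: Sequence[Measurement], group_b: Sequence[Measurement]
) -> tuple[float, float, str]:
    """Two-sided rank-sum test; returns (U statistic of A, p, test kind).

    Exact enumeration when ``min(n) <= 10`` and there are no ties; otherwise
    the normal approximation with midrank tie correction and continuity
    correction.  Censored measurements rank below observed ones via
    surrogate keys (see :func:`infantri.estimators.rank_values`).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    a = rank_values(group_a)
    b = rank_values(group_b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # Every value tied: no evidence of a shift in either direction.
        return float(len(a) * len(b) / 2.0), 1.0, NORMAL
    if not has_ties and min(len(a), len(b)) <= EXACT_N_MAX:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), EXACT
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), min(float(res.pvalue), 1.0), NORMAL


def censored_median(series: Sequence[Measurement]) -> Limit:
    """Median on the censoring-aware ordering; inside the censored block it
    is reported censored at the LOQ."""
    vals, cens, loqs = sort_series(series)
    return _rank_limit(vals, cens, loqs, 0.5)


def compare_feeding_groups(
    cohort: Sequence[InfantRecord],
    analyte: str,
    age_months: int,
    screen_outliers: bool = True,
) -> ComparisonResult:
    """Compare feeding-group medians for one analyte at one age.

    Outlier screening is applied to each group exactly as on the estimation
    path, so the test and the reference intervals see the same data.
    """
    series = {}
    for feeding in ("breastfed", "not_breastfed"):
        s = extract_series(cohort, analyte, age_months, feeding)
        if not s:
            raise ValueError(
                f"no {feeding} records for {analyte} at {age_months} months"
            )
        if screen_outliers:
            report = dixon_screen([m.value for m in s])
            s = [s[i] for i in report.kept_indices]
        series[feeding] = s

    stat, p, test = wilcoxon_rank_sum(series["breastfed"], series["not_breastfed"])
    return ComparisonResult(
        analyte=analyte,
        age_months=age_months,
        median_breastfed=censored_median(series["breastfed"]),
        median_not_breastfed=censored_median(series["not_breastfed"]),
        p_value=p,
        test=test,
        statistic=stat,
        n_breastfed=len(series["breastfed"]),
        n_not_breastfed=len(series["not_breastfed"]),
    )


def format_p(p: float) -> str:
    """Display convention: two decimals, "< 0.001" below that threshold."""
    if p < 0.001:
        return "< 0.001"
    return f"{p:.2f}"
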