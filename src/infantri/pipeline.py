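"""End-to-end estimation pipeline.

Chains the study's analysis: CRP exclusion → per-series outlier screening →
method selection and reference-limit estimation (with bootstrap CIs) →
feeding-group comparison → partition testing, over the full grid of
analyte × age × group (all / breastfed / not_breastfed).

Results are plain dataclasses serializable to a flat CSV (one row per
series) and a structured JSON document that :mod:`infantri.report` can
render as a publication-style table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimators
from .compare import ComparisonResult, compare_feeding_groups, format_p
from .estimators import Limit, ReferenceInterval, estimate_series
from .preprocess import (
    ANALYTE_UNITS,
    DEFAULT_CRP_THRESHOLD,
    PANEL_ANALYTES,
    InfantRecord,
    exclude_elevated_crp,
    extract_series,
)
from .screening import GroupSummary, PartitionDecision, harris_boyd

GROUP_COLUMNS = ("all", "breastfed", "not_breastfed")
AGES = (3, 6)


@dataclass(frozen=True)
class SeriesResult:
    """One estimated series: its key, summary stats, and interval."""

    analyte: str
    age_months: int
    group: str  # all | breastfed | not_breastfed
    interval: ReferenceInterval
    median: Limit
    q25: Limit
    q75: Limit

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.analyte, self.age_months, self.group)


@dataclass
class PipelineResult:
    series: list[SeriesResult] = field(default_factory=list)
    comparisons: list[ComparisonResult] = field(default_factory=list)
    partitions: dict[str, list[dict]] = field(default_factory=dict)
    n_excluded_crp: int = 0
    n_input: int = 0


def _summary_limits(series) -> tuple[Limit, Limit, Limit]:
    from .compare import censored_median
    from .estimators import _rank_limit, sort_series

    vals, cens, loqs = sort_series(series)
    return (
        _rank_limit(vals, cens, loqs, 0.5),
        _rank_limit(vals, cens, loqs, 0.25),
        _rank_limit(vals, cens, loqs, 0.75),
    )


def _partition_rows(cohort, analyte, age_months) -> list[dict]:
    """Harris–Boyd decisions for feeding and sex at one analyte × age."""
    rows = []
    for factor, split in (
        ("feeding", lambda r: r.feeding),
        ("sex", lambda r: r.sex),
    ):
        groups: dict[str, list[float]] = {}
        for rec in cohort:
            if rec.age_months != age_months:
                continue
            m = rec.panel.get(analyte)
            if m is None:
                continue
            groups.setdefault(split(rec), []).append(m.value)
        labels = sorted(k for k in groups if k != "unknown")
        if len(labels) != 2:
            continue
        a, b = (np.asarray(groups[k], dtype=float) for k in labels)
        if len(a) < 2 or len(b) < 2:
            continue
        dec = harris_boyd(
            GroupSummary(len(a), float(a.mean()), float(a.std(ddof=1))),
            GroupSummary(len(b), float(b.mean()), float(b.std(ddof=1))),
        )
        rows.append(
            {
                "analyte": analyte,
                "age_months": age_months,
                "factor": factor,
                "groups": labels,
                "z": dec.z,
                "z_star": dec.z_star,
                "sd_ratio": dec.sd_ratio,
                "partition": dec.partition,
            }
        )
    return rows


def run_pipeline(
    cohort: Sequence[InfantRecord],
    crp_threshold: float = DEFAULT_CRP_THRESHOLD,
    ci_level: float = estimators.DEFAULT_CI_LEVEL,
    boot_reps: int = estimators.DEFAULT_BOOT_REPS,
    seed: int = 0,
    censoring_fallback: float = estimators.CENSORING_FALLBACK,
    compare_feeding: bool = True,
    analytes: Sequence[str] = PANEL_ANALYTES,
) -> PipelineResult:
    """Run the whole analysis on a cohort of records.

    Bootstrap randomness is derived from ``seed`` through per-series
    substreams in a fixed (analyte-major, age, group) order, so results are
    reproducible and independent of which analytes are requested together.
    """
    kept, excluded = exclude_elevated_crp(cohort, crp_threshold)
    result = PipelineResult(n_excluded_crp=len(excluded), n_input=len(cohort))

    for analyte in analytes:
        for age in AGES:
            for group in GROUP_COLUMNS:
                feeding = None if group == "all" else group
                series = extract_series(kept, analyte, age, feeding)
                if not series:
                    continue
                # Substream keyed by identity, not loop position.
                ss = np.random.SeedSequence(
                    [int(seed), PANEL_ANALYTES.index(analyte), age,
                     GROUP_COLUMNS.index(group)]
                )
                interval = estimate_series(
                    series,
                    ci_level=ci_level,
                    boot_reps=boot_reps,
                    seed=ss,
                    censoring_fallback=censoring_fallback,
                )
                kept_series = [series[i] for i in interval.outlier_report.kept_indices]
                med, q25, q75 = _summary_limits(kept_series)
                result.series.append(
                    SeriesResult(analyte, age, group, interval, med, q25, q75)
                )
            part = _partition_rows(kept, analyte, age)
            if part:
                result.partitions.setdefault(analyte, []).extend(part)
            if compare_feeding:
                try:
                    result.comparisons.append(
                        compare_feeding_groups(kept, analyte, age)
                    )
                except ValueError:
                    pass  # a feeding stratum absent in this cohort
    return result


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _limit_dict(limit: Limit | None) -> dict | None:
    if limit is None:
        return None
    return {"value": limit.value, "censored": limit.censored, "loq": limit.loq}


def _limit_from_dict(d: dict | None) -> Limit | None:
    if d is None:
        return None
    return Limit(value=d["value"], censored=d["censored"], loq=d.get("loq"))


def _ci_dict(ci) -> list | None:
    return None if ci is None else [_limit_dict(ci[0]), _limit_dict(ci[1])]


def _ci_from_list(lst) -> tuple[Limit, Limit] | None:
    return None if lst is None else (_limit_from_dict(lst[0]), _limit_from_dict(lst[1]))


def result_to_dict(result: PipelineResult) -> dict:
    """Structured JSON-ready document; round-trips via :func:`result_from_dict`."""
    return {
        "n_input": result.n_input,
        "n_excluded_crp": result.n_excluded_crp,
        "series": [
            {
                "analyte": s.analyte,
                "units": ANALYTE_UNITS.get(s.analyte, ""),
                "age_months": s.age_months,
                "group": s.group,
                "method": s.interval.method,
                "n_used": s.interval.n_used,
                "outliers_removed": s.interval.outlier_report.removed_count
                if s.interval.outlier_report
                else 0,
                "outlier_values": list(s.interval.outlier_report.removed_values)
                if s.interval.outlier_report
                else [],
                "median": _limit_dict(s.median),
                "q25": _limit_dict(s.q25),
                "q75": _limit_dict(s.q75),
                "lower": _limit_dict(s.interval.lower),
                "upper": _limit_dict(s.interval.upper),
                "lower_ci": _ci_dict(s.interval.lower_ci),
                "upper_ci": _ci_dict(s.interval.upper_ci),
            }
            for s in result.series
        ],
        "comparisons": [
            {
                "analyte": c.analyte,
                "age_months": c.age_months,
                "median_breastfed": _limit_dict(c.median_breastfed),
                "median_not_breastfed": _limit_dict(c.median_not_breastfed),
                "p_value": c.p_value,
                "p_display": format_p(c.p_value),
                "test": c.test,
                "n_breastfed": c.n_breastfed,
                "n_not_breastfed": c.n_not_breastfed,
            }
            for c in result.comparisons
        ],
        "partitions": result.partitions,
    }


def write_results_json(result: PipelineResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result_to_dict(result), fh, indent=1)


def results_to_frame(result: PipelineResult) -> pd.DataFrame:
    """Flat machine-readable results: one row per estimated series."""
    rows = []
    comp_p = {(c.analyte, c.age_months): c.p_value for c in result.comparisons}

    def num(limit: Limit | None):
        return None if limit is None else limit.value

    for s in result.series:
        iv = s.interval
        rows.append(
            {
                "analyte": s.analyte,
                "age_months": s.age_months,
                "group": s.group,
                "method": iv.method,
                "n": iv.n_used,
                "outliers_removed": iv.outlier_report.removed_count
                if iv.outlier_report
                else 0,
                "median": num(s.median),
                "q25": num(s.q25),
                "q75": num(s.q75),
                "LL": num(iv.lower),
                "LL_censored": iv.lower.censored,
                "LL_ci_lo": num(iv.lower_ci[0]) if iv.lower_ci else None,
                "LL_ci_hi": num(iv.lower_ci[1]) if iv.lower_ci else None,
                "UL": num(iv.upper),
                "UL_censored": iv.upper.censored,
                "UL_ci_lo": num(iv.upper_ci[0]) if iv.upper_ci else None,
                "UL_ci_hi": num(iv.upper_ci[1]) if iv.upper_ci else None,
                "p_nutrition": comp_p.get((s.analyte, s.age_months)),
            }
        )
    return pd.DataFrame(rows)


def write_results_csv(result: PipelineResult, path: str | Path) -> None:
    results_to_frame(result).to_csv(path, index=False)
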