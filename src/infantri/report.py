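"""Publication-style rendering of reference-interval results.

Rows are analyte-major, age-minor, with the three group columns
(all / breastfed / not breastfed) side by side, each showing n,
"median (IQR)", and the two reference limits with their 90% CIs —
censored entries rendered "< x".  Removed outliers are aggregated in
footnote lines, and an optional "current limits" file marks estimated
limits whose CI excludes the currently used laboratory limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .estimators import DIRECT, Limit

#: Printed decimals per analyte (the source table prints integers throughout).
DEFAULT_DECIMALS = {a: 0 for a in ("Alb", "ALT", "AST", "ALP", "GGT", "BIL", "BIL_conj")}

EN_DASH = "–"


def _fmt_value(limit: Limit | Mapping, decimals: int) -> str:
    if isinstance(limit, Mapping):
        limit = Limit(limit["value"], limit["censored"], limit.get("loq"))
    if limit.censored:
        return f"< {limit.loq:g}"
    return f"{limit.value:.{decimals}f}"


def format_limit(
    limit: Limit,
    ci: tuple[Limit, Limit] | None = None,
    decimals: int = 0,
    dash: str = EN_DASH,
) -> str:
    """Render "V (L–H)"; censored entries as "< x"; no CI → bare "V"."""
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    v = _fmt_value(limit, decimals)
    if ci is None:
        return v
    lo, hi = (_fmt_value(c, decimals) for c in ci)
    if hi.startswith("<"):
        hi = " " + hi  # "< 9 (< 9– < 9)" style: breathing space before "<"
    return f"{v} ({lo}{dash}{hi})"


def format_median_iqr(
    median: Limit, q25: Limit, q75: Limit, decimals: int = 0, dash: str = EN_DASH
) -> str:
    return format_limit(median, (q25, q75), decimals, dash)


@dataclass(frozen=True)
class ReportRow:
    """One rendered cell group: an analyte × age × group column."""

    analyte: str
    units: str
    age_months: int
    group: str
    n: int
    median_iqr: str
    ll_text: str
    ul_text: str
    method: str
    outliers_removed: int
    p_nutrition: str | None = None
    ll_outside_current: bool | None = None
    ul_outside_current: bool | None = None


def _series_key(s: Mapping) -> tuple:
    return (s["analyte"], s["age_months"], s["group"])


def _limit_of(d: Mapping | None) -> Limit | None:
    if d is None:
        return None
    return Limit(d["value"], d["censored"], d.get("loq"))


def _ci_of(lst) -> tuple[Limit, Limit] | None:
    if lst is None:
        return None
    return (_limit_of(lst[0]), _limit_of(lst[1]))


def build_report(
    results: Mapping,
    decimals: Mapping[str, int] | None = None,
    current_limits: pd.DataFrame | None = None,
    dash: str = EN_DASH,
) -> tuple[list[ReportRow], list[str]]:
    """Build report rows plus footnote lines from a results document
    (the JSON structure written by :mod:`infantri.pipeline`).

    ``current_limits``, when given, is a frame with columns
    analyte, age_months, current_ll, current_ul; an estimated limit is
    flagged "outside current" when its CI (or the point itself, for
    CI-less methods) lies entirely beyond the current limit.
    """
    series = results["series"]
    if not series:
        raise ValueError("no estimated series to report")
    keys = [_series_key(s) for s in series]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate series keys in results")
    decimals = dict(DEFAULT_DECIMALS) | dict(decimals or {})

    comp = {
        (c["analyte"], c["age_months"]): c["p_display"]
        for c in results.get("comparisons", [])
    }
    current = {}
    if current_limits is not None:
        for _, row in current_limits.iterrows():
            current[(row["analyte"], int(row["age_months"]))] = (
                float(row["current_ll"]),
                float(row["current_ul"]),
            )

    rows: list[ReportRow] = []
    footnotes: list[str] = []
    order = {k: i for i, k in enumerate(["all", "breastfed", "not_breastfed"])}
    series_sorted = sorted(
        series,
        key=lambda s: (
            list(DEFAULT_DECIMALS).index(s["analyte"])
            if s["analyte"] in DEFAULT_DECIMALS
            else 99,
            s["age_months"],
            order.get(s["group"], 9),
        ),
    )
    for s in series_sorted:
        dec = decimals.get(s["analyte"], 0)
        ll, ul = _limit_of(s["lower"]), _limit_of(s["upper"])
        ll_ci, ul_ci = _ci_of(s.get("lower_ci")), _ci_of(s.get("upper_ci"))
        ll_out = ul_out = None
        cur = current.get((s["analyte"], s["age_months"]))
        if cur is not None:
            cur_ll, cur_ul = cur
            lo_band = ll_ci or (ll, ll)
            hi_band = ul_ci or (ul, ul)
            ll_out = cur_ll < lo_band[0].value or cur_ll > lo_band[1].value
            ul_out = cur_ul < hi_band[0].value or cur_ul > hi_band[1].value
        row = ReportRow(
            analyte=s["analyte"],
            units=s.get("units", ""),
            age_months=s["age_months"],
            group=s["group"],
            n=s["n_used"] + s.get("outliers_removed", 0),
            median_iqr=format_median_iqr(
                _limit_of(s["median"]), _limit_of(s["q25"]), _limit_of(s["q75"]),
                dec, dash,
            ),
            ll_text=format_limit(ll, ll_ci, dec, dash),
            ul_text=format_limit(ul, ul_ci, dec, dash),
            method=s["method"],
            outliers_removed=s.get("outliers_removed", 0),
            p_nutrition=comp.get((s["analyte"], s["age_months"]))
            if s["group"] == "all"
            else None,
            ll_outside_current=ll_out,
            ul_outside_current=ul_out,
        )
        rows.append(row)
        if row.outliers_removed:
            footnotes.append(
                f"{row.analyte}, {row.age_months} months, {row.group}: "
                f"{row.outliers_removed} outlier(s) removed"
            )
        if s["method"] == DIRECT:
            footnotes.append(
                f"{row.analyte}, {row.age_months} months, {row.group}: "
                "limits are direct 2.5%/97.5% percentiles (no CI)"
            )
    return rows, footnotes


def report_to_frame(rows: Iterable[ReportRow]) -> pd.DataFrame:
    """CSV-ready report (ASCII hyphens in ranges)."""
    df = pd.DataFrame([vars(r) for r in rows])
    for col in ("median_iqr", "ll_text", "ul_text"):
        df[col] = df[col].str.replace(EN_DASH, "-")
    return df


def render_text(rows: list[ReportRow], footnotes: list[str]) -> str:
    """Fixed-width text table, one line per analyte × age × group."""
    header = (
        f"{'Analyte':<9} {'Age':>3} {'Group':<14} {'n':>4} "
        f"{'Median (IQR)':<22} {'LL (90% CI)':<22} {'UL (90% CI)':<22} {'p (feeding)':<10}"
    )
    lines = [header, "-" * len(header)]
    for r in rows:
        lines.append(
            f"{r.analyte:<9} {r.age_months:>3} {r.group:<14} {r.n:>4} "
            f"{r.median_iqr:<22} {r.ll_text:<22} {r.ul_text:<22} "
            f"{r.p_nutrition or '':<10}"
        )
    if footnotes:
        lines.append("")
        lines.extend(f"* {f}" for f in footnotes)
    return "\n".join(lines) + "\n"


def read_current_limits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"analyte", "age_months", "current_ll", "current_ul"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"current-limits file missing columns {sorted(missing)}")
    return df
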