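"""Record types, censored-value parsing, and pre-estimation filtering.

Laboratory analyzers report results below the measuring range only as
``"< x"`` where ``x`` is the limit of quantitation (LOQ).  Such results are
*left-censored*: all that is known is that the true concentration lies below
``x``.  This module parses and serializes that notation losslessly, validates
per-infant records, and applies the healthy-reference exclusion filter
(C-reactive protein above threshold, indicating acute infection).

Censoring is propagated, never imputed: a censored :class:`Measurement`
carries the LOQ as its numeric value plus a flag, and every downstream
rank-based procedure treats censored results as a tied block below all
observed values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: The liver panel, in canonical column order.
PANEL_ANALYTES = ("Alb", "ALT", "AST", "ALP", "GGT", "BIL", "BIL_conj")

#: Units per analyte (CRP is used only for exclusion).
ANALYTE_UNITS = {
    "Alb": "g/L",
    "ALT": "U/L",
    "AST": "U/L",
    "ALP": "U/L",
    "GGT": "U/L",
    "BIL": "µmol/L",
    "BIL_conj": "µmol/L",
    "CRP": "mg/L",
}

FEEDING_GROUPS = ("breastfed", "not_breastfed")

#: Default CRP exclusion threshold (mg/L); subjects strictly above are removed.
DEFAULT_CRP_THRESHOLD = 4.0


class ParseError(ValueError):
    """Raised when a raw cell cannot be read as a measurement."""


class ValidationError(ValueError):
    """Raised when a record violates the cohort schema."""


@dataclass(frozen=True)
class Measurement:
    """One analyte result, possibly left-censored at its LOQ.

    For a censored measurement ``value == loq`` and the semantic reading is
    "result < loq"; for an observed one ``loq`` is ``None``.
    """

    analyte: str
    value: float
    censored: bool = False
    loq: float | None = None

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValidationError(
                f"{self.analyte}: measurement value must be positive, got {self.value}"
            )
        if self.censored:
            if self.loq is None or self.loq != self.value:
                raise ValidationError(
                    f"{self.analyte}: censored measurement must carry value == loq"
                )
        elif self.loq is not None:
            raise ValidationError(
                f"{self.analyte}: loq is only stored for censored measurements"
            )


@dataclass(frozen=True)
class InfantRecord:
    """One subject visit: demographics, CRP, and the liver panel."""

    subject_id: str
    age_months: int
    feeding: str
    sex: str
    crp: Measurement
    panel: dict[str, Measurement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_months not in (3, 6):
            raise ValidationError(
                f"{self.subject_id}: age_months must be 3 or 6, got {self.age_months}"
            )
        if self.feeding not in FEEDING_GROUPS:
            raise ValidationError(
                f"{self.subject_id}: feeding must be one of {FEEDING_GROUPS}"
            )
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"{self.subject_id}: bad sex {self.sex!r}")
        unknown = set(self.panel) - set(PANEL_ANALYTES)
        if unknown:
            raise ValidationError(
                f"{self.subject_id}: unknown panel analytes {sorted(unknown)}"
            )


_CENSORED_RE = re.compile(r"^<\s*(\S+)$")


def parse_value(text: str, analyte: str, *, row: object = None) -> Measurement:
    """Parse a raw CSV cell into a :class:`Measurement`.

    ``"<x"`` (internal whitespace allowed) yields a censored measurement with
    LOQ ``x``; a plain numeral yields an observed one.  Non-numeric, zero or
    negative payloads raise :class:`ParseError` naming the offending cell.
    """
    where = f" (row {row}, column {analyte})" if row is not None else f" ({analyte})"
    stripped = text.strip()
    if not stripped:
        raise ParseError(f"empty cell{where}")
    m = _CENSORED_RE.match(stripped)
    payload = m.group(1) if m else stripped
    try:
        value = float(payload)
    except ValueError:
        raise ParseError(f"cannot parse {text!r} as a measurement{where}") from None
    if not value > 0:
        raise ParseError(f"non-positive measurement {text!r}{where}")
    if m:
        return Measurement(analyte, value, censored=True, loq=value)
    return Measurement(analyte, value)


def serialize_value(m: Measurement) -> str:
    """Canonical text form: ``"<{loq:g}"`` when censored, else ``repr(value)``.

    ``repr`` of a float round-trips bit-exactly, so
    ``parse_value(serialize_value(m)) == m`` for observed measurements; for
    censored ones the ``%g`` LOQ rendering is canonical (LOQs are short
    decimals by construction).
    """
    if m.censored:
        return f"<{m.loq:g}"
    return repr(float(m.value))


def exclude_elevated_crp(
    cohort: Sequence[InfantRecord],
    threshold: float = DEFAULT_CRP_THRESHOLD,
) -> tuple[list[InfantRecord], list[InfantRecord]]:
    """Split a cohort into (kept, excluded) by the CRP infection filter.

    A record is excluded when its observed CRP is *strictly* greater than
    ``threshold``.  A censored CRP (below the measuring range) is by
    definition below its LOQ and is kept, provided its LOQ does not exceed
    the threshold — a censoring limit above the threshold would leave the
    comparison indeterminate and raises :class:`ValidationError`.
    Input order is preserved in both outputs.
    """
    if not threshold > 0:
        raise ValidationError(f"CRP threshold must be positive, got {threshold}")
    kept: list[InfantRecord] = []
    excluded: list[InfantRecord] = []
    for rec in cohort:
        crp = rec.crp
        if crp is None:
            raise ValidationError(f"{rec.subject_id}: missing CRP measurement")
        if crp.censored:
            if crp.loq > threshold:
                raise ValidationError(
                    f"{rec.subject_id}: censored CRP '<{crp.loq:g}' is indeterminate "
                    f"against threshold {threshold:g}"
                )
            kept.append(rec)
        elif crp.value > threshold:
            excluded.append(rec)
        else:
            kept.append(rec)
    return kept, excluded


def extract_series(
    cohort: Iterable[InfantRecord],
    analyte: str,
    age_months: int,
    feeding: str | None = None,
) -> list[Measurement]:
    """Collect one analyte's measurements for an age group.

    ``feeding=None`` pools both feeding groups (the "all infants" column).
    Records with a missing cell for the analyte are skipped, matching the
    per-analyte availability of real panels.
    """
    if analyte not in PANEL_ANALYTES:
        raise ValidationError(f"unknown analyte {analyte!r}")
    if feeding is not None and feeding not in FEEDING_GROUPS:
        raise ValidationError(f"unknown feeding group {feeding!r}")
    out = []
    for rec in cohort:
        if rec.age_months != age_months:
            continue
        if feeding is not None and rec.feeding != feeding:
            continue
        m = rec.panel.get(analyte)
        if m is not None:
            out.append(m)
    return out


def cohort_to_frame(cohort: Sequence[InfantRecord]) -> pd.DataFrame:
    """Serialize a cohort to the canonical tabular form (all cells text)."""
    rows = []
    for rec in cohort:
        row = {
            "subject_id": rec.subject_id,
            "age_months": str(rec.age_months),
            "feeding": rec.feeding,
            "sex": rec.sex,
            "crp": serialize_value(rec.crp),
        }
        for a in PANEL_ANALYTES:
            m = rec.panel.get(a)
            row[a] = serialize_value(m) if m is not None else ""
        rows.append(row)
    cols = ["subject_id", "age_months", "feeding", "sex", "crp", *PANEL_ANALYTES]
    return pd.DataFrame(rows, columns=cols)


def write_cohort_csv(cohort: Sequence[InfantRecord], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[InfantRecord]:
    """Read a cohort CSV (UTF-8, '.' decimal separator, header required)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"subject_id", "age_months", "feeding", "sex", "crp"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing columns {sorted(missing)}")
    analyte_cols = [c for c in df.columns if c in PANEL_ANALYTES]
    records = []
    for idx, row in df.iterrows():
        panel = {}
        for a in analyte_cols:
            cell = row[a]
            if cell.strip():
                panel[a] = parse_value(cell, a, row=idx)
        try:
            age = int(row["age_months"])
        except ValueError:
            raise ValidationError(
                f"row {idx}: bad age_months {row['age_months']!r}"
            ) from None
        records.append(
            InfantRecord(
                subject_id=row["subject_id"],
                age_months=age,
                feeding=row["feeding"],
                sex=row["sex"] or "unknown",
                crp=parse_value(row["crp"], "CRP", row=idx),
                panel=panel,
            )
        )
    return records
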