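"""Synthetic infant-cohort generator.

The study data behind published infant liver-biochemistry reference intervals
are not openly deposited, so this module generates cohorts with the same
statistical structure: right-skewed, strictly positive analyte distributions
summarized by group medians and interquartile ranges, left-censoring at
analyte-specific limits of quantitation, separate parameters per
age × feeding group, and a small fraction of subjects with elevated
C-reactive protein who must be excluded downstream.

Analytes are modelled as log-normal.  A log-normal is parameterized here by
``log_median`` (its median is ``exp(log_median)``) and ``log_sigma`` (the SD
on the log scale); :func:`fit_lognormal_from_median_iqr` maps a published
"median (q25–q75)" summary onto those parameters exactly, matching the median
and the quartile *ratio*.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .preprocess import (
    ANALYTE_UNITS,
    FEEDING_GROUPS,
    PANEL_ANALYTES,
    InfantRecord,
    Measurement,
    write_cohort_csv,
)

#: Standard-normal 75th percentile; IQR of a log-normal spans
#: ``2 * Z75 * log_sigma`` on the log scale.
Z75 = float(stats.norm.ppf(0.75))


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class AnalyteSpec:
    """Log-normal model for one analyte in one group, plus its LOQ."""

    name: str
    units: str
    loq: float
    log_median: float
    log_sigma: float

    def __post_init__(self) -> None:
        if self.name not in (*PANEL_ANALYTES, "CRP"):
            raise ConfigError(f"unknown analyte {self.name!r}")
        if not self.loq > 0:
            raise ConfigError(f"{self.name}: loq must be positive")
        if not self.log_sigma > 0:
            raise ConfigError(f"{self.name}: log_sigma must be positive")

    @property
    def median(self) -> float:
        return math.exp(self.log_median)


@dataclass(frozen=True)
class GroupSpec:
    """One age × feeding cell of the design: sample size and analyte models."""

    age_months: int
    feeding: str
    n: int
    analyte_specs: tuple[AnalyteSpec, ...]
    crp_elevated_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.age_months not in (3, 6):
            raise ConfigError(f"age_months must be 3 or 6, got {self.age_months}")
        if self.feeding not in FEEDING_GROUPS:
            raise ConfigError(f"feeding must be one of {FEEDING_GROUPS}")
        if self.n < 0:
            raise ConfigError("group size n must be >= 0")
        if not 0.0 <= self.crp_elevated_prob <= 1.0:
            raise ConfigError("crp_elevated_prob must lie in [0, 1]")
        names = [s.name for s in self.analyte_specs]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate analyte specs in group")

    def spec_for(self, analyte: str) -> AnalyteSpec | None:
        for s in self.analyte_specs:
            if s.name == analyte:
                return s
        return None


@dataclass(frozen=True)
class CohortConfig:
    """Full generator parameterization: groups, CRP filter level, seed."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0
    crp_threshold: float = 4.0
    crp_loq: float = 0.1

    def __post_init__(self) -> None:
        keys = [(g.age_months, g.feeding) for g in self.groups]
        if len(keys) != len(set(keys)):
            raise ConfigError("group (age, feeding) pairs must be unique")
        if not self.crp_threshold > 0:
            raise ConfigError("crp_threshold must be positive")
        if not 0 < self.crp_loq <= self.crp_threshold:
            raise ConfigError("crp_loq must lie in (0, crp_threshold]")

    def group(self, age_months: int, feeding: str) -> GroupSpec:
        for g in self.groups:
            if (g.age_months, g.feeding) == (age_months, feeding):
                return g
        raise ConfigError(f"no group ({age_months}, {feeding}) in config")


def fit_lognormal_from_median_iqr(
    median: float, q25: float, q75: float
) -> tuple[float, float]:
    """Map a "median (q25–q75)" summary to (log_median, log_sigma).

    The returned log-normal has exactly the given median, and its quartile
    ratio equals ``q75/q25`` (a two-parameter family cannot also match both
    quartiles individually unless the summary is log-symmetric).

    Raises :class:`ConfigError` unless ``0 < q25 < median < q75``.
    """
    if not (0 < q25 < median < q75):
        raise ConfigError(
            f"invalid summary: need 0 < q25 < median < q75, "
            f"got median={median}, q25={q25}, q75={q75}"
        )
    log_sigma = math.log(q75 / q25) / (2.0 * Z75)
    return math.log(median), log_sigma


def true_quantile(spec: AnalyteSpec, p: float) -> float:
    """Exact p-quantile of the spec's log-normal: ``exp(log_median + z_p·log_sigma)``."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must lie in (0, 1), got {p}")
    return math.exp(spec.log_median + stats.norm.ppf(p) * spec.log_sigma)


def _group_rng(seed: int, group: GroupSpec) -> np.random.Generator:
    # Substream derived from the group identity, not list position, so adding
    # a group never perturbs the draws of existing ones.
    feed_code = FEEDING_GROUPS.index(group.feeding)
    ss = np.random.SeedSequence([int(seed), group.age_months, feed_code])
    return np.random.default_rng(ss)


def _measurement(analyte: str, value: float, loq: float) -> Measurement:
    if value < loq:
        return Measurement(analyte, loq, censored=True, loq=loq)
    return Measurement(analyte, float(value))


def generate_cohort(config: CohortConfig) -> list[InfantRecord]:
    """Draw a full cohort; identical config (incl. seed) gives identical output.

    Per subject: each panel analyte with a spec in its group is drawn
    log-normal and censored at the spec's LOQ; CRP is a two-component
    mixture — with probability ``crp_elevated_prob`` an "infection" value
    strictly above ``crp_threshold`` (uniform up to 10× the threshold),
    otherwise a bulk value uniform on (0, threshold], itself censored at
    ``crp_loq``; sex is balanced Bernoulli.
    """
    records: list[InfantRecord] = []
    for group in config.groups:
        rng = _group_rng(config.seed, group)
        n = group.n
        draws = {
            spec.name: rng.lognormal(spec.log_median, spec.log_sigma, size=n)
            for spec in group.analyte_specs
            if spec.name != "CRP"
        }
        elevated = rng.random(n) < group.crp_elevated_prob
        crp_bulk = rng.uniform(0.0, config.crp_threshold, size=n)
        crp_hot = rng.uniform(config.crp_threshold, 10.0 * config.crp_threshold, size=n)
        sex_draw = rng.random(n)
        tag = f"{group.age_months}m-{'bf' if group.feeding == 'breastfed' else 'ff'}"
        for i in range(n):
            panel = {}
            for spec in group.analyte_specs:
                if spec.name == "CRP":
                    continue
                panel[spec.name] = _measurement(spec.name, draws[spec.name][i], spec.loq)
            crp_value = crp_hot[i] if elevated[i] else crp_bulk[i]
            crp = _measurement("CRP", crp_value, config.crp_loq)
            records.append(
                InfantRecord(
                    subject_id=f"{tag}-{i:04d}",
                    age_months=group.age_months,
                    feeding=group.feeding,
                    sex="male" if sex_draw[i] < 0.5 else "female",
                    crp=crp,
                    panel=panel,
                )
            )
    return records


def simulate_to_csv(config: CohortConfig, path: str | Path) -> list[InfantRecord]:
    """Generate a cohort and write it as the canonical CSV; returns the records."""
    cohort = generate_cohort(config)
    write_cohort_csv(cohort, path)
    return cohort


# ---------------------------------------------------------------------------
# TOML configuration
# ---------------------------------------------------------------------------

def _analyte_spec_from_dict(d: dict, group_tag: str) -> AnalyteSpec:
    name = d.get("name")
    if name is None:
        raise ConfigError(f"{group_tag}: analyte entry without a name")
    units = d.get("units", ANALYTE_UNITS.get(name, ""))
    loq = d.get("loq")
    if loq is None:
        raise ConfigError(f"{group_tag}/{name}: loq is required")
    if "log_median" in d or "log_sigma" in d:
        if not ("log_median" in d and "log_sigma" in d):
            raise ConfigError(
                f"{group_tag}/{name}: log_median and log_sigma must be given together"
            )
        lm, ls = float(d["log_median"]), float(d["log_sigma"])
    else:
        try:
            lm, ls = fit_lognormal_from_median_iqr(
                float(d["median"]), float(d["q25"]), float(d["q75"])
            )
        except KeyError as e:
            raise ConfigError(
                f"{group_tag}/{name}: need median/q25/q75 or log_median/log_sigma"
            ) from e
    return AnalyteSpec(name=name, units=units, loq=float(loq), log_median=lm, log_sigma=ls)


def read_config_toml(path: str | Path) -> CohortConfig:
    """Load a :class:`CohortConfig` from a TOML file.

    Layout: top-level ``seed``, ``crp_threshold``, ``crp_loq``; one
    ``[[group]]`` table per age × feeding cell with ``age_months``,
    ``feeding``, ``n``, ``crp_elevated_prob`` and nested ``[[group.analyte]]``
    entries giving either ``median``/``q25``/``q75`` or explicit
    ``log_median``/``log_sigma``, plus ``loq``.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    groups = []
    for g in raw.get("group", []):
        tag = f"group({g.get('age_months')}, {g.get('feeding')})"
        specs = tuple(_analyte_spec_from_dict(a, tag) for a in g.get("analyte", []))
        groups.append(
            GroupSpec(
                age_months=int(g["age_months"]),
                feeding=str(g["feeding"]),
                n=int(g["n"]),
                analyte_specs=specs,
                crp_elevated_prob=float(g.get("crp_elevated_prob", 0.0)),
            )
        )
    return CohortConfig(
        groups=tuple(groups),
        seed=int(raw.get("seed", 0)),
        crp_threshold=float(raw.get("crp_threshold", 4.0)),
        crp_loq=float(raw.get("crp_loq", 0.1)),
    )


def config_to_toml(config: CohortConfig) -> str:
    """Render a config back to TOML text (explicit log-scale parameters)."""
    lines = [
        f"seed = {int(config.seed)}",
        f"crp_threshold = {float(config.crp_threshold)!r}",
        f"crp_loq = {float(config.crp_loq)!r}",
    ]
    for g in config.groups:
        lines += [
            "",
            "[[group]]",
            f"age_months = {g.age_months}",
            f'feeding = "{g.feeding}"',
            f"n = {g.n}",
            f"crp_elevated_prob = {float(g.crp_elevated_prob)!r}",
        ]
        for s in g.analyte_specs:
            lines += [
                "",
                "  [[group.analyte]]",
                f'  name = "{s.name}"',
                f'  units = "{s.units}"',
                f"  loq = {float(s.loq)!r}",
                f"  log_median = {float(s.log_median)!r}",
                f"  log_sigma = {float(s.log_sigma)!r}",
            ]
    return "\n".join(lines) + "\n"
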