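"""Default cohort parameterization for the infant liver panel.

Encodes published group summaries (median and interquartile range per
analyte × age × feeding group) from a cohort of 619 healthy term Finnish
infants sampled at 3 and 6 months, together with the assay limits of
quantitation implied by the "< x" entries of the published table
(ALT < 9 U/L, GGT < 7 U/L, total bilirubin < 3 µmol/L, conjugated
bilirubin < 2 µmol/L).

Where a published summary is itself censored (a median or quartile printed
as "< x"), a log-normal cannot be fit from it; those cells carry explicit
log-scale parameters chosen once (see docs/methods.md) so that the observed
part of the summary is respected:

* total bilirubin, not breastfed: median 4, q75 from the summary, q25
  censored — spread fit from the upper half only;
* conjugated bilirubin with censored median "< 2": sub-LOQ median fixed at
  1.5 µmol/L (1.3 at 6 months, not breastfed, whose q75 is already 2) and
  spread fit from median → q75.

Group sizes: the published per-group n's are *post* CRP exclusion; the
generator defaults inflate them by 1/(1 − 42/619) so that the filtered
series sizes match the published table in expectation.
"""

from __future__ import annotations

import math

from .cohort import AnalyteSpec, CohortConfig, GroupSpec, Z75, fit_lognormal_from_median_iqr
from .preprocess import ANALYTE_UNITS

#: Fraction of subjects with CRP above the 4 mg/L exclusion threshold
#: (42 of 619 in the source cohort).
CRP_ELEVATED_PROB = 42.0 / 619.0

#: Limits of quantitation per analyte.  ALT/GGT/BIL/BIL_conj are the assay
#: limits visible in the published table; the rest are nominal low limits
#: that the simulated distributions essentially never reach.
LOQS = {
    "Alb": 10.0,
    "ALT": 9.0,
    "AST": 5.0,
    "ALP": 20.0,
    "GGT": 7.0,
    "BIL": 3.0,
    "BIL_conj": 2.0,
}

#: Published post-exclusion group sizes (modal per-analyte n).
TABLE_GROUP_N = {
    (3, "breastfed"): 226,
    (3, "not_breastfed"): 50,
    (6, "breastfed"): 175,
    (6, "not_breastfed"): 98,
}

#: Published median (q25, q75) per (analyte, age, feeding); None where the
#: summary is censored and explicit parameters are used instead.
GROUP_SUMMARIES = {
    (3, "breastfed"): {
        "Alb": (41, 39, 43),
        "ALT": (36, 24, 52),
        "AST": (53, 43, 65),
        "ALP": (294, 241, 350),
        "GGT": (25, 20, 33),
        "BIL": (7, 4, 10),
        "BIL_conj": None,  # 2 (<2–4)
    },
    (3, "not_breastfed"): {
        "Alb": (41, 40, 43),
        "ALT": (30, 11, 42),
        "AST": (45, 38, 51),
        "ALP": (288, 203, 326),
        "GGT": (25, 21, 32),
        "BIL": None,  # 4 (<3–7)
        "BIL_conj": None,  # <2 (<2–3)
    },
    (6, "breastfed"): {
        "Alb": (43, 41, 45),
        "ALT": (33, 22, 44),
        "AST": (56, 48, 67),
        "ALP": (241, 192, 298),
        "GGT": (18, 15, 23),
        "BIL": (5, 4, 8),
        "BIL_conj": None,  # <2 (<2–3)
    },
    (6, "not_breastfed"): {
        "Alb": (43, 41, 45),
        "ALT": (31, 24, 37),
        "AST": (48, 42, 55),
        "ALP": (286, 232, 328),
        "GGT": (17, 14, 20),
        "BIL": None,  # 4 (<3–5)
        "BIL_conj": None,  # <2 (<2–2)
    },
}


def _upper_half_sigma(median: float, q75: float) -> float:
    # Spread from the uncensored upper half of a summary: q75/median ratio.
    return math.log(q75 / median) / Z75


#: Explicit log-scale parameters for censored-summary cells:
#: (log_median, log_sigma).
EXPLICIT_LOG_PARAMS = {
    (3, "breastfed", "BIL_conj"): (math.log(2.0), _upper_half_sigma(2.0, 4.0)),
    (3, "not_breastfed", "BIL"): (math.log(4.0), _upper_half_sigma(4.0, 7.0)),
    (3, "not_breastfed", "BIL_conj"): (math.log(1.5), _upper_half_sigma(1.5, 3.0)),
    (6, "breastfed", "BIL_conj"): (math.log(1.5), _upper_half_sigma(1.5, 3.0)),
    (6, "not_breastfed", "BIL"): (math.log(4.0), _upper_half_sigma(4.0, 5.0)),
    (6, "not_breastfed", "BIL_conj"): (math.log(1.3), _upper_half_sigma(1.3, 2.0)),
}


def default_analyte_specs(age_months: int, feeding: str) -> tuple[AnalyteSpec, ...]:
    """Analyte specs for one age × feeding group of the default design."""
    summaries = GROUP_SUMMARIES[(age_months, feeding)]
    specs = []
    for name, summary in summaries.items():
        if summary is None:
            lm, ls = EXPLICIT_LOG_PARAMS[(age_months, feeding, name)]
        else:
            lm, ls = fit_lognormal_from_median_iqr(*map(float, summary))
        specs.append(
            AnalyteSpec(
                name=name,
                units=ANALYTE_UNITS[name],
                loq=LOQS[name],
                log_median=lm,
                log_sigma=ls,
            )
        )
    return tuple(specs)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The full default design: four groups at published scale, 6.8% CRP-elevated."""
    groups = []
    for (age, feeding), n_post in TABLE_GROUP_N.items():
        n_raw = round(n_post / (1.0 - CRP_ELEVATED_PROB))
        groups.append(
            GroupSpec(
                age_months=age,
                feeding=feeding,
                n=n_raw,
                analyte_specs=default_analyte_specs(age, feeding),
                crp_elevated_prob=CRP_ELEVATED_PROB,
            )
        )
    return CohortConfig(groups=tuple(groups), seed=seed, crp_threshold=4.0)
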