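"""Reference-interval estimators: nonparametric, robust (biweight), and
direct-percentile, with bootstrap confidence intervals.

A 95% reference interval spans the 2.5th and 97.5th percentiles of the
healthy population; each limit carries a 90% confidence interval by default.
Three estimators are provided, selected by sample size and censoring:

* **nonparametric** — rank-based, for samples over 120: the p-th limit sits
  at rank ``p·(n+1)`` with linear interpolation between adjacent order
  statistics (clamped to the sample range);
* **robust** — the Horn–Pesce biweight for smaller samples: an iteratively
  reweighted biweight location with a biweight-midvariance scale, expanded
  into limits by a Student-t prediction factor;
* **direct percentile** — the rank estimator without confidence intervals,
  for heavily censored series where resampling the censored block is not
  meaningful.

Left-censored results enter every rank computation as a tied block at their
LOQ, ordered below all observed values; a limit (or CI endpoint) that
resolves inside that block is reported censored, "< LOQ".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .preprocess import Measurement
from .screening import OutlierReport, dixon_screen

LOWER_P = 0.025
UPPER_P = 0.975
DEFAULT_CI_LEVEL = 0.90
DEFAULT_BOOT_REPS = 2000

#: Tuning constant of the biweight location iteration (units of MAD).
C_LOCATION = 3.7
#: Tuning constant of the biweight midvariance (units of MAD).
C_SCALE = 9.0

#: Censored fraction at or above which estimation falls back to direct
#: percentiles without confidence intervals.
CENSORING_FALLBACK = 0.5

NONPARAMETRIC = "nonparametric"
ROBUST = "robust"
DIRECT = "direct_percentile"


@dataclass(frozen=True)
class Limit:
    """One reference limit; censored limits are reported as "< loq"."""

    value: float
    censored: bool = False
    loq: float | None = None

    def __post_init__(self) -> None:
        if self.censored and (self.loq is None or self.loq != self.value):
            raise ValueError("censored limit must carry value == loq")

    def __str__(self) -> str:
        return f"<{self.loq:g}" if self.censored else f"{self.value:g}"


@dataclass(frozen=True)
class ReferenceInterval:
    """Estimated lower/upper limits with optional 90% CIs and provenance."""

    analyte: str
    method: str
    n_used: int
    lower: Limit
    upper: Limit
    lower_ci: tuple[Limit, Limit] | None = None
    upper_ci: tuple[Limit, Limit] | None = None
    outlier_report: OutlierReport | None = None

    def __post_init__(self) -> None:
        if self.lower.value > self.upper.value:
            raise ValueError("lower limit exceeds upper limit")
        for point, ci in ((self.lower, self.lower_ci), (self.upper, self.upper_ci)):
            if ci is not None and not (ci[0].value <= point.value <= ci[1].value):
                raise ValueError("confidence interval does not bracket its limit")
        if self.method == DIRECT and (self.lower_ci or self.upper_ci):
            raise ValueError("direct-percentile limits carry no confidence intervals")


# ---------------------------------------------------------------------------
# censoring-aware ordering
# ---------------------------------------------------------------------------

def sort_series(
    series: Sequence[Measurement],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort a series with censored results below observed ones at equal value.

    Returns ``(values, censored, loqs)`` arrays in that order; censored
    entries carry their LOQ as value and in ``loqs`` (NaN for observed).
    """
    if len(series) == 0:
        raise ValueError("empty series")
    values = np.array([m.value for m in series], dtype=float)
    censored = np.array([m.censored for m in series], dtype=bool)
    loqs = np.array(
        [m.loq if m.censored else np.nan for m in series], dtype=float
    )
    order = np.lexsort((~censored, values))
    return values[order], censored[order], loqs[order]


def rank_values(series: Sequence[Measurement]) -> np.ndarray:
    """Numeric surrogates preserving the censored-block ordering.

    A censored result maps to a value infinitesimally below its LOQ so that
    censored results at a common LOQ tie with each other and rank strictly
    below any observed value at or above that LOQ.  Used for ranking only,
    never as a measurement value.
    """
    out = np.empty(len(series), dtype=float)
    for i, m in enumerate(series):
        out[i] = m.loq * (1.0 - 1e-9) if m.censored else m.value
    return out


def censored_fraction(series: Sequence[Measurement]) -> float:
    if len(series) == 0:
        raise ValueError("empty series")
    return sum(m.censored for m in series) / len(series)


# ---------------------------------------------------------------------------
# rank interpolation
# ---------------------------------------------------------------------------

def _interp_at_rank(sorted_vals: np.ndarray, r: float) -> np.ndarray | float:
    """Value at 1-based rank ``r`` with linear interpolation, clamped to the
    sample range.  Works on the last axis, so bootstrap matrices vectorize."""
    n = sorted_vals.shape[-1]
    if r <= 1:
        return sorted_vals[..., 0]
    if r >= n:
        return sorted_vals[..., -1]
    f = int(math.floor(r))
    g = r - f
    if g == 0:
        return sorted_vals[..., f - 1]
    return sorted_vals[..., f - 1] * (1.0 - g) + sorted_vals[..., f] * g


def _rank_limit(
    sorted_vals: np.ndarray,
    sorted_cens: np.ndarray,
    sorted_loqs: np.ndarray,
    p: float,
) -> Limit:
    """Point limit at rank ``p·(n+1)``, censoring-aware.

    The limit is censored exactly when its upper bracketing order statistic
    is censored — i.e. the rank resolves inside the censored tied block.
    """
    n = sorted_vals.size
    r = min(max(p * (n + 1), 1.0), float(n))
    value = float(_interp_at_rank(sorted_vals, r))
    f = math.floor(r)
    k = f if r == f else f + 1  # 1-based upper bracketing index
    if sorted_cens[k - 1]:
        loq = float(sorted_loqs[k - 1])
        return Limit(value=loq, censored=True, loq=loq)
    return Limit(value=value)


def _flag_endpoint(value: float, sorted_cens: np.ndarray, sorted_loqs: np.ndarray) -> Limit:
    """Censor-flag a numeric CI endpoint: inside/below the censored block →
    reported at the block's LOQ."""
    if sorted_cens.any():
        block_loq = float(np.nanmax(sorted_loqs))
        if value <= block_loq:
            return Limit(value=block_loq, censored=True, loq=block_loq)
    return Limit(value=float(value))


# ---------------------------------------------------------------------------
# nonparametric / direct percentile
# ---------------------------------------------------------------------------

def _bootstrap_rank_limits(
    values: np.ndarray, boot_reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap distribution of the rank-based lower/upper limits."""
    n = values.size
    idx = rng.integers(0, n, size=(boot_reps, n))
    samples = np.sort(values[idx], axis=1)
    r_lo = min(max(LOWER_P * (n + 1), 1.0), float(n))
    r_hi = min(max(UPPER_P * (n + 1), 1.0), float(n))
    return (
        np.asarray(_interp_at_rank(samples, r_lo), dtype=float),
        np.asarray(_interp_at_rank(samples, r_hi), dtype=float),
    )


def _percentile_ci(
    boot: np.ndarray, point: float, ci_level: float
) -> tuple[float, float]:
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    # Percentile CIs are widened (rarely, and minutely) to bracket the point
    # estimate, so the nesting invariant holds on every run.
    return min(float(lo), point), max(float(hi), point)


def nonparametric_ri(
    series: Sequence[Measurement],
    ci_level: float = DEFAULT_CI_LEVEL,
    boot_reps: int = DEFAULT_BOOT_REPS,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    outlier_report: OutlierReport | None = None,
) -> ReferenceInterval:
    """Rank-based reference limits with bootstrap percentile CIs.

    Limits at ranks ``0.025·(n+1)`` and ``0.975·(n+1)``; CIs from
    ``boot_reps`` resamples of the same rank estimator.  Intended for
    n > 120 (a warning is issued below that).
    """
    vals, cens, loqs = sort_series(series)
    n = vals.size
    if n <= 120:
        warnings.warn(
            f"nonparametric method recommended for n > 120, got n={n}", stacklevel=2
        )
    lower = _rank_limit(vals, cens, loqs, LOWER_P)
    upper = _rank_limit(vals, cens, loqs, UPPER_P)

    rng = np.random.default_rng(seed)
    boot_lo, boot_hi = _bootstrap_rank_limits(vals, boot_reps, rng)
    lo_ci = _percentile_ci(boot_lo, lower.value, ci_level)
    hi_ci = _percentile_ci(boot_hi, upper.value, ci_level)
    analyte = series[0].analyte
    return ReferenceInterval(
        analyte=analyte,
        method=NONPARAMETRIC,
        n_used=n,
        lower=lower,
        upper=upper,
        lower_ci=tuple(_flag_endpoint(v, cens, loqs) for v in lo_ci),
        upper_ci=tuple(_flag_endpoint(v, cens, loqs) for v in hi_ci),
        outlier_report=outlier_report,
    )


def direct_percentile_ri(
    series: Sequence[Measurement],
    outlier_report: OutlierReport | None = None,
) -> ReferenceInterval:
    """Direct 2.5th/97.5th percentiles, no confidence intervals.

    The fallback for heavily censored series, where most results sit in the
    tied block at the LOQ and interval estimation for the limits is not
    meaningful."""
    vals, cens, loqs = sort_series(series)
    return ReferenceInterval(
        analyte=series[0].analyte,
        method=DIRECT,
        n_used=vals.size,
        lower=_rank_limit(vals, cens, loqs, LOWER_P),
        upper=_rank_limit(vals, cens, loqs, UPPER_P),
        outlier_report=outlier_report,
    )


# ---------------------------------------------------------------------------
# robust (Horn–Pesce biweight)
# ---------------------------------------------------------------------------

def _biweight_location(X: np.ndarray, c: float = C_LOCATION) -> np.ndarray:
    """Biweight location per row of ``X`` (2-D), anchored at median/MAD.

    Starts at the median; weights ``(1-u²)²`` for ``|u| < 1`` with
    ``u = (x - T)/(c·MAD)``; iterates to ``|ΔT| < 1e-8·MAD`` (cap 100).
    Rows with zero MAD keep their median.
    """
    M = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - M), axis=1, keepdims=True)
    T = M.copy()
    scale = c * mad
    live = (mad > 0).ravel()
    for _ in range(100):
        if not live.any():
            break
        u = np.divide(X - T, scale, out=np.zeros_like(X), where=scale > 0)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        sw = w.sum(axis=1, keepdims=True)
        T_new = np.where(sw > 0, (w * X).sum(axis=1, keepdims=True) / np.where(sw > 0, sw, 1.0), T)
        delta = np.abs(T_new - T).ravel()
        T = np.where(live[:, None], T_new, T)
        live = live & (delta >= 1e-8 * mad.ravel())
    return T.ravel()


def _biweight_scale(X: np.ndarray, c: float = C_SCALE) -> np.ndarray:
    """Biweight midvariance (square root) per row, anchored at median/MAD.

    ``s² = n·Σ a⁴(x-M)² / D²`` with ``a = 1-u²`` on ``|u| < 1``,
    ``u = (x-M)/(c·MAD)`` and ``D = Σ a(1-5u²)``; zero where MAD is zero.
    """
    n = X.shape[1]
    M = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - M), axis=1, keepdims=True)
    scale = c * mad
    u = np.divide(X - M, scale, out=np.zeros_like(X), where=scale > 0)
    mask = np.abs(u) < 1.0
    a = np.where(mask, 1.0 - u**2, 0.0)
    num = (a**4 * (X - M) ** 2).sum(axis=1)
    den = (a * (1.0 - 5.0 * u**2) * mask).sum(axis=1)
    s2 = np.where(
        (mad.ravel() > 0) & (den > 0), n * num / np.where(den > 0, den, 1.0) ** 2, 0.0
    )
    return np.sqrt(s2)


def _biweight_limits(X: np.ndarray, t_factor: float) -> tuple[np.ndarray, np.ndarray]:
    T = _biweight_location(X)
    s = _biweight_scale(X)
    return T - t_factor * s, T + t_factor * s


def robust_ri(
    series: Sequence[Measurement],
    ci_level: float = DEFAULT_CI_LEVEL,
    boot_reps: int = DEFAULT_BOOT_REPS,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    outlier_report: OutlierReport | None = None,
) -> ReferenceInterval:
    """Horn–Pesce biweight reference limits with bootstrap percentile CIs.

    Limits ``T_bi ± t(0.975, n-1) · s_bi · sqrt(1 + 1/n)``: a prediction-type
    interval for a new observation around the robust location.  With zero
    MAD (over half the sample tied) the interval degenerates to
    [median, median] with a warning.  Censored results participate at their
    LOQ; a limit resolving at or below the censored block is reported
    censored.
    """
    vals, cens, loqs = sort_series(series)
    n = vals.size
    if n < 20:
        warnings.warn(f"robust method recommended for n >= 20, got n={n}", stacklevel=2)
    mad = np.median(np.abs(vals - np.median(vals)))
    analyte = series[0].analyte
    if mad == 0:
        warnings.warn(
            f"{analyte}: zero MAD, robust interval degenerates to the median",
            stacklevel=2,
        )
        med = float(np.median(vals))
        point = _flag_endpoint(med, cens, loqs)
        zero_ci = (point, point)
        return ReferenceInterval(
            analyte=analyte,
            method=ROBUST,
            n_used=n,
            lower=point,
            upper=point,
            lower_ci=zero_ci,
            upper_ci=zero_ci,
            outlier_report=outlier_report,
        )

    t_factor = float(stats.t.ppf(0.975, n - 1)) * math.sqrt(1.0 + 1.0 / n)
    lo_arr, hi_arr = _biweight_limits(vals[None, :], t_factor)
    lo_pt, hi_pt = float(lo_arr[0]), float(hi_arr[0])

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(boot_reps, n))
    boot_lo, boot_hi = _biweight_limits(vals[idx], t_factor)
    lo_ci = _percentile_ci(boot_lo, lo_pt, ci_level)
    hi_ci = _percentile_ci(boot_hi, hi_pt, ci_level)

    return ReferenceInterval(
        analyte=analyte,
        method=ROBUST,
        n_used=n,
        lower=_flag_endpoint(lo_pt, cens, loqs),
        upper=_flag_endpoint(hi_pt, cens, loqs),
        lower_ci=tuple(_flag_endpoint(v, cens, loqs) for v in lo_ci),
        upper_ci=tuple(_flag_endpoint(v, cens, loqs) for v in hi_ci),
        outlier_report=outlier_report,
    )


# ---------------------------------------------------------------------------
# method selection and composition
# ---------------------------------------------------------------------------

def select_method(
    n: int,
    censored_frac: float,
    censoring_fallback: float = CENSORING_FALLBACK,
) -> str:
    """Pick the estimator: heavy censoring → direct percentiles; otherwise
    rank-based above 120 (strictly) and robust at or below."""
    if n < 1:
        raise ValueError("need at least one observation")
    if censored_frac >= censoring_fallback:
        return DIRECT
    return NONPARAMETRIC if n > 120 else ROBUST


def estimate_series(
    series: Sequence[Measurement],
    ci_level: float = DEFAULT_CI_LEVEL,
    boot_reps: int = DEFAULT_BOOT_REPS,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    censoring_fallback: float = CENSORING_FALLBACK,
    screen_outliers: bool = True,
) -> ReferenceInterval:
    """Full per-series estimation: outlier screen → method selection → limits.

    Censored values enter the outlier screen at their LOQ.  ``n_used`` is the
    post-screening sample size, and the selected method reflects the
    post-screening n and censored fraction.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if screen_outliers:
        report = dixon_screen([m.value for m in series])
        kept = [series[i] for i in report.kept_indices]
    else:
        report = OutlierReport((), (), len(series), tuple(range(len(series))))
        kept = list(series)

    method = select_method(len(kept), censored_fraction(kept), censoring_fallback)
    if method == DIRECT:
        return direct_percentile_ri(kept, outlier_report=report)
    if method == NONPARAMETRIC:
        return nonparametric_ri(
            kept, ci_level=ci_level, boot_reps=boot_reps, seed=seed,
            outlier_report=report,
        )
    return robust_ri(
        kept, ci_level=ci_level, boot_reps=boot_reps, seed=seed,
        outlier_report=report,
    )
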