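# Methods

## The estimation problem

A 95% reference interval is the pair of population percentiles (2.5th,
97.5th) of an analyte in healthy subjects; each estimated limit carries a
90% confidence interval expressing its sampling uncertainty. For infant
liver biochemistry three complications dominate: small subgroup sizes once
the cohort is split by age and feeding; strong right skew in the enzyme and
bilirubin distributions; and left-censoring, because assays report results
below their measuring range only as "< LOQ".

## Censoring convention

A censored result is stored as (value = LOQ, censored flag). Every
rank-based computation sorts censored results as a tied block strictly
below all observed values at the same LOQ (observed values equal to the
LOQ sort above the block; in practice ties with the block have probability
zero for continuous data). No value is ever imputed. A limit, CI endpoint,
or median whose rank resolves inside the block — equivalently, whose
numeric value does not exceed the block's LOQ — is reported censored,
"< LOQ". For the Wilcoxon test the block enters through surrogate keys at
`LOQ·(1−1e−9)`, so the standard midrank tie correction absorbs it.

## Preprocessing

CRP > 4 mg/L (strict inequality; a value of exactly 4.0 is kept) excludes
a subject from every series. A censored CRP is below its LOQ and therefore
below the threshold, provided LOQ ≤ threshold; a censored CRP whose LOQ
exceeds the threshold is indeterminate and raises an error rather than
being silently kept or dropped. Missing analyte cells are permitted and
simply shorten that analyte's series.

## Outlier screening

The one-third-of-range rule: on sorted data, delete the maximum when
`(x(n) − x(n−1)) / (x(n) − x(1)) > 1/3`, the minimum symmetrically; after a
deletion, re-test the reduced sample. When both tails fire, the larger
ratio is removed first (ties go to the high tail). Deletions are capped at
5% of the original n, protecting heavy-tailed series from mass deletion;
zero range or n < 3 means no removals (the latter with a warning).
Screening runs per estimation series (analyte × age × group), after the CRP
filter and before estimation, with censored values participating at their
LOQ — a tied censored minimum has zero gap and can never fire.

## Partition testing

Harris–Boyd: `z = |mean₁ − mean₂| / sqrt(sd₁²/n₁ + sd₂²/n₂)` against
`z* = 3·sqrt(((n₁+n₂)/2)/120)`; additionally partition when
`max(sd)/min(sd) > 1.5` (limit configurable). The pipeline evaluates the
criterion for feeding and for sex at every analyte × age and records the
decision; it does not itself re-stratify, leaving that to the caller, and
reports the standard grouped columns (all / breastfed / not breastfed).

## Limit estimators

**Method selection.** Censored fraction ≥ 0.5 → direct percentiles;
otherwise n > 120 (strictly) → nonparametric; otherwise robust. The 0.5
fallback threshold is configurable (`--censoring-fallback`).

**Nonparametric.** The p-th limit sits at rank `r = p·(n+1)` with linear
interpolation between adjacent order statistics, clamped to the sample
range — the convention recommended for reference samples of at least 120.
At least four percentile conventions exist and disagree materially at tail
ranks; this one is fixed and oracle-tested. Under it the estimated limits
are unbiased in probability mass: `E[F(x̂_p)] = r/(n+1) ≈ p`, which the
calibration run confirms (mean mass below the lower limit 2.52%, at or
below the upper 97.53%, over 1000 Gaussian cohorts of n = 240).

**Robust (Horn–Pesce biweight).** Location `T_bi`: start at the median with
MAD as fixed scale anchor; weights `w = (1−u²)²` for `|u| < 1`,
`u = (x−T)/(c_loc·MAD)`, `c_loc = 3.7`; iterate `T ← Σwx/Σw` until
`|ΔT| < 1e−8·MAD` (cap 100). Scale `s_bi`: biweight midvariance,
`s² = n·Σa⁴(x−M)²/D²` with `a = 1−u²` on `|u| < 1`, `u = (x−M)/(9·MAD)`,
`D = Σa(1−5u²)`. Limits: `T_bi ± t(0.975, n−1)·s_bi·sqrt(1+1/n)`.
Published descriptions of the robust method differ in the scale constant
and denominator; these constants are validated by Gaussian recovery — over
500 replicates at n = 60 the mean limits land within ±0.1 of μ ± 1.96σ
(both the `D²` and `D(D−1)` denominators pass; the standard `D²` form is
used). MAD = 0 degenerates to [median, median] with a warning so batch runs
complete. Note the interval is symmetric about `T_bi`: on strongly skewed
data its limits are *not* consistent for the 2.5th/97.5th percentiles (see
Limitations).

**Direct percentiles.** The rank estimator applied as-is, CIs omitted:
when most of a series is a censored tied block, resampling the block yields
no meaningful interval for a limit inside it.

**Confidence intervals.** Seeded bootstrap percentile CIs (default 2000
resamples, level 0.90) for both the nonparametric and robust methods — one
mechanism for both, including the robust case where no closed form exists.
Rank-table CIs are a known alternative for the nonparametric case; the
bootstrap's measured coverage (90.2% for the upper limit at n = 240, target
90 ± 3) made a second mechanism unnecessary. Percentile CIs are widened,
when needed, to bracket the point estimate, so CI nesting holds on every
run. Bootstrap substreams derive from the master seed per series in a fixed
key order, so adding analytes does not perturb existing results.

## Feeding comparison

Two-sided Wilcoxon rank-sum per analyte × age on the outlier-screened
series (the same screening as the estimation path; both sample sizes are
recorded). Exact enumeration when min(n) ≤ 10 without ties, else the normal
approximation with midrank tie correction and continuity correction; a
fully tied comparison returns p = 1. p-values display as two decimals,
"< 0.001" below that. No multiplicity correction by default (per-analyte
raw p-values); Holm adjustment can be applied by the caller.

## Synthetic cohort generator

**What it emulates.** Each analyte in each age × feeding group is
log-normal — right-skewed, positive support, and two parameters that map
one-to-one onto a published "median (q25–q75)" summary: the median is
matched exactly and `log_sigma = log(q75/q25)/(2·z₀.₇₅)` matches the
quartile *ratio*. Draws below the analyte's LOQ are stored censored at the
LOQ. CRP is a two-component mixture: bulk uniform on (0, 4] mg/L (censored
at 0.1 mg/L) and, with probability 42/619 ≈ 0.068, an "infection" value
uniform on (4, 40] — only exceedance of the threshold matters downstream.
Sex is balanced and carries no effect. Group sizes default to the published
post-exclusion n's inflated by 1/(1 − 0.068), so filtered series match the
published table in expectation.

**Censored summaries.** A summary whose median or quartile is itself
printed "< x" cannot parameterize a log-normal and is refused by the
fitting routine; the default design instead fixes those cells explicitly:
spread from the uncensored upper half (`log(q75/median)/z₀.₇₅`), and
sub-LOQ medians set once at 1.5 µmol/L for conjugated bilirubin printed
"< 2" (1.3 µmol/L where q75 is already 2). These are plausibility choices,
not estimates.

**What it does not emulate.** No within-subject correlation between 3- and
6-month visits (subjects resampled at both ages are drawn independently);
no sex effect; no assay imprecision beyond the distributional model; and a
two-parameter log-normal cannot match both quartiles of a summary that is
not log-symmetric — for the most skewed groups (e.g. formula-fed ALT at
3 months, fitted log_sigma ≈ 0.99) the implied upper tail is heavier than
the real data's. Passing end-to-end tests therefore demonstrate the
pipeline's correctness and calibration on data with the assumed structure,
not distributional fidelity to any real cohort.

**Determinism.** One master seed; per-group substreams derive from
(seed, age, feeding), so identical configs give byte-identical CSVs and
adding a group leaves existing groups' draws unchanged.

## Problem sizes in the shipped checks

The calibration suite uses 1000 replicate cohorts of n = 240 for the
nonparametric coverage and tail-mass checks, 500 replicates of n = 60 for
robust Gaussian recovery, 2000 null replicates for the partition-test
firing rate, and 100 seeded full-design cohorts for the feeding-comparison
power check — sizes at which the binomial noise of each measured rate is
well inside the asserted tolerance.

## Known limitations

* The symmetric robust interval is biased off the true tail percentiles on
  skewed data; on the default synthetic design its limits for the skewed
  small-n groups deviate from the generator's true quantiles by 10–70%.
  This mirrors how the method behaves on real skewed analytes and is why
  rank-based limits are preferred whenever n permits.
* Upper-limit estimates for high-variance analytes at n ≈ 50–230 carry
  10–25% relative sampling error; single-cohort agreement with population
  quantiles at tighter tolerances is not attainable at these sizes.
* Bootstrap CIs for limits inside a censored block collapse to the block
  and say nothing beyond "< LOQ".
* Feeding is a binary contrast (exclusive/partial breastfeeding pooled vs
  formula); finer feeding taxonomies and age-continuous reference curves
  are out of scope.
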