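"""Reference-limit estimators: rank arithmetic, biweight, censoring, selection."""

import warnings

import numpy as np
import pytest
from scipy import stats

from infantri.estimators import (
    DIRECT,
    NONPARAMETRIC,
    ROBUST,
    direct_percentile_ri,
    estimate_series,
    nonparametric_ri,
    robust_ri,
    select_method,
)
from infantri.preprocess import Measurement

from conftest import censored, gaussian_series, observed


def quiet_nonparametric(series, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return nonparametric_ri(series, **kw)


class TestSelectMethod:
    @pytest.mark.parametrize(
        "n,frac,expected",
        [
            (226, 0.0, NONPARAMETRIC),
            (121, 0.0, NONPARAMETRIC),
            (120, 0.0, ROBUST),  # "over 120" is strict
            (49, 0.0, ROBUST),
            (49, 0.6, DIRECT),
            (500, 0.5, DIRECT),  # censoring rule dominates sample size
            (500, 0.49, NONPARAMETRIC),
        ],
    )
    def test_selection_table(self, n, frac, expected):
        assert select_method(n, frac) == expected

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            select_method(0, 0.0)


class TestNonparametric:
    def test_identity_ladder_rank_arithmetic(self):
        series = observed(range(1, 121))
        with pytest.warns(UserWarning, match="recommended"):
            ri = nonparametric_ri(series, boot_reps=50, seed=0)
        assert ri.lower.value == pytest.approx(3.025, abs=1e-12)
        assert ri.upper.value == pytest.approx(117.975, abs=1e-12)

    def test_constant_series_degenerate(self):
        ri = quiet_nonparametric(observed([7.0] * 30), boot_reps=100, seed=0)
        assert ri.lower.value == ri.upper.value == 7.0
        assert ri.upper_ci[0].value == ri.upper_ci[1].value == 7.0

    def test_gaussian_limits_recover_population_quantiles(self):
        series = gaussian_series(5000, rng=123)
        ri = nonparametric_ri(series, boot_reps=200, seed=1)
        assert ri.lower.value == pytest.approx(10 - 1.96, abs=0.1)
        assert ri.upper.value == pytest.approx(10 + 1.96, abs=0.1)

    def test_brute_force_oracle(self):
        # Naive sort + rank interpolation, written independently of the
        # estimator's internals.
        def naive(xs, p):
            xs = sorted(xs)
            n = len(xs)
            r = min(max(p * (n + 1), 1.0), float(n))
            f = int(np.floor(r))
            g = r - f
            if f >= n:
                return xs[-1]
            return xs[f - 1] + g * (xs[f] - xs[f - 1])

        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(5, 400))
            xs = rng.lognormal(2.0, 0.7, n)
            ri = quiet_nonparametric(observed(xs), boot_reps=2, seed=0)
            assert ri.lower.value == pytest.approx(naive(xs, 0.025), abs=1e-12)
            assert ri.upper.value == pytest.approx(naive(xs, 0.975), abs=1e-12)

    def test_limits_within_sample_range(self):
        rng = np.random.default_rng(7)
        xs = rng.uniform(5, 50, 10)
        ri = quiet_nonparametric(observed(xs), boot_reps=10, seed=0)
        assert xs.min() <= ri.lower.value <= ri.upper.value <= xs.max()

    def test_ci_nesting(self):
        for seed in range(5):
            series = gaussian_series(150, rng=seed)
            ri = nonparametric_ri(series, boot_reps=300, seed=seed)
            assert ri.lower_ci[0].value <= ri.lower.value <= ri.lower_ci[1].value
            assert ri.upper_ci[0].value <= ri.upper.value <= ri.upper_ci[1].value

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            nonparametric_ri([])

    def test_censored_block_limit_reported_censored(self):
        series = censored(9.0, 50) + observed(np.linspace(10, 40, 150))
        ri = nonparametric_ri(series, boot_reps=100, seed=0)
        assert ri.lower.censored and ri.lower.loq == 9.0
        assert str(ri.lower) == "<9"
        assert ri.lower_ci[0].censored and ri.lower_ci[1].censored
        assert not ri.upper.censored


class TestRobust:
    def test_symmetric_fixed_point(self):
        with pytest.warns(UserWarning, match="n >= 20"):
            ri = robust_ri(observed([1, 2, 3, 4, 5]), boot_reps=50, seed=0)
        midpoint = (ri.lower.value + ri.upper.value) / 2
        assert midpoint == pytest.approx(3.0, abs=1e-9)

    def test_constant_series_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="zero MAD"):
            ri = robust_ri(observed([4.0] * 25), boot_reps=10, seed=0)
        assert ri.lower.value == ri.upper.value == 4.0

    def test_gaussian_recovery_mean_limits(self):
        # 200 replicates at n=60: validates the biweight tuning constants
        # and the t-based interval form (the acceptance run uses 500).
        rng = np.random.default_rng(31)
        lls, uls = [], []
        for _ in range(200):
            ri = robust_ri(gaussian_series(60, rng=rng), boot_reps=2, seed=0)
            lls.append(ri.lower.value)
            uls.append(ri.upper.value)
        assert np.mean(lls) == pytest.approx(10 - 1.96, abs=0.1)
        assert np.mean(uls) == pytest.approx(10 + 1.96, abs=0.1)

    def test_agrees_with_nonparametric_on_large_gaussian(self):
        series = gaussian_series(5000, rng=17)
        rob = robust_ri(series, boot_reps=2, seed=0)
        non = nonparametric_ri(series, boot_reps=2, seed=0)
        assert rob.lower.value == pytest.approx(non.lower.value, abs=0.1)
        assert rob.upper.value == pytest.approx(non.upper.value, abs=0.1)

    def test_censored_lower_limit_reported_at_loq(self):
        series = censored(9.0, 10) + observed(np.linspace(10, 30, 50))
        ri = robust_ri(series, boot_reps=100, seed=0)
        if ri.lower.censored:
            assert ri.lower.value == ri.lower.loq == 9.0


class TestDirectPercentile:
    def test_lower_limit_inside_censored_block(self):
        series = censored(2.0, 60) + observed(np.linspace(2.1, 5.0, 40))
        ri = direct_percentile_ri(series)
        assert ri.method == DIRECT
        assert ri.lower.censored and ri.lower.loq == 2.0
        assert not ri.upper.censored
        assert 2.1 < ri.upper.value <= 5.0
        assert ri.lower_ci is None and ri.upper_ci is None

    def test_fully_censored_series(self):
        ri = direct_percentile_ri(censored(2.0, 30))
        assert ri.lower.censored and ri.upper.censored
        assert ri.lower.loq == ri.upper.loq == 2.0


class TestEquivariance:
    @pytest.mark.parametrize("method", ["nonparametric", "robust", "direct"])
    def test_affine_equivariance(self, method):
        rng = np.random.default_rng(11)
        xs = rng.lognormal(2, 0.4, 140)
        a, b = 2.5, 7.0
        fns = {
            "nonparametric": lambda s: nonparametric_ri(s, boot_reps=2, seed=0),
            "robust": lambda s: robust_ri(s, boot_reps=2, seed=0),
            "direct": direct_percentile_ri,
        }
        base = fns[method](observed(xs))
        moved = fns[method](observed(a * xs + b))
        assert moved.lower.value == pytest.approx(a * base.lower.value + b, rel=1e-9)
        assert moved.upper.value == pytest.approx(a * base.upper.value + b, rel=1e-9)


class TestEstimateSeries:
    def test_outlier_then_nonparametric(self):
        series = observed(list(range(1, 122)) + [10000])
        ri = estimate_series(series, boot_reps=50, seed=0)
        assert ri.outlier_report.removed_values == (10000.0,)
        assert ri.n_used == 121
        assert ri.method == NONPARAMETRIC

    def test_small_clean_sample_goes_robust(self):
        ri = estimate_series(observed(range(1, 51)), boot_reps=50, seed=0)
        assert ri.method == ROBUST
        assert ri.outlier_report.removed_count == 0

    def test_heavy_censoring_forces_direct(self):
        series = censored(2.0, 70) + observed(np.linspace(2.5, 6, 30))
        ri = estimate_series(series, boot_reps=50, seed=0)
        assert ri.method == DIRECT
        assert ri.lower_ci is None

    def test_seeded_reproducibility(self):
        series = gaussian_series(200, rng=3)
        a = estimate_series(series, boot_reps=200, seed=42)
        b = estimate_series(series, boot_reps=200, seed=42)
        assert a == b
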