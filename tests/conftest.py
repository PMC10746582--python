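import numpy as np
import pytest

from infantri.cohort import AnalyteSpec, CohortConfig, GroupSpec
from infantri.preprocess import Measurement


def gaussian_series(n, mu=10.0, sigma=1.0, rng=None, analyte="X"):
    """Positive Gaussian series as Measurement objects."""
    rng = np.random.default_rng(rng)
    values = rng.normal(mu, sigma, n)
    return [Measurement(analyte, float(v)) for v in values]


def observed(values, analyte="X"):
    return [Measurement(analyte, float(v)) for v in values]


def censored(loq, k, analyte="X"):
    return [Measurement(analyte, float(loq), censored=True, loq=float(loq))
            for _ in range(k)]


@pytest.fixture
def small_config():
    """Two-group config, small n, one skewed analyte with a binding LOQ."""
    def spec(name, loq, lm, ls):
        return AnalyteSpec(name=name, units="U/L", loq=loq, log_median=lm, log_sigma=ls)

    groups = (
        GroupSpec(
            age_months=3, feeding="breastfed", n=60,
            analyte_specs=(spec("ALT", 9.0, np.log(30.0), 0.5),),
            crp_elevated_prob=0.1,
        ),
        GroupSpec(
            age_months=3, feeding="not_breastfed", n=40,
            analyte_specs=(spec("ALT", 9.0, np.log(20.0), 0.5),),
            crp_elevated_prob=0.1,
        ),
    )
    return CohortConfig(groups=groups, seed=7)
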