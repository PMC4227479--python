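import numpy as np
import pytest

from dynreward.cohort import CovariateModel, GroupSpec, sample_cohort
from dynreward.schedule import make_schedule


@pytest.fixture(scope="session")
def seq1():
    return make_schedule("sequence-1")


def small_specs(n: int = 4) -> list[GroupSpec]:
    """Three tiny groups with well-separated parameters, for fast tests."""
    cov_lo = CovariateModel(2.4, -0.05, 0.8, 4.0, 2, 4, 267.0, 135.0)
    cov_hi = CovariateModel(5.9, -0.05, 1.8, 2.9, 4, 14, 325.0, 244.0)
    return [
        GroupSpec("control", n, mu_alpha=0.55, sigma_alpha=0.3, mu_logbeta=1.4, sigma_logbeta=0.2),
        GroupSpec("low-psychosis", n, mu_alpha=1.1, sigma_alpha=0.3, mu_logbeta=1.4,
                  sigma_logbeta=0.2, covariate_model=cov_lo),
        GroupSpec("high-psychosis", n, mu_alpha=1.15, sigma_alpha=0.3, mu_logbeta=1.0,
                  sigma_logbeta=0.2, covariate_model=cov_hi),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    return sample_cohort(small_specs(), np.random.default_rng(11))
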