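import pytest

import artdating as ad


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed cohort at moderate n for pipeline-level checks."""
    params = ad.default_params(n_spont=4000, n_fresh=2000, n_frozen=2000, seed=11)
    return ad.simulate_cohort(params)


@pytest.fixture(scope="session")
def errorfree_art():
    """ART-only cohort in the error-free ultrasound limit.

    With no ultrasound dating error the pairwise GA difference reduces
    to the record's follicular phase minus k, which makes calibration
    identities exact.
    """
    params = ad.default_params(n_fresh=3000, n_frozen=3000, us_error_sd_days=0.0, seed=5)
    return ad.simulate_cohort(params)


@pytest.fixture(scope="session")
def big_spont():
    """Large spontaneous cohort for parameter-recovery checks."""
    params = ad.default_params(n_spont=50_000, seed=7)
    return ad.simulate_cohort(params)
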