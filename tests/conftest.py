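from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_cohort_32():
    """A 32-patient cohort under the published study's conditions."""
    from fluidresp.cohort import generate_cohort, paper_default_spec

    return generate_cohort(paper_default_spec(n_patients=32, seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """10,000-patient paper-default cohort with its raw draws; shared by
    the calibration and large-sample consistency checks."""
    from fluidresp.cohort import generate_cohort, paper_default_spec

    spec = replace(paper_default_spec(), n_patients=10_000, seed=1)
    return generate_cohort(spec, return_draws=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
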