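import numpy as np
import pytest

from pctpoly.synthetic import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=(32, 32, 16), spacing=(3.0, 3.0, 4.0), gain_log_sd=0.2, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
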