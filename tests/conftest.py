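import numpy as np
import pytest

from olinh import COVID_VACCINATION_AFRICA, InhParams, OlinhParams


@pytest.fixture(scope="session")
def vaccination():
    """The packaged 46-country vaccination-rate sample."""
    return COVID_VACCINATION_AFRICA.values


@pytest.fixture
def w_std():
    """A moderate reference parameter vector used throughout."""
    return OlinhParams(1.25, 1.5, 1.5, 1.5)


@pytest.fixture
def w_fitted():
    """The vaccination-data maximum-likelihood point (heavy delta-theta ridge)."""
    return OlinhParams(9.0385, 1.8521, 716.7624, 0.2115)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
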