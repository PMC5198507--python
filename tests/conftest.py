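import numpy as np
import pytest

from virodyn.config import example_model


@pytest.fixture(scope="session")
def m17():
    """Worked example A: logistic growth, exponential-shift incidence."""
    return example_model("example17")


@pytest.fixture(scope="session")
def m18():
    """Worked example B: linear growth, Crowley–Martin incidence."""
    return example_model("example18")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
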