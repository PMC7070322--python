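import hypothesis
import pytest

from aqbd import backward_eliminate
from aqbd.datasets import (RESPONSE_NAMES, celecoxib_cmas, celecoxib_factors,
                           celecoxib_optimum, load_celecoxib_ccf,
                           load_celecoxib_verification)

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def ccf_design():
    return load_celecoxib_ccf()


@pytest.fixture(scope="session")
def verification_design():
    return load_celecoxib_verification()


@pytest.fixture(scope="session")
def factors():
    return celecoxib_factors()


@pytest.fixture(scope="session")
def cmas():
    return celecoxib_cmas()


@pytest.fixture(scope="session")
def optimum_point():
    return celecoxib_optimum()


@pytest.fixture(scope="session")
def fitted_models(ccf_design):
    """Backward-eliminated model per response, fitted once per session."""
    return {r: backward_eliminate(ccf_design, r) for r in RESPONSE_NAMES}


@pytest.fixture(scope="session")
def model_list(fitted_models, cmas):
    return [fitted_models[c.response_name] for c in cmas]
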