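import logging

import pytest

import oafiscal as oa
from oafiscal.synthetic import SyntheticSpec, make_input_bundle


@pytest.fixture(scope="session", autouse=True)
def quiet_logger():
    logger = logging.getLogger("oafiscal")
    old = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(old)


@pytest.fixture(scope="session")
def uk_inputs():
    """Packaged UK reference bundle (published tariffs, synthetic lifetable)."""
    return oa.uk_reference_inputs(seed=1)


@pytest.fixture(scope="session")
def synthetic_inputs():
    """Fully synthetic bundle with direction-realistic effects."""
    return make_input_bundle(SyntheticSpec(seed=7))
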