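import logging

import pytest

from copdsim import PatientProfile, RiskEquationSet, baseline_state
from copdsim.synthetic import (
    base_case_config,
    known_delta_fixture,
    paper_like_equations,
    reference_profile,
)


@pytest.fixture(autouse=True)
def _quiet_clamp_warnings(caplog):
    # clamp warnings are expected in long lifetime runs; keep test output clean
    logging.getLogger("copdsim.equations").setLevel(logging.ERROR)
    yield


@pytest.fixture
def profile() -> PatientProfile:
    return reference_profile()


@pytest.fixture
def state(profile):
    return baseline_state(profile)


@pytest.fixture
def null_equations() -> RiskEquationSet:
    return RiskEquationSet.null()


@pytest.fixture
def default_equations() -> RiskEquationSet:
    return paper_like_equations()


@pytest.fixture
def base_config():
    return base_case_config(seed=0)


@pytest.fixture
def known_delta_config():
    return known_delta_fixture()
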