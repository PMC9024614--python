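import pytest

from aomflux import build_core_model, optimize
from aomflux.core_network import ATP_DEMAND_ID
from aomflux.scenarios import BUILTIN_SCENARIOS, build_scenario_model


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def atp_max_model():
    """Core confurcation model under the reference ATP-maximization setup."""
    return build_scenario_model(BUILTIN_SCENARIOS()["atp_max_confurcation"])


@pytest.fixture(scope="session")
def atp_max_solution(atp_max_model):
    return optimize(atp_max_model, objective=ATP_DEMAND_ID, parsimonious=True)


@pytest.fixture(scope="session")
def rnf_swap_model():
    return build_scenario_model(BUILTIN_SCENARIOS()["atp_max_rnf_swap"])


@pytest.fixture(scope="session")
def rnf_swap_solution(rnf_swap_model):
    return optimize(rnf_swap_model, objective=ATP_DEMAND_ID, parsimonious=True)
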