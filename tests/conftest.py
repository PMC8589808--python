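import numpy as np
import pytest

from enact import (
    ActivationSpec,
    DiGraph,
    build_weight_matrix,
    default_smooth_params,
    fixture_graph,
    recipe_params,
)


@pytest.fixture(scope="session")
def three_cycle():
    return fixture_graph("three-cycle")


@pytest.fixture(scope="session")
def kirk_silber():
    return fixture_graph("kirk-silber")


@pytest.fixture(scope="session")
def two_cell():
    return fixture_graph("two-cell")


@pytest.fixture(scope="session")
def ten_node():
    return fixture_graph("ten-node")


@pytest.fixture(scope="session")
def params04():
    """Recipe parameters at threshold delta = 0.4 (the default point)."""
    return recipe_params(0.4)


@pytest.fixture(scope="session")
def smooth04(params04):
    return ActivationSpec.from_params(params04, "smooth")


@pytest.fixture(scope="session")
def piecewise04(params04):
    return ActivationSpec.from_params(params04, "piecewise")
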