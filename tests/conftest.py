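import pytest

from depthmatch import DistanceGrid, make_design, simulate_panel


@pytest.fixture(scope="session")
def grid() -> DistanceGrid:
    return DistanceGrid()


@pytest.fixture(scope="session")
def exp1_design():
    return make_design("exp1")


@pytest.fixture(scope="session")
def small_panel(exp1_design):
    """Three-observer panel, large enough for cross-module pipeline tests."""
    return simulate_panel(3, design=exp1_design, seed=123)
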