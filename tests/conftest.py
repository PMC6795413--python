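import numpy as np
import pytest

from dualda.ecosystem import ColumnGrid, ColumnModel, default_initial_state


@pytest.fixture(scope="session")
def model2():
    """2-layer column model (22 state entries): cheap adjoint oracles."""
    return ColumnModel(grid=ColumnGrid.uniform(n_layers=2))


@pytest.fixture(scope="session")
def model3():
    return ColumnModel(grid=ColumnGrid.uniform(n_layers=3))


@pytest.fixture(scope="session")
def model5():
    """The default 5-layer configuration."""
    return ColumnModel()


@pytest.fixture
def state2(model2):
    return default_initial_state(model2.grid)


@pytest.fixture
def state5(model5):
    return default_initial_state(model5.grid)


def random_positive_state(model, seed=0, scale=0.3):
    """A random non-negative state around the default profile."""
    rng = np.random.default_rng(seed)
    base = default_initial_state(model.grid).values
    return base * np.exp(scale * rng.standard_normal(model.n))
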