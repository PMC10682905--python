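import numpy as np
import pytest

from nichekit import synthdata
from nichekit.grids import EnvStack, GridGeometry, Layer


@pytest.fixture
def geom_small() -> GridGeometry:
    return GridGeometry(n_rows=30, n_cols=30, x_origin=-110.0, y_origin=30.0, cell_size=0.05)


@pytest.fixture
def geom_tiny() -> GridGeometry:
    return GridGeometry(n_rows=4, n_cols=5, x_origin=0.0, y_origin=2.0, cell_size=0.5)


@pytest.fixture
def stack_small(geom_small) -> EnvStack:
    return synthdata.make_env_layers(seed=42, geometry=geom_small, n_vars=3, smoothness=2.0)


@pytest.fixture
def niches():
    return synthdata.default_niches(3)


@pytest.fixture
def constant_layer(geom_tiny) -> Layer:
    return Layer("const", geom_tiny, np.full(geom_tiny.shape, 7.0))


def make_world(seed: int, n_rows: int = 40, n_cols: int = 40, n_vars: int = 3, smoothness: float = 3.0):
    """Seeded synthetic world used by several test modules."""
    geom = GridGeometry(n_rows, n_cols, -110.0, 30.0, 0.05)
    stack = synthdata.make_env_layers(seed=seed, geometry=geom, n_vars=n_vars, smoothness=smoothness)
    return stack, synthdata.default_niches(n_vars)
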