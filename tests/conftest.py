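import numpy as np
import pytest

from mwablate import applicator as app
from mwablate import bioheat as bh
from mwablate.grid import VoxelGrid


@pytest.fixture(scope="session")
def tissue():
    return bh.TissueModel()


@pytest.fixture(scope="session")
def blood():
    return bh.BloodModel()


@pytest.fixture(scope="session")
def table():
    return app.default_table()


@pytest.fixture
def small_grid():
    """Centered 1 mm grid, 40 mm box."""
    n = 41
    half = (n - 1) / 2.0
    return VoxelGrid((n, n, n), (1.0, 1.0, 1.0), (-half, -half, -half))


@pytest.fixture
def rng():
    return np.random.default_rng(20230942)


def centered_grid(n: int, spacing: float) -> VoxelGrid:
    half = (n - 1) / 2.0 * spacing
    return VoxelGrid((n, n, n), (spacing,) * 3, (-half, -half, -half))
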