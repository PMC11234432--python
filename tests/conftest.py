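import numpy as np
import pytest

from pvtarget.config import RunConfig
from pvtarget.geometry import BifurcationSpec, rasterize
from pvtarget.magnet import DiscMagnet


@pytest.fixture(scope="session")
def magnet() -> DiscMagnet:
    """The N40 targeting magnet (Br 1.3 T, R 2.0 mm, D 2.4 mm)."""
    return DiscMagnet()


@pytest.fixture(scope="session")
def default_spec() -> BifurcationSpec:
    return BifurcationSpec()


@pytest.fixture(scope="session")
def bifurcation_mask(default_spec):
    """Default bifurcation rasterized at lumen/16."""
    return rasterize(default_spec, 0.125e-3)


@pytest.fixture(scope="session")
def straight_mask_32():
    """Straight 16 mm channel, 32 cells across the 2 mm lumen."""
    spec = BifurcationSpec(branch_length=0.0, trunk_length=16e-3)
    return rasterize(spec, 2e-3 / 32)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
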