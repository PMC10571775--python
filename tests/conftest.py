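import numpy as np
import pytest

from hippomech import BSMConfig, BellParams, CellGeometry, HippoParams
from hippomech.bsm_coupler import GrowthParams
from hippomech.tissue_mechanics import MechParams, build_hex_patch


@pytest.fixture
def bell():
    return BellParams()


@pytest.fixture
def hippo():
    return HippoParams()


@pytest.fixture
def single_cell():
    return CellGeometry.single_cell(1)


@pytest.fixture
def patch():
    """Soft module-default patch (purely mechanical demonstrations)."""
    return build_hex_patch(1.0, MechParams())


@pytest.fixture
def quick_config():
    """Coupled config with a short horizon for fast loop tests."""
    cfg = BSMConfig()
    cfg.horizon = 5.0
    cfg.coupling_dt = 60.0
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(20230)
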