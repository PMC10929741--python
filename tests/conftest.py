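import numpy as np
import pytest

from qaflens.config import GeneratorConfig, StudyConfig
from qaflens import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gen_cfg():
    return GeneratorConfig()


@pytest.fixture
def quiet_cfg():
    """Generator with all stochastic rendering noise disabled."""
    import dataclasses
    return dataclasses.replace(GeneratorConfig(), noise_scale=0.0)


@pytest.fixture
def small_study():
    """Reduced-size rendered study for smoke tests."""
    cfg = StudyConfig()
    cfg.n, cfg.surgery_n = 32, 8
    cfg.qaf_size_px = 96
    cfg.lqaf_rows = cfg.lqaf_cols = 32
    cfg.acoct_shape = (48, 64)
    cfg.scheimpflug_shape = (48, 48)
    return cfg


@pytest.fixture
def geometry():
    return syn.FundusGeometry.default(160)
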