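import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fnpgrange.config import Config
from fnpgrange.geometry import build_geometry
from fnpgrange.phasespace import emission_model_from_config


@pytest.fixture()
def config():
    return Config()


@pytest.fixture()
def exact_config():
    """Config with effectively disabled energy cuts for exact-kinematics work.

    A sub-threshold hit removed by a cut makes the selected coincidence
    non-consecutive, which legitimately breaks the closed-form round trip;
    kinematic-exactness checks therefore run with negligible cuts.
    """
    cfg = Config()
    cfg.resolution.cut_fn_mev = 1e-12
    cfg.resolution.cut_pg_mev = 1e-12
    return cfg


@pytest.fixture()
def geometry(config):
    return build_geometry(config)


@pytest.fixture()
def emission_model(config):
    return emission_model_from_config(config)


@pytest.fixture(autouse=True)
def _quiet_beta_warnings():
    # fast-neutron spectra reach v/c ~ 0.35; the package warns once per batch
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*v/c > 0.1.*")
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
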