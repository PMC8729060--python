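import copy

import pytest

import endosim as es


@pytest.fixture(scope="session")
def default_cfg():
    return es.default_scenario()


@pytest.fixture()
def cfg(default_cfg):
    """Fresh mutable copy of the base-case configuration."""
    return copy.deepcopy(default_cfg)


@pytest.fixture(scope="session")
def model():
    """Calibrated baseline shared across tests (moderate calibration n)."""
    c = es.default_scenario()
    c.calibration.n_cal = 400_000
    return es.calibrate_scenario(c)
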