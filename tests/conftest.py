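import numpy as np
import pytest

from delaywta.dde_solver import integrate_dde
from delaywta.model_core import ModelParams, StimulusProtocol


@pytest.fixture(scope="session")
def params_sub():
    """Canonical parameters at the subcritical delay."""
    return ModelParams(tau_1=1.4, tau_2=1.4)


@pytest.fixture(scope="session")
def params_super():
    """Canonical parameters at the supercritical delay."""
    return ModelParams(tau_1=1.7, tau_2=1.7)


@pytest.fixture(scope="session")
def traj_rest(params_sub):
    return integrate_dde(params_sub, StimulusProtocol(sigma=0.0))


@pytest.fixture(scope="session")
def traj_fig3b(params_sub):
    return integrate_dde(params_sub, StimulusProtocol(sigma=0.3))


@pytest.fixture(scope="session")
def traj_fig3c(params_super):
    return integrate_dde(params_super, StimulusProtocol(sigma=0.3))


@pytest.fixture(scope="session")
def traj_fig3d(params_super):
    return integrate_dde(params_super, StimulusProtocol(sigma=1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
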