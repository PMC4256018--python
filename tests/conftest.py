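import warnings

import numpy as np
import pytest

from ornpn.datatypes import NeuronParamVector, PopulationModel, StimulusEvent
from ornpn.defaults import default_orn_model, default_pn_model


@pytest.fixture(scope="session")
def orn_model():
    return default_orn_model()


@pytest.fixture(scope="session")
def pn_model():
    return default_pn_model()


@pytest.fixture
def median_orn(orn_model):
    return orn_model.median_params()


@pytest.fixture
def degenerate_model(orn_model):
    """Zero-variance copy of the default model: every draw is the median."""
    return PopulationModel(M=orn_model.M, Sigma=np.zeros((6, 6)),
                           N=orn_model.N, spont_lognorm=orn_model.spont_lognorm)


@pytest.fixture
def simple_stim():
    return StimulusEvent(dose_log_ng=1.0)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*clipped to 0.*")
        warnings.filterwarnings("ignore", message=".*non-decreasing in dose.*")
        warnings.filterwarnings("ignore", message=".*spontaneous rate set to 0.*")
        yield


def make_params(**kw) -> NeuronParamVector:
    base = dict(F_M=163.0, C_half=1.35, n=0.81, L_0=150.0, lam=28.0, L_m=60.0)
    base.update(kw)
    return NeuronParamVector(**base)
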