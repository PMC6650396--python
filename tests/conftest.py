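"""Shared fixtures: the expensive nominal-model objects are session-scoped."""

import numpy as np
import pytest

from nfatnet import (
    build_full_network,
    find_baseline,
    make_sequential_pulses,
    nominal_parameters,
    simulate,
)


@pytest.fixture(scope="session")
def full_model():
    return build_full_network()


@pytest.fixture(scope="session")
def nominal():
    return nominal_parameters()


@pytest.fixture(scope="session")
def baseline(full_model, nominal):
    return find_baseline(full_model, nominal)


@pytest.fixture(scope="session")
def equal_pulse_protocol():
    return make_sequential_pulses(1.0, 1.0)


@pytest.fixture(scope="session")
def nominal_trajectory(full_model, nominal, equal_pulse_protocol, baseline):
    """The calibrated model under two equal TCR pulses 48 h apart."""
    return simulate(full_model, nominal, equal_pulse_protocol, baseline=baseline)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
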