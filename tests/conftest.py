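"""Shared fixtures: one default synthetic system reused across test modules."""
import numpy as np
import pytest

from chromlink.synthetic_data import (
    TruthConfig,
    generate_truth,
    simulate_contact_maps,
    simulate_peaks_expression,
)


@pytest.fixture(scope="session")
def default_config():
    return TruthConfig(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_config):
    return generate_truth(default_config)


@pytest.fixture(scope="session")
def default_maps(default_truth):
    return simulate_contact_maps(default_truth)


@pytest.fixture(scope="session")
def default_peaks_expression(default_truth):
    return simulate_peaks_expression(default_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
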