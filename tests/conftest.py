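"""Shared fixtures: the reference design, reference-configuration synthetic trials
(noisy and zero-noise) and their derived tables, generated once per session."""

import pytest

from mixtrial import simulate
from mixtrial.indices import build_index_table, rme_long_table
from mixtrial.model import default_design


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def ref_config(design):
    return simulate.reference_config(design, rng_seed=1)


@pytest.fixture(scope="session")
def noisy_records(ref_config):
    return simulate.generate_trial(ref_config)


@pytest.fixture(scope="session")
def zero_config(ref_config):
    return simulate.zero_noise(ref_config)


@pytest.fixture(scope="session")
def zero_records(zero_config):
    return simulate.generate_trial(zero_config)


@pytest.fixture(scope="session")
def zero_index_table(zero_records, design):
    return build_index_table(zero_records, design)


@pytest.fixture(scope="session")
def noisy_index_table(noisy_records, design):
    return build_index_table(noisy_records, design)


@pytest.fixture(scope="session")
def noisy_rme_table(noisy_records, design):
    return rme_long_table(noisy_records, design)
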