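import numpy as np
import pytest

from metopls import (
    AnalysisConfig,
    EffectSpec,
    default_design,
    default_panel,
    preprocess,
    simulate,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def dataset(panel, design):
    """One default-effects simulated dataset, shared across tests."""
    table, lods, truth = simulate(panel, design, EffectSpec(), seed=7)
    return table, lods, truth


@pytest.fixture(scope="session")
def clean_dataset(panel, design, dataset):
    table, lods, truth = dataset
    pre = preprocess(table, design, lods)
    return pre, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20200323)


@pytest.fixture()
def fast_config():
    return AnalysisConfig(n_perm=30, seed=11)
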