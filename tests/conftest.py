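import numpy as np
import pytest

from aglab.features import CorpusStatistics, feature_matrix
from aglab.stimuli import build_stimulus_set


@pytest.fixture(scope="session")
def centre_left_design():
    """One fixed stimulus bundle shared across tests."""
    return build_stimulus_set("centre-left", seed=7)


@pytest.fixture(scope="session")
def centre_left_features(centre_left_design):
    stats = CorpusStatistics.from_corpus(centre_left_design.training)
    return feature_matrix(centre_left_design.pairs, stats, "chunk-rep")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
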