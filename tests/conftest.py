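import numpy as np
import pytest

from maesig.adtree import TrainingSet
from maesig.chromatin_features import build_feature_matrix
from maesig.synthetic import SimulationConfig, simulate_counts, simulate_tracks, simulate_truth


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11, n_genes=2000)


@pytest.fixture(scope="session")
def truth(sim_config):
    return simulate_truth(sim_config)


@pytest.fixture(scope="session")
def tracks_and_genes(truth, sim_config):
    return simulate_tracks(truth, sim_config)


@pytest.fixture(scope="session")
def feature_matrix(tracks_and_genes):
    tracks, input_track, genes = tracks_and_genes
    return build_feature_matrix(tracks, input_track, genes)


@pytest.fixture(scope="session")
def count_records(truth, sim_config):
    return simulate_counts(truth, sim_config)


@pytest.fixture(scope="session")
def training_set(feature_matrix, truth):
    """Labeled subset at roughly the scale of a curated training catalog."""
    rng = np.random.default_rng(5)
    mae = truth.index[truth["class"] == "MAE"]
    bae = truth.index[truth["class"] == "BAE"]
    labels = {g: "MAE" for g in rng.choice(mae, 150, replace=False)}
    labels |= {g: "BAE" for g in rng.choice(bae, 600, replace=False)}
    return TrainingSet.from_labels(feature_matrix, labels)
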