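import numpy as np
import pandas as pd
import pytest

from magic_mae.gene_body_signal import build_feature_table
from magic_mae.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_labels,
    simulate_tracks,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=300, n_x_genes=5, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A compact simulated dataset shared across tests: models, labels, tracks."""
    models = simulate_annotation(small_config)
    labels = simulate_labels(small_config)
    tracks = simulate_tracks(models, labels, small_config)
    return models, labels, tracks


@pytest.fixture(scope="session")
def small_features(small_dataset):
    models, labels, tracks = small_dataset
    return build_feature_table(
        models,
        [tracks["k27"]],
        [tracks["k36"]],
        input_tracks=[tracks["input"]],
        rna_tracks=[tracks["rna"]],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def truth_table(labels: pd.Series) -> pd.DataFrame:
    """Planted-truth benchmark calls (MAE vs BAE) from simulation labels."""
    return pd.DataFrame(
        {
            "gene_id": labels.index,
            "benchmark_call": np.where(labels == "MAE", "MAE", "BAE"),
        }
    )
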