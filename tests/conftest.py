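import numpy as np
import pytest

from fluorospec import simulate
from fluorospec.models import ModelConfig


@pytest.fixture(scope="session")
def tiny_library():
    """32 molecules (8 PFAS, 24 background), deterministic."""
    return simulate.generate_library(8, 24, seed=123)


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(seed=0)


@pytest.fixture(scope="session")
def memorizing_ae(tiny_config):
    """A small autoencoder trained to near-convergence on 24 molecules."""
    from fluorospec.training import train_autoencoder

    library = simulate.generate_library(6, 18, seed=77)
    model, history = train_autoencoder(library, tiny_config, epochs=250, seed=0,
                                       batch_size=8)
    return model, library, history


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


TINY_PIPELINE_CONFIG = {
    "seed": 7,
    "library": {"n_pfas": 5, "n_background": 15},
    "fixtures": {"spectra_per_compound": 2},
    "ae": {"epochs": 6, "train_fraction": 0.8},
    "encoder": {"epochs": 3, "val_fraction": 0.0},
    "model": {"gru_hidden": 64, "attn_layers": 1, "attn_heads": 2,
              "d_model": 32, "ffn_dim": 32, "cnn_channels": 4},
}


@pytest.fixture(scope="session")
def tiny_pipeline_runs(tmp_path_factory):
    """The same scaled-down workflow executed twice with identical seeds."""
    import json

    from fluorospec.pipeline import DEFAULT_CONFIG, Pipeline, _merge

    runs = []
    for name in ("a", "b"):
        config = _merge(DEFAULT_CONFIG,
                        json.loads(json.dumps(TINY_PIPELINE_CONFIG)))
        pipeline = Pipeline(config, tmp_path_factory.mktemp(f"pipe_{name}"))
        pipeline.run()
        runs.append(pipeline)
    return runs
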