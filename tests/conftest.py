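"""Shared fixtures: synthetic datasets and a small trained model.

Everything is generated programmatically at test time from fixed seeds; no
audio files are stored in the repository.
"""

import numpy as np
import pytest

from eatsound.io import read_manifest
from eatsound.model import ModelConfig, train
from eatsound.synth import SynthConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """30 short synthetic recordings (2 speakers), with strong labels."""
    out = tmp_path_factory.mktemp("tiny_data")
    return generate_dataset(SynthConfig(seed=42), n_speakers=2,
                            n_recordings=15, out_dir=str(out),
                            events_range=(6, 10))


@pytest.fixture(scope="session")
def fixture_model(tiny_dataset):
    """A small hybrid model trained briefly on the tiny dataset.

    Good enough for behavioral contracts (decoding silence, determinism,
    alignment plumbing); not meant to hit the end-to-end accuracy bar.
    """
    cfg = ModelConfig(enc_hidden=32, dec_hidden=32, att_dim=32, epochs=20,
                      seed=7, alpha=0.7)
    model, history = train(tiny_dataset, None, cfg)
    return model, history
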