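"""Shared fixtures: tiny deterministic worlds and fast training configs."""

import numpy as np
import pytest

from deepmda.evaluate import PipelineInputs
from deepmda.model import TrainConfig
from deepmda.synthetic import SynthConfig, generate_world


@pytest.fixture(scope="session")
def tiny_world():
    """A small planted world reused by the protocol tests."""
    return generate_world(SynthConfig(nm=40, nd=20, seed=11))


@pytest.fixture(scope="session")
def tiny_inputs(tiny_world):
    w = tiny_world
    return PipelineInputs(amd=w.amd, fs=w.fs, amt=w.amt, ald=w.ald, agd=w.agd,
                          descriptors=w.descriptors)


@pytest.fixture()
def fast_config():
    """Training config scaled for tiny fixtures (seconds, not minutes)."""
    return TrainConfig(
        seed=0,
        pretrain_epochs=5,
        train_epochs=10,
        patience=3,
        code_dim=8,
        mirna_hidden=(16,),
        disease_hidden=(16,),
        classifier_hidden=(16, 8),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
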