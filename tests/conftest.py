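import numpy as np
import pytest

from rsrnsp import (Model, NetworkConfig, TrainProtocol,
                    make_counting_sequence, train)


@pytest.fixture
def tiny_config():
    """A small but valid network configuration for fast unit tests."""
    return NetworkConfig(n_excitatory=30, n_output=3, p_c=0.2,
                         n_input_subset=5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def trained_counting_model():
    """One short counting-task training run shared by read-only tests."""
    seq = make_counting_sequence(4, 300)
    cfg = NetworkConfig(n_excitatory=100, p_c=0.05, seed=3)
    model = Model.for_task(cfg, seq)
    proto = TrainProtocol(stage1_steps=50, stage2_steps=400, alternations=20)
    history = train(model, proto, seq)
    return model, history, seq
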