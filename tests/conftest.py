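import numpy as np
import pytest

from eeggan import (
    TrainConfig,
    generate_session,
    normalize,
    session_spec_2b,
    train_gan,
)


@pytest.fixture(scope="session")
def tiny_2b_session():
    """Small 3-channel, 2-class session used by training smoke tests."""
    spec = session_spec_2b(trials_per_class=8, snr=0.5, seed=42)
    epochs, stats = normalize(generate_session(spec))
    return spec, epochs, stats


@pytest.fixture(scope="session")
def trained_tiny_gan(tiny_2b_session):
    """A briefly trained GAN on the tiny 2b-like session (shared, read-only)."""
    _, epochs, _ = tiny_2b_session
    tcfg = TrainConfig(gan_epochs=2, clf_epochs=1, batch_size=16, seed=3)
    G, D, state = train_gan(epochs, tcfg=tcfg)
    return G, D, state, tcfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
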