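import numpy as np
import pytest

import topogen as tg
from topogen.study import run_desk_study


@pytest.fixture(scope="session")
def world():
    return tg.SyntheticWorldSpec()


@pytest.fixture(scope="session")
def vocab():
    return tg.build_vocabulary(["HHH", "EHEE"])


@pytest.fixture(scope="session")
def tiny_transformer(vocab):
    cfg = tg.TransformerConfig(n_layers=1, n_heads=2, head_dim=4, ff_dim=16)
    return tg.GeneratorModel(vocab, cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_lstm(vocab):
    cfg = tg.LSTMConfig(n_layers=1, hidden_dim=8, embed_dim=6)
    return tg.GeneratorModel(vocab, cfg, seed=11)


def make_uniform_model(vocab, backend="transformer"):
    """A model whose next-token distribution is uniform over residues + end."""
    cfg = (tg.TransformerConfig(n_layers=1, n_heads=2, head_dim=4, ff_dim=8)
           if backend == "transformer" else
           tg.LSTMConfig(n_layers=1, hidden_dim=8, embed_dim=6))
    model = tg.GeneratorModel(vocab, cfg, seed=0)
    for p in model.parameters():
        p.data[...] = 0.0
    return model


@pytest.fixture(scope="session")
def desk_study():
    """The full desk-scale pipeline, shared across acceptance tests."""
    return run_desk_study(seed=7)


@pytest.fixture(scope="session")
def synthetic_hhh(world):
    rng = np.random.default_rng(5)
    return [tg.sample_synthetic_sequence(world, "HHH", rng).residues for _ in range(300)]
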