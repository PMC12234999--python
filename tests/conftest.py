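import numpy as np
import pytest

from csglearn import (
    EncoderConfig,
    SplitSpec,
    TrainConfig,
    default_bond_type_vocabulary,
    make_default_corpus,
    split_dataset,
    train_model,
)


@pytest.fixture(scope="session")
def vocab():
    return default_bond_type_vocabulary()


@pytest.fixture(scope="session")
def corpus():
    """The default synthetic fixture: 120 molecules, 300 labeled reactions."""
    return make_default_corpus(seed=0)


@pytest.fixture(scope="session")
def corpus_splits(corpus):
    _, reactions = corpus
    return split_dataset(reactions, SplitSpec(seed=0))


def _fixture_train_config(epochs=60):
    return TrainConfig(
        margin=4.0, learning_rate=1e-3, epochs=epochs, batch_size=32, seed=0
    )


@pytest.fixture(scope="session")
def fitted_csgl(corpus_splits):
    """CSGL(GCN) d=64, L=2, H=1, 60 epochs on the fixture train split."""
    train, _, _ = corpus_splits
    return train_model(
        train,
        encoder_config=EncoderConfig(gnn_type="gcn", hidden_dim=64, num_layers=2),
        train_config=_fixture_train_config(),
        with_csgnn=True,
    )


@pytest.fixture(scope="session")
def fitted_csgnn_free(corpus_splits):
    """The CSGNN-free variant used for transfer to classification/properties."""
    train, _, _ = corpus_splits
    return train_model(
        train,
        encoder_config=EncoderConfig(gnn_type="gcn", hidden_dim=64, num_layers=2),
        train_config=_fixture_train_config(),
        with_csgnn=False,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
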