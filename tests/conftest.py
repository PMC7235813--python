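import dataclasses

import numpy as np
import pytest

import layerfuse as lf


@pytest.fixture(scope="session")
def small_corpus():
    return lf.generate_corpus(lf.default_corpus_spec(n_sentences=200, seed=5))


@pytest.fixture(scope="session")
def micro_encoder_config():
    return lf.EncoderConfig(
        n_layers=2, hidden_size=16, n_encoder_heads=2,
        vocabulary_size=80, max_sentence_length=64,
        dropout_rate=0.1, seed=3,
    )


def random_stack(L, n, d, seed=0):
    rng = np.random.default_rng(seed)
    return lf.LayerStack([rng.normal(size=(n, d)) for _ in range(L)])


@pytest.fixture(scope="session")
def trained_tiny(small_corpus, micro_encoder_config):
    """One quick end-to-end training shared by the model-level tests."""
    train_set, valid_set, test_set = lf.split_corpus(
        small_corpus, (0.6, 0.2, 0.2), seed=5)
    model, history = lf.train(
        train_set, valid_set, micro_encoder_config,
        train_config=lf.TrainConfig(epochs=3, batch_size=32,
                                    learning_rate=2e-3, seed=7),
        method="multihead", n_fusion_heads=2,
    )
    return {"model": model, "history": history,
            "train": train_set, "valid": valid_set, "test": test_set}
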