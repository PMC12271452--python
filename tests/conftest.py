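import numpy as np
import pytest

from ehrclust.encoder import ModelConfig
from ehrclust.sequences import prepare_sequences
from ehrclust.synthetic import generate_cohort, table1_config


@pytest.fixture(scope="session")
def small_cohort():
    """150 patients from the default (realistic-marginals) configuration."""
    records, truth = generate_cohort(table1_config(150, seed=3))
    return records, truth


@pytest.fixture(scope="session")
def small_sequences(small_cohort):
    records, _ = small_cohort
    seqs, vocab = prepare_sequences(records, min_patient_count=2)
    return seqs, vocab


@pytest.fixture(scope="session")
def tiny_model_config(small_sequences):
    _, vocab = small_sequences
    return ModelConfig(
        vocab_size=len(vocab),
        hidden_size=16,
        attention_heads=2,
        discriminator_layers=2,
        generator_layers=1,
        pretrain_epochs=2,
        diffcse_epochs=2,
        batch_size=32,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
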