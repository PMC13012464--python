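import numpy as np
import pytest

from peppinet.synthetic import SyntheticSpec, gen_interaction_data
from peppinet.training import TrainConfig, make_cv_folds, train_model


@pytest.fixture(scope="session")
def planted_data():
    """Default planted-interaction dataset (2000 pairs, dim 64)."""
    return gen_interaction_data(SyntheticSpec())


@pytest.fixture(scope="session")
def small_planted_data():
    """A fast, smaller planted dataset for training-behavior tests."""
    return gen_interaction_data(
        SyntheticSpec(n_peptides=20, n_proteins=15, dim=16, seed=99)
    )


@pytest.fixture(scope="session")
def quick_train_config():
    return TrainConfig(max_epochs=30, patience=5, seed=1234)


@pytest.fixture(scope="session")
def trained_small_model(small_planted_data, quick_train_config):
    """One fold trained on the small planted set; reused across test modules."""
    pairs = list(small_planted_data.pairs)
    fold = make_cv_folds(pairs, k=5, seed=1234)[0]
    model = train_model(fold, pairs, small_planted_data.embeddings, quick_train_config)
    return fold, model
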