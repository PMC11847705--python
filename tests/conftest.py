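import numpy as np
import pytest

from comet.code_embedding import EmbeddingHyper, tables_for_bundle
from comet.comet_net import EHREncoderConfig
from comet.synthetic_cohort import SyntheticConfig, generate


TINY = dict(n_pretrain=60, n_omics=14, vocab_size=30, n_analytes=8,
            latent_dim=2, horizon=8, samples_per_omics_patient=2,
            sample_window=4)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small continuous-outcome cohort for fast unit tests."""
    bundle, truth = generate(SyntheticConfig(seed=7, **TINY))
    return bundle, truth


@pytest.fixture(scope="session")
def tiny_binary_bundle():
    bundle, truth = generate(SyntheticConfig(seed=11, outcome_type="binary",
                                             prevalence=0.3, **TINY))
    return bundle, truth


@pytest.fixture(scope="session")
def tiny_tables(tiny_bundle):
    bundle, _ = tiny_bundle
    return tables_for_bundle(bundle, 8, EmbeddingHyper(seed=3, epochs=2),
                             shared=True)


@pytest.fixture()
def fast_config():
    return EHREncoderConfig(hidden_dim=8, n_layers=2, dropout=0.1,
                            learning_rate=1e-2, max_epochs=5,
                            batch_size_pretrain=32, batch_size_omics=8,
                            seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
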