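import numpy as np
import pytest

from imagene.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with real signal: 3 causal genes, disease-driven labels."""
    cfg = SyntheticConfig(
        n_subjects=120,
        n_snps=60,
        n_genes=12,
        n_features=8,
        n_causal_genes=3,
        effect_size=0.8,
        noise_sd=1.0,
        n_disease_features=4,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
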