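import numpy as np
import pytest

from mimelat.simulate import GeneratorConfig, generate_paired


@pytest.fixture(scope="session")
def latent_dataset():
    """Small latent-regime cohort with ground truth (shared across tests)."""
    cfg = GeneratorConfig(n_samples=250, n_taxa=100, n_metabolites=50,
                          latent_dim_true=10, noise_sd_mic=0.05,
                          noise_sd_met=0.05, seed=0)
    return generate_paired(cfg)


@pytest.fixture(scope="session")
def dominant_dataset():
    """Dominant-producer cohort with low noise."""
    cfg = GeneratorConfig(regime="dominant", n_samples=150, n_taxa=50,
                          n_metabolites=30, noise_sd_met=0.05, seed=0)
    return generate_paired(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
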