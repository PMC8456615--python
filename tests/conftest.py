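import numpy as np
import pytest

import chemovae as cv
from chemovae.vae import VAEArchitecture


@pytest.fixture(scope="session")
def small_cohort():
    """3 tumor types x 50 samples, 300 genes; well-separated clusters."""
    return cv.generate_cohort(
        cv.SyntheticSpec(n_types=3, samples_per_type=50, n_genes=300, seed=2)
    )


@pytest.fixture(scope="session")
def small_features(small_cohort):
    X, filt, params = cv.build_vae_input(
        small_cohort.counts_matrix(),
        small_cohort.abundance_matrix(),
        small_cohort.type_of,
    )
    return X


@pytest.fixture(scope="session")
def trained_vae(small_features):
    arch = VAEArchitecture(latent_dim=8, n_layers=6, loss_kind="l1")
    return cv.train_vae(small_features, arch, seed=0)


@pytest.fixture()
def rng():
    # fresh, function-scoped stream so each test is deterministic in isolation
    return np.random.default_rng(123)
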