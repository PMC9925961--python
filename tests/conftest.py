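"""Shared fixtures: small synthetic cohorts and pre-trained models.

Session-scoped so the expensive trainings run once per session.
"""

import numpy as np
import pytest

from cmedgan.autoencoder import AEConfig, train_autoencoder
from cmedgan.adversarial import GANConfig, train_cmedgan
from cmedgan.cohort import CohortSpec, generate_cohort
from cmedgan.preprocess import FeatureTable, dummy_code, impute, normalize


def preprocess_cohort(cohort):
    raw = dummy_code(impute(cohort.raw))
    ft, stats = normalize(raw)
    y = cohort.raw.labels.to_numpy(dtype=int)
    return ft, y, stats


@pytest.fixture(scope="session")
def cohort20():
    """400 patients, 14 continuous + 6 binary features, 10% deaths, clear signal."""
    spec = CohortSpec(
        n_patients=400, n_continuous=14, n_binary=6, n_categorical=0,
        prevalence=0.10, effect_size=0.6, missing_rate=0.0, seed=3,
    )
    c = generate_cohort(spec)
    ft, y, _ = preprocess_cohort(c)
    return ft, y, c.truth


@pytest.fixture(scope="session")
def memo_fixture():
    """50 patients, 10 features, strong class signal — a memorisation target."""
    spec = CohortSpec(
        n_patients=50, n_continuous=7, n_binary=3, n_categorical=0,
        prevalence=0.3, effect_size=2.0, missing_rate=0.0, seed=5,
    )
    c = generate_cohort(spec)
    ft, y, _ = preprocess_cohort(c)
    return ft, y


@pytest.fixture(scope="session")
def memo_ae(memo_fixture):
    ft, y = memo_fixture
    return train_autoencoder(ft, y, AEConfig(d_latent=8, hidden=64, epochs=500, seed=0))


@pytest.fixture(scope="session")
def trained_ae(cohort20):
    ft, y, _ = cohort20
    return train_autoencoder(ft, y, AEConfig(d_latent=16, hidden=64, epochs=200, seed=0))


@pytest.fixture(scope="session")
def trained_gan(cohort20, trained_ae):
    ft, y, _ = cohort20
    cfg = GANConfig(d_noise=16, hidden=128, iters=800, lr=2e-4, seed=1)
    return train_cmedgan(ft, y, trained_ae, cfg)


@pytest.fixture(scope="session")
def separable2d():
    """Linearly separable 2-feature classification fixture (n=200)."""
    rng = np.random.default_rng(9)
    n = 100
    x0 = rng.normal([0.25, 0.25], 0.05, size=(n, 2))
    x1 = rng.normal([0.75, 0.75], 0.05, size=(n, 2))
    X = np.clip(np.vstack([x0, x1]), 0, 1)
    y = np.repeat([0, 1], n)
    perm = rng.permutation(2 * n)
    ft = FeatureTable(X[perm], ["f0", "f1"], ["continuous", "continuous"])
    return ft, y[perm]
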