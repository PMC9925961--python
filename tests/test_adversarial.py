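"""WGAN-GP losses, gradient penalty, adversarial training and generation."""

import numpy as np
import pytest

from cmedgan import nn
from cmedgan.adversarial import (
    GANConfig,
    GANParams,
    critic_loss,
    generate_fake,
    generator_loss,
    gradient_penalty,
    train_cmedgan,
)
from cmedgan.autoencoder import AEConfig, train_autoencoder
from cmedgan.preprocess import FeatureTable


class TestGradientPenalty:
    def test_unit_gradient_linear_critic_has_zero_penalty(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        critic = (lambda x, y: x @ w, lambda x, y: np.tile(w, (len(x), 1)))
        real, fake = rng.random((8, 3)), rng.random((8, 3))
        pen = gradient_penalty(critic, real, fake, np.zeros(8), gp_lambda=10.0, seed=1)
        assert pen == pytest.approx(0.0, abs=1e-12)

    def test_slope_k_one_dimensional_critic(self):
        # critic(x) = 2x: penalty = lambda * (2 - 1)^2
        critic = (lambda x, y: 2.0 * x[:, 0], lambda x, y: np.full_like(x, 2.0))
        real, fake = np.ones((5, 1)), np.zeros((5, 1))
        pen = gradient_penalty(critic, real, fake, np.zeros(5), gp_lambda=10.0, seed=0)
        assert pen == pytest.approx(10.0, abs=1e-12)

    def test_constant_critic_pays_full_penalty(self):
        critic = (lambda x, y: np.full(len(x), 3.0), lambda x, y: np.zeros_like(x))
        pen = gradient_penalty(critic, np.ones((4, 2)), np.zeros((4, 2)),
                               np.zeros(4), gp_lambda=7.0, seed=0)
        assert pen == pytest.approx(7.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_penalty_nonnegative_for_random_net_critics(self, seed):
        rng = np.random.default_rng(seed)
        critic = nn.init_net([4, 8, 1], rng)
        pen = gradient_penalty(critic, rng.random((6, 3)), rng.random((6, 3)),
                               rng.integers(0, 2, 6), gp_lambda=10.0, seed=seed)
        assert pen >= 0.0

    def test_matches_finite_difference_oracle_on_toy_critic(self):
        """Analytic penalty vs one built from finite-difference gradients."""
        rng = np.random.default_rng(3)
        critic = nn.init_net([3, 8, 1], rng)  # 2 features + label
        real, fake = rng.random((10, 2)), rng.random((10, 2))
        labels = rng.integers(0, 2, 10).astype(float)
        lam, seed = 10.0, 4
        pen = gradient_penalty(critic, real, fake, labels, gp_lambda=lam, seed=seed)

        # reproduce the interpolates, then estimate the gradient numerically
        eps_rng = np.random.default_rng(seed)
        eps = eps_rng.random((10, 1))
        xhat = eps * real + (1 - eps) * fake
        full = np.hstack([xhat, labels.reshape(-1, 1)])
        h = 1e-5
        g = np.zeros_like(full)
        for j in range(full.shape[1]):
            up, dn = full.copy(), full.copy()
            up[:, j] += h
            dn[:, j] -= h
            fu, _ = nn.forward(critic, up)
            fd_, _ = nn.forward(critic, dn)
            g[:, j] = (fu[:, 0] - fd_[:, 0]) / (2 * h)
        oracle = lam * np.mean((np.linalg.norm(g, axis=1) - 1.0) ** 2)
        assert pen == pytest.approx(oracle, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        critic = (lambda x, y: x[:, 0], lambda x, y: np.ones_like(x))
        with pytest.raises(ValueError):
            gradient_penalty(critic, np.ones((3, 2)), np.ones((4, 2)), np.zeros(3))


class TestLosses:
    CONST = staticmethod(lambda c: (lambda x, y: np.full(len(x), c),
                                    lambda x, y: np.zeros_like(x)))

    def test_constant_critic_loss_is_penalty_only(self):
        crit = self.CONST(2.5)
        rng = np.random.default_rng(0)
        real, fake = rng.random((6, 2)), rng.random((6, 2))
        gp = gradient_penalty(crit, real, fake, np.zeros(6), gp_lambda=10.0)
        assert gp == pytest.approx(10.0, abs=1e-12)
        assert critic_loss(crit, real, fake, np.zeros(6), np.zeros(6), gp) == \
            pytest.approx(gp, abs=1e-12)

    def test_identical_batches_zero_wasserstein_term(self):
        rng = np.random.default_rng(1)
        critic = nn.init_net([3, 6, 1], rng)
        batch = rng.random((7, 2))
        y = np.zeros(7)
        assert critic_loss(critic, batch, batch, y, y, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_wasserstein_term_linear_in_critic_scale(self):
        rng = np.random.default_rng(2)
        base = nn.init_net([3, 6, 1], rng)
        doubled = base.copy()
        doubled.weights[-1] = 2.0 * doubled.weights[-1]
        real, fake = rng.random((5, 2)), rng.random((5, 2))
        y = np.zeros(5)
        l1 = critic_loss(base, real, fake, y, y, 0.0)
        l2 = critic_loss(doubled, real, fake, y, y, 0.0)
        assert l2 == pytest.approx(2 * l1, abs=1e-10)

    def test_generator_loss_is_negated_mean_score(self):
        assert generator_loss(self.CONST(0.0), np.ones((4, 2)), np.zeros(4)) == 0.0
        assert generator_loss(self.CONST(5.0), np.ones((4, 2)), np.zeros(4)) == -5.0


class TestTraining:
    def test_zero_iterations_is_noop(self, cohort20, trained_ae):
        ft, y, _ = cohort20
        cfg = GANConfig(d_noise=8, hidden=16, iters=0, seed=5)
        a = train_cmedgan(ft, y, trained_ae, cfg)
        b = train_cmedgan(ft, y, trained_ae, cfg)
        for wa, wb in zip(a.generator.weights, b.generator.weights):
            np.testing.assert_array_equal(wa, wb)
        assert a.trace_wasserstein == []

    def test_loss_traces_finite_and_deterministic(self, cohort20, trained_ae):
        ft, y, _ = cohort20
        cfg = GANConfig(d_noise=8, hidden=16, iters=20, seed=6)
        a = train_cmedgan(ft, y, trained_ae, cfg)
        b = train_cmedgan(ft, y, trained_ae, cfg)
        assert np.isfinite(a.trace_wasserstein).all()
        assert np.isfinite(a.trace_penalty).all()
        np.testing.assert_allclose(a.trace_wasserstein, b.trace_wasserstein, atol=1e-6)

    def test_schema_mismatch_rejected(self, cohort20, trained_ae):
        ft, y, _ = cohort20
        narrow = FeatureTable(ft.X[:, :5], ft.columns[:5], ft.kinds[:5])
        with pytest.raises(ValueError, match="schema"):
            train_cmedgan(narrow, y, trained_ae, GANConfig(iters=1))

    def test_bernoulli_marginal_recovered(self):
        """All-binary fixture: fake Bernoulli rate approaches the real rate."""
        means = []
        for s in range(5):
            X = (np.random.default_rng(100 + s).random((300, 1)) < 0.7).astype(float)
            ft = FeatureTable(X, ["b0"], ["binary"])
            y = np.zeros(300, dtype=int)
            with pytest.warns(UserWarning):  # d_latent exceeds the single column
                ae = train_autoencoder(ft, y, AEConfig(d_latent=2, hidden=16,
                                                       epochs=200, seed=s))
            gan = train_cmedgan(ft, y, ae, GANConfig(d_noise=4, hidden=16,
                                                     iters=1000, lr=2e-4, seed=s))
            fake, _ = generate_fake(gan, y, seed=s)
            means.append(float(fake.X.mean()))
        assert 0.6 <= np.median(means) <= 0.8


class TestGenerateFake:
    def test_requested_labels_pass_through_exactly(self, trained_gan):
        want = np.repeat([1, 0], [40, 60])
        ft, y = generate_fake(trained_gan, want, seed=0)
        np.testing.assert_array_equal(y, want)
        assert ft.n_rows == 100
        assert ft.X.min() >= 0 and ft.X.max() <= 1

    def test_seed_determinism(self, trained_gan):
        want = np.repeat([0, 1], [30, 10])
        a, _ = generate_fake(trained_gan, want, seed=3)
        b, _ = generate_fake(trained_gan, want, seed=3)
        np.testing.assert_array_equal(a.X, b.X)

    def test_round_binary_mode_hardens_binary_columns(self, trained_gan):
        want = np.zeros(50, dtype=int)
        ft, _ = generate_fake(trained_gan, want, seed=1, round_binary=True)
        bmask = np.array([k == "binary" for k in ft.kinds])
        assert np.isin(ft.X[:, bmask], [0.0, 1.0]).all()
        assert ((ft.X[:, ~bmask] > 0) & (ft.X[:, ~bmask] < 1)).all()

    def test_fake_positives_resemble_real_positives(self, cohort20, trained_gan):
        """Conditional fidelity: same-label means are the closer ones."""
        ft, y, _ = cohort20
        fake, fy = generate_fake(
            trained_gan, np.ones(200, dtype=int), seed=2
        )
        fake_mu = fake.X.mean(axis=0)
        d_pos = np.abs(fake_mu - ft.X[y == 1].mean(axis=0)).mean()
        d_neg = np.abs(fake_mu - ft.X[y == 0].mean(axis=0)).mean()
        assert d_pos < d_neg

    def test_label_shuffle_changes_fake_distribution(self, cohort20, trained_gan):
        """Generated classes differ on the discriminative columns."""
        ft, y, truth = cohort20
        fake_pos, _ = generate_fake(trained_gan, np.ones(300, dtype=int), seed=4)
        fake_neg, _ = generate_fake(trained_gan, np.zeros(300, dtype=int), seed=4)
        n_cont = len(truth["mu0"])
        gap = (fake_pos.X[:, :n_cont].mean(0) - fake_neg.X[:, :n_cont].mean(0)).mean()
        # permutation null: pool and resplit
        pool = np.vstack([fake_pos.X[:, :n_cont], fake_neg.X[:, :n_cont]])
        rng = np.random.default_rng(0)
        null = []
        for _ in range(200):
            perm = rng.permutation(600)
            null.append((pool[perm[:300]].mean(0) - pool[perm[300:]].mean(0)).mean())
        assert gap > np.quantile(null, 0.95)


def test_checkpoint_roundtrip(tmp_path, trained_gan):
    path = tmp_path / "gan.npz"
    trained_gan.save(path)
    loaded = GANParams.load(path)
    want = np.repeat([0, 1], [5, 5])
    a, _ = generate_fake(trained_gan, want, seed=9)
    b, _ = generate_fake(loaded, want, seed=9)
    np.testing.assert_array_equal(a.X, b.X)
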