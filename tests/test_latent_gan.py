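"""WGAN-GP: shapes, Eq.-style losses, gradient penalty and training dynamics."""

import numpy as np
import pytest

from molgen.autodiff import Tensor
from molgen.chem_data import MoleculeRecord
from molgen.latent_gan import (GANConfig, build_gan, gradient_penalty,
                               sample_molecules, train_wgan, wgan_losses)

SMALL = dict(z_dim=8, critic_units=(32, 32, 32), gen_units=(16, 32), dropout=0.0,
             batch_size=50, seed=0)


class LinearCritic:
    """D(x) = scale * w.x with ||w|| = 1; gradient norm is `scale` everywhere."""

    def __init__(self, w, scale=1.0):
        w = np.asarray(w, dtype=float)
        self.w = Tensor(scale * w.reshape(-1, 1) / np.linalg.norm(w),
                        requires_grad=True)

    def __call__(self, x):
        return (x @ self.w).mean(axis=1)


class TestShapes:
    def test_generator_and_critic_contracts(self):
        gan = build_gan(GANConfig(**SMALL), latent_dim=6)
        lat = gan.generate_latents(7)
        assert lat.shape == (7, 6) and np.isfinite(lat).all()
        scores = gan.critic(Tensor(np.random.default_rng(0).normal(size=(7, 6))))
        assert scores.shape == (7,)

    def test_same_seed_same_output(self):
        a = build_gan(GANConfig(**SMALL), latent_dim=6)
        b = build_gan(GANConfig(**SMALL), latent_dim=6)
        assert np.array_equal(a.generate_latents(5), b.generate_latents(5))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            GANConfig(z_dim=0)
        with pytest.raises(ValueError):
            GANConfig(dropout=1.0)
        with pytest.raises(ValueError):
            build_gan(GANConfig(**SMALL), latent_dim=0)


class TestGradientPenalty:
    def test_unit_norm_linear_critic_zero_penalty(self):
        rng = np.random.default_rng(0)
        gp = gradient_penalty(LinearCritic([0.6, 0.8]), rng.normal(size=(8, 2)),
                              rng.normal(size=(8, 2)), rng=rng)
        assert float(gp.data) == pytest.approx(0.0, abs=1e-10)

    def test_doubled_critic_penalty_one(self):
        rng = np.random.default_rng(0)
        gp = gradient_penalty(LinearCritic([0.6, 0.8], scale=2.0),
                              rng.normal(size=(8, 2)), rng.normal(size=(8, 2)),
                              rng=rng)
        assert float(gp.data) == pytest.approx(1.0, abs=1e-9)

    def test_matches_finite_difference_gradient_norms(self):
        """Analytic interpolate gradients vs central differences, random critic."""
        rng = np.random.default_rng(1)
        gan = build_gan(GANConfig(**SMALL), latent_dim=4)
        gan.eval()
        real = rng.normal(size=(8, 4))
        fake = rng.normal(size=(8, 4))
        eps = rng.random((8, 1))
        xhat = eps * fake + (1 - eps) * real

        def d(x):
            from molgen.autodiff import no_grad
            with no_grad():
                return gan.critic(Tensor(x)).data

        h = 1e-5
        num_norms = np.empty(8)
        for i in range(8):
            g = np.empty(4)
            for j in range(4):
                xp, xm = xhat.copy(), xhat.copy()
                xp[i, j] += h
                xm[i, j] -= h
                g[j] = (d(xp)[i] - d(xm)[i]) / (2 * h)
            num_norms[i] = np.linalg.norm(g)
        expected = float(((num_norms - 1) ** 2).mean())
        gp = gradient_penalty(gan.critic, real, fake, eps=eps)
        assert float(gp.data) == pytest.approx(expected, abs=1e-3)

    def test_interpolates_on_segment(self):
        rng = np.random.default_rng(2)
        real, fake = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        eps = rng.random((5, 1))
        xhat = eps * fake + (1 - eps) * real
        assert np.allclose(xhat - real, eps * (fake - real))

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            gradient_penalty(LinearCritic([1.0]), np.empty((0, 1)), np.empty((0, 1)))


class TestLosses:
    def test_constant_critic_reduces_to_lambda(self):
        class Const:
            def __call__(self, x):
                return x.sum(axis=1) * 0.0 + 3.0

        rng = np.random.default_rng(0)
        gan = build_gan(GANConfig(**SMALL), latent_dim=3)
        gan.eval()
        out = wgan_losses(Const(), gan.generator, rng.normal(size=(6, 3)),
                          gan.sample_z(6), gp_lambda=10.0, rng=rng)
        # E[D] terms cancel; zero gradient means GP = (0-1)^2 = 1
        assert float(out["critic_loss"].data) == pytest.approx(10.0)

    def test_lambda_zero_gives_plain_wasserstein(self):
        rng = np.random.default_rng(0)
        gan = build_gan(GANConfig(**SMALL), latent_dim=3)
        gan.eval()
        real = rng.normal(size=(6, 3))
        z = gan.sample_z(6)
        out = wgan_losses(gan.critic, gan.generator, real, z, gp_lambda=0.0, rng=rng)
        assert float(out["critic_loss"].data) == pytest.approx(-out["wasserstein"])

    def test_hand_computed_two_sample_linear_case(self):
        critic = LinearCritic([1.0, 0.0])  # D(x) = x0
        real = np.array([[1.0, 0.0], [3.0, 0.0]])
        fake = np.array([[0.0, 0.0], [2.0, 0.0]])

        class IdentityGen:
            def __call__(self, z):
                return z

        rng = np.random.default_rng(0)
        out = wgan_losses(critic, IdentityGen(), real, Tensor(fake), gp_lambda=10.0,
                          rng=rng)
        # E[D(fake)] = 1, E[D(real)] = 2, GP = 0 for the unit-norm linear critic
        assert float(out["critic_loss"].data) == pytest.approx(1.0 - 2.0, abs=1e-9)
        assert float(out["generator_loss"].data) == pytest.approx(-1.0)

    def test_lambda_monotonicity(self):
        rng = np.random.default_rng(3)
        critic = LinearCritic([0.6, 0.8], scale=2.0)  # non-unit gradient
        real, fake = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))

        class IdentityGen:
            def __call__(self, z):
                return z

        losses = []
        for lam in (0.0, 1.0, 5.0, 10.0):
            out = wgan_losses(critic, IdentityGen(), real, Tensor(fake), lam,
                              rng=np.random.default_rng(0))
            losses.append(float(out["critic_loss"].data))
        assert losses == sorted(losses) and losses[0] < losses[-1]


class TestTraining:
    def test_empty_dataset_raises(self):
        gan = build_gan(GANConfig(**SMALL), latent_dim=2)
        with pytest.raises(ValueError):
            train_wgan(gan, np.empty((0, 2)))

    def test_seeded_histories_identical(self):
        rng = np.random.default_rng(0)
        lat = rng.normal(size=(120, 2))
        cfg = GANConfig(**{**SMALL, "epochs": 5})
        _, h1 = train_wgan(build_gan(cfg, 2), lat)
        _, h2 = train_wgan(build_gan(cfg, 2), lat)
        assert h1["critic_loss"] == h2["critic_loss"]

    def test_distribution_matching_on_2d_gaussian(self):
        """Generated per-dimension means approach the real means."""
        rng = np.random.default_rng(0)
        lat = rng.normal(loc=[1.5, -2.0], scale=0.5, size=(500, 2))
        cfg = GANConfig(**{**SMALL, "gen_units": (32,), "epochs": 100, "lr": 5e-4})
        gan, hist = train_wgan(build_gan(cfg, 2), lat)
        sample = gan.generate_latents(1000)
        assert np.abs(sample.mean(axis=0) - lat.mean(axis=0)).max() < 0.2
        # the critic's Wasserstein estimate ends below its running peak
        w = np.abs(np.array(hist["wasserstein"]))
        assert np.mean(w[-20:]) < w.max()


class TestSampling:
    def test_always_valid_stub(self):
        gan = build_gan(GANConfig(**SMALL), latent_dim=2)
        records, validity = sample_molecules(gan, lambda lat: ["CC"] * len(lat),
                                             n_valid=10, batch=5)
        assert len(records) == 10 and validity == 1.0
        assert all(isinstance(r, MoleculeRecord) for r in records)

    def test_alternating_stub_half_validity(self):
        gan = build_gan(GANConfig(**SMALL), latent_dim=2)

        def alternating(lat):
            return ["CC" if i % 2 == 0 else "((" for i in range(len(lat))]

        records, validity = sample_molecules(gan, alternating, n_valid=10, batch=20)
        assert len(records) == 10
        assert validity == 0.5

    def test_all_invalid_stub_terminates(self, caplog):
        gan = build_gan(GANConfig(**SMALL), latent_dim=2)
        records, validity = sample_molecules(gan, lambda lat: ["(("] * len(lat),
                                             n_valid=5, max_draws=100, batch=50)
        assert records == [] and validity == 0.0
        assert any("exhausted" in r.message for r in caplog.records)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        from molgen.latent_gan import load_gan, save_gan

        gan = build_gan(GANConfig(**SMALL), latent_dim=5)
        save_gan(gan, tmp_path / "gan")
        loaded = load_gan(tmp_path / "gan")
        z = np.random.default_rng(0).random((4, SMALL["z_dim"]))
        from molgen.autodiff import Tensor, no_grad
        gan.eval(), loaded.eval()
        with no_grad():
            a = gan.generator(Tensor(z)).data
            b = loaded.generator(Tensor(z)).data
        assert np.allclose(a, b)
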