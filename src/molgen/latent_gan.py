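"""Wasserstein GAN with gradient penalty over autoencoder latent vectors.

Training a GAN directly on SMILES strings fails because sampling discrete
tokens is not differentiable; operating on the autoencoder's continuous
context vectors sidesteps this.  Both networks are plain feed-forward stacks:
the critic scores a latent vector, the generator maps a uniform noise vector
``z`` to a synthetic latent vector.  The critic loss is

    E[D(G(z))] - E[D(x)] + lambda * E[(||grad_xhat D(xhat)||_2 - 1)^2]

with ``xhat`` sampled uniformly on the segments joining real and fake batch
members; the penalty pushes the critic toward 1-Lipschitz.  The generator
minimizes ``-E[D(G(z))]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, grad, no_grad
from .chem_data import MoleculeRecord, Origin, is_valid

log = logging.getLogger(__name__)


@dataclass
class GANConfig:
    z_dim: int = 64
    critic_units: tuple = (256, 256, 256)
    gen_units: tuple = (128, 256, 256, 256, 256)
    leaky_alpha: float = 0.3
    bn_momentum: float = 0.9
    lr: float = 0.0001
    dropout: float = 0.2
    gp_lambda: float = 10.0
    n_critic: int = 5
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.z_dim <= 0:
            raise ValueError("z_dim must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be non-negative")


class Critic(nn.Module):
    """Feed-forward critic; a mean over the last (activation-free) dense layer
    reduces it to the per-sample scalar the Wasserstein loss requires."""

    def __init__(self, config: GANConfig, latent_dim: int, rng):
        super().__init__()
        self.alpha = config.leaky_alpha
        units = list(config.critic_units)
        self.hidden = []
        n_in = latent_dim
        for k, u in enumerate(units[:-1]):
            layer = nn.Dense(n_in, u, rng)
            setattr(self, f"dense{k}", layer)
            self.hidden.append(layer)
            n_in = u
        self.final = nn.Dense(n_in, units[-1], rng)
        self.drop = nn.Dropout(config.dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.hidden:
            x = self.drop(layer(x).leaky_relu(self.alpha))
        return self.final(x).mean(axis=1)


class Generator(nn.Module):
    def __init__(self, config: GANConfig, latent_dim: int, rng):
        super().__init__()
        self.alpha = config.leaky_alpha
        self.z_dim = config.z_dim
        self.hidden, self.bns = [], []
        n_in = config.z_dim
        for k, u in enumerate(config.gen_units):
            layer = nn.Dense(n_in, u, rng)
            bn = nn.BatchNorm(u, momentum=config.bn_momentum)
            setattr(self, f"dense{k}", layer)
            setattr(self, f"bn{k}", bn)
            self.hidden.append(layer)
            self.bns.append(bn)
            n_in = u
        self.out = nn.Dense(n_in, latent_dim, rng)
        self.drop = nn.Dropout(config.dropout, rng)

    def __call__(self, z: Tensor) -> Tensor:
        x = z
        for layer, bn in zip(self.hidden, self.bns):
            x = self.drop(bn(layer(x).leaky_relu(self.alpha)))
        return self.out(x)


class LatentGAN(nn.Module):
    def __init__(self, config: GANConfig, latent_dim: int):
        super().__init__()
        if latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        self.config = config
        self.latent_dim = latent_dim
        self.rng = np.random.default_rng(config.seed)
        param_rng = np.random.default_rng(config.seed + 1)
        self.generator = Generator(config, latent_dim, param_rng)
        self.critic = Critic(config, latent_dim, param_rng)

    def sample_z(self, n: int) -> np.ndarray:
        # z ~ U(0,1) per dimension
        return self.rng.random((n, self.config.z_dim))

    def generate_latents(self, n: int) -> np.ndarray:
        """Inference-mode generator samples, shape (n, latent_dim)."""
        was_training = self.training
        self.eval()
        with no_grad():
            out = self.generator(Tensor(self.sample_z(n))).data
        self.train(was_training)
        return out


def build_gan(config: GANConfig, latent_dim: int) -> LatentGAN:
    return LatentGAN(config, latent_dim)


def gradient_penalty(critic, real, fake, eps=None, rng=None) -> Tensor:
    """E[(||grad_xhat D(xhat)||_2 - 1)^2] over per-sample segment interpolates."""
    real = real if isinstance(real, Tensor) else Tensor(real)
    fake = fake if isinstance(fake, Tensor) else Tensor(fake)
    n = real.shape[0]
    if n == 0 or fake.shape[0] != n:
        raise ValueError("real and fake batches must be non-empty and equal-sized")
    if eps is None:
        eps = (rng or np.random.default_rng()).random((n, 1))
    eps = np.asarray(eps, dtype=np.float64).reshape(n, 1)
    xhat = Tensor(eps * fake.data + (1.0 - eps) * real.data, requires_grad=True)
    score = critic(xhat).sum()
    (gx,) = grad(score, [xhat], create_graph=True)
    norms = ((gx ** 2).sum(axis=1) + 1e-24) ** 0.5
    return ((norms - 1.0) ** 2).mean()


def wgan_losses(critic, generator, real, z, gp_lambda: float, rng=None) -> dict:
    """Eq.-style losses: critic E[D(fake)] - E[D(real)] + lambda*GP; generator -E[D(fake)]."""
    real = real if isinstance(real, Tensor) else Tensor(real)
    z = z if isinstance(z, Tensor) else Tensor(z)
    fake = generator(z)
    d_fake = critic(fake).mean()
    d_real = critic(real).mean()
    gp = gradient_penalty(critic, real, fake.detach(), rng=rng)
    return {
        "critic_loss": d_fake - d_real + gp_lambda * gp,
        "generator_loss": -d_fake,
        "wasserstein": float((d_real - d_fake).data),
        "gp": float(gp.data),
    }


def train_wgan(gan: LatentGAN, latents: np.ndarray, config: GANConfig | None = None,
               verbose: bool = False):
    """Adversarial training: `n_critic` critic updates per generator update.

    `latents` are encoder outputs (the GAN's real data). Returns the gan and a
    per-epoch history of critic/generator losses and the Wasserstein estimate.
    """
    cfg = config or gan.config
    latents = np.asarray(latents, dtype=np.float64)
    if latents.ndim != 2 or len(latents) == 0:
        raise ValueError("latents must be a non-empty (n, latent_dim) array")
    if latents.shape[1] != gan.latent_dim:
        raise ValueError("latent dimension mismatch")
    opt_c = nn.Adam(gan.critic.parameters(), lr=cfg.lr)
    opt_g = nn.Adam(gan.generator.parameters(), lr=cfg.lr)
    history = {"critic_loss": [], "generator_loss": [], "wasserstein": []}
    rng = gan.rng
    B = min(cfg.batch_size, len(latents))
    for _ in range(cfg.epochs):
        gan.train()
        ep = train_wgan_epoch(gan, latents, cfg, opt_c, opt_g, rng, B)
        for k in history:
            history[k].append(ep[k])
        if verbose:
            print(
                f"critic {ep['critic_loss']:.4f}  gen {ep['generator_loss']:.4f}"
                f"  W {ep['wasserstein']:.4f}"
            )
    gan.eval()
    return gan, history


def train_wgan_epoch(gan, latents, cfg, opt_c, opt_g, rng, batch_size=None):
    """One pass over the data in batches; per batch, n_critic critic updates
    (each on a fresh real sample) followed by one generator update."""
    B = batch_size or min(cfg.batch_size, len(latents))
    n_steps = max(1, len(latents) // B)
    stats = {"critic_loss": 0.0, "generator_loss": 0.0, "wasserstein": 0.0}
    for _ in range(n_steps):
        for _ in range(cfg.n_critic):
            real = latents[rng.choice(len(latents), B, replace=False)]
            z = gan.sample_z(B)
            with no_grad():
                fake = gan.generator(Tensor(z)).data
            d_fake = gan.critic(Tensor(fake)).mean()
            d_real = gan.critic(Tensor(real)).mean()
            gp = gradient_penalty(gan.critic, real, fake, rng=rng)
            loss_c = d_fake - d_real + cfg.gp_lambda * gp
            opt_c.zero_grad()
            loss_c.backward()
            opt_c.step()
        z = gan.sample_z(B)
        loss_g = -gan.critic(gan.generator(Tensor(z))).mean()
        opt_g.zero_grad()
        loss_g.backward()
        opt_g.step()
        stats["critic_loss"] += float(loss_c.data)
        stats["generator_loss"] += float(loss_g.data)
        stats["wasserstein"] += float((d_real - d_fake).data)
    return {k: v / n_steps for k, v in stats.items()}


def save_gan(gan: LatentGAN, path):
    """Checkpoint: npz weights plus a JSON config sidecar."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    np.savez(path.with_suffix(".npz"), **gan.state_dict())
    sidecar = {"config": asdict(gan.config), "latent_dim": gan.latent_dim}
    sidecar["config"]["critic_units"] = list(gan.config.critic_units)
    sidecar["config"]["gen_units"] = list(gan.config.gen_units)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_gan(path) -> LatentGAN:
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = sidecar["config"]
    cfg["critic_units"] = tuple(cfg["critic_units"])
    cfg["gen_units"] = tuple(cfg["gen_units"])
    gan = LatentGAN(GANConfig(**cfg), sidecar["latent_dim"])
    with np.load(path.with_suffix(".npz")) as f:
        gan.load_state_dict(dict(f))
    gan.eval()
    return gan


def sample_molecules(gan: LatentGAN, decoder, n_valid: int, max_draws: int = 10000,
                     batch: int = 128) -> tuple[list[MoleculeRecord], float]:
    """Draw generator samples and decode until `n_valid` valid molecules.

    `decoder` maps an (n, latent_dim) array to SMILES strings (typically the
    autoencoder's `decode`).  Returns the records (origin=generated) and the
    validity rate of the attempt stream; stops with a warning if `max_draws`
    latents have been decoded first.
    """
    records, n_drawn, n_valid_seen = [], 0, 0
    while len(records) < n_valid and n_drawn < max_draws:
        k = min(batch, max_draws - n_drawn)
        n_drawn += k
        for smi in decoder(gan.generate_latents(k)):
            if is_valid(smi):
                n_valid_seen += 1
                if len(records) < n_valid:
                    rec = MoleculeRecord.from_smiles(smi, origin=Origin.GENERATED)
                    records.append(rec)
    validity = n_valid_seen / max(n_drawn, 1)
    if len(records) < n_valid:
        log.warning(
            "sampling exhausted after %d draws: %d/%d valid molecules",
            n_drawn, len(records), n_valid,
        )
    return records, validity
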