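"""Sequence-to-sequence SMILES autoencoder.

The encoder embeds a tokenized SMILES, runs it through two stacked
bidirectional LSTM layers, concatenates the final hidden and cell states of
the top layer and projects them to a fixed-length context vector; a Gaussian
noise layer (training mode only) regularizes the latent space.  The decoder
maps the context vector through four independent dense layers to the initial
hidden/cell states of two stacked LSTM layers and predicts the token sequence
with a softmax output layer, trained with teacher forcing under categorical
cross-entropy.  Batch normalization (momentum 0.9 by default) sits between
the main layers of both halves.

The context vectors are the "real data" consumed by the latent-space GAN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, concat, no_grad
from .chem_data import Vocabulary, decode_row, encode_dataset


@dataclass
class AutoencoderConfig:
    embed_dim: int = 64  # input embedding width (grid-searched value unavailable)
    rnn_units: int = 512
    latent_dim: int = 256
    noise_std: float = 0.1
    bn_momentum: float = 0.9
    batch_size: int = 128
    lr: float = 0.01
    max_epochs: int = 100
    val_fraction: float = 0.1
    lr_decay: float = 1.0  # multiplicative per-epoch decay
    max_len: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("embed_dim", "rnn_units", "latent_dim", "batch_size", "max_epochs", "max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


class SmilesAutoencoder(nn.Module):
    def __init__(self, config: AutoencoderConfig, vocab: Vocabulary):
        super().__init__()
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        V, E, H, L = len(vocab), config.embed_dim, config.rnn_units, config.latent_dim
        m = config.bn_momentum
        # encoder
        self.embed = nn.Embedding(V, E, rng)
        self.enc_bn0 = nn.BatchNorm(E, momentum=m)
        self.enc_lstm1 = nn.BiLSTMLayer(E, H, rng)
        self.enc_bn1 = nn.BatchNorm(2 * H, momentum=m)
        self.enc_lstm2 = nn.BiLSTMLayer(2 * H, H, rng)
        self.to_latent = nn.Dense(4 * H, L, rng)
        self.latent_bn = nn.BatchNorm(L, momentum=m)
        self.noise = nn.GaussianNoise(config.noise_std, rng)
        # decoder: four independent dense layers build the initial states
        self.state_h1 = nn.Dense(L, H, rng)
        self.state_c1 = nn.Dense(L, H, rng)
        self.state_h2 = nn.Dense(L, H, rng)
        self.state_c2 = nn.Dense(L, H, rng)
        self.dec_embed = nn.Embedding(V, E, rng)
        self.dec_lstm1 = nn.LSTMLayer(E, H, rng)
        self.dec_bn1 = nn.BatchNorm(H, momentum=m)
        self.dec_lstm2 = nn.LSTMLayer(H, H, rng)
        self.dec_bn2 = nn.BatchNorm(H, momentum=m)
        self.out = nn.Dense(H, V, rng)

    # ------------------------------------------------------------------ encode
    @staticmethod
    def _bn_seq(bn, seq, width):
        """Apply a BatchNorm over a stacked (T, B, F) sequence in one call."""
        T, B = seq.shape[0], seq.shape[1]
        return bn(seq.reshape(T * B, width)).reshape(T, B, width)

    def _encode_graph(self, rows: np.ndarray) -> Tensor:
        """Context vectors for an integer-encoded batch (graph-building)."""
        E, H = self.config.embed_dim, self.config.rnn_units
        mask = (rows.T != self.vocab.pad_idx)  # (T, B); freezes state on pads
        emb = self.embed(rows.T)  # (T, B, E)
        xs = self._bn_seq(self.enc_bn0, emb, E)
        h1, _ = self.enc_lstm1(xs, mask=mask)
        h1 = self._bn_seq(self.enc_bn1, h1, 2 * H)
        _, (hf, cf, hb, cb) = self.enc_lstm2(h1, mask=mask)
        # fixed concatenation order: [fwd h, bwd h, fwd c, bwd c]
        states = concat([hf, hb, cf, cb], axis=1)
        z = self.latent_bn(self.to_latent(states))
        return self.noise(z)

    def encode(self, smiles_list: list[str]) -> np.ndarray:
        """Deterministic (inference-mode) context vectors, shape (n, latent_dim)."""
        was_training = self.training
        self.eval()
        rows = encode_dataset(smiles_list, self.vocab, self.config.max_len)
        pad = self.vocab.pad_idx
        lengths = (rows != pad).sum(axis=1)
        # group by length so every batch is pad-free: the encoder then sees
        # each molecule exactly as the training path (which trims batch-wise)
        order = np.argsort(lengths, kind="stable")
        out = np.empty((len(rows), self.config.latent_dim))
        with no_grad():
            B = max(self.config.batch_size, 1)
            for i in range(0, len(order), B):
                sel = order[i : i + B]
                T = int(lengths[sel].max())
                out[sel] = self._encode_graph(rows[sel][:, :T]).data
        self.train(was_training)
        return out

    # ------------------------------------------------------------------ decode
    def _init_states(self, z: Tensor):
        return (
            (self.state_h1(z).tanh(), self.state_c1(z).tanh()),
            (self.state_h2(z).tanh(), self.state_c2(z).tanh()),
        )

    def _decoder_step(self, tok_idx, states):
        (h1, c1), (h2, c2) = states
        x = self.dec_embed(tok_idx)
        h1, c1 = self.dec_lstm1.cell(x, h1, c1)
        y = self.dec_bn1(h1)
        h2, c2 = self.dec_lstm2.cell(y, h2, c2)
        y = self.dec_bn2(h2)
        logits = self.out(y)
        return logits, ((h1, c1), (h2, c2))

    def decode(self, latents: np.ndarray, mode: str = "greedy", temperature: float = 1.0,
               rng: np.random.Generator | None = None) -> list[str]:
        """Autoregressive decoding from context vectors to SMILES strings.

        Runs from the start token until the end token or `max_len`. `greedy`
        takes the argmax at every step; `sample` draws from the softmax at the
        given temperature (temperature 0 falls back to greedy).
        """
        latents = np.asarray(latents, dtype=np.float64)
        if latents.ndim == 1:
            latents = latents[None, :]
        if latents.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent vectors have length {latents.shape[1]}, expected {self.config.latent_dim}"
            )
        if mode == "sample" and temperature == 0.0:
            mode = "greedy"
        if rng is None:
            rng = self.rng
        was_training = self.training
        self.eval()
        vocab = self.vocab
        n = latents.shape[0]
        with no_grad():
            states = self._init_states(Tensor(latents))
            tok = np.full(n, vocab.start_idx, dtype=np.int64)
            done = np.zeros(n, dtype=bool)
            seqs = np.full((n, self.config.max_len), vocab.pad_idx, dtype=np.int64)
            for t in range(self.config.max_len):
                logits, states = self._decoder_step(tok, states)
                ld = logits.data
                if mode == "greedy":
                    nxt = ld.argmax(axis=1)
                else:
                    scaled = ld / max(temperature, 1e-8)
                    scaled -= scaled.max(axis=1, keepdims=True)
                    p = np.exp(scaled)
                    p /= p.sum(axis=1, keepdims=True)
                    nxt = np.array([rng.choice(len(vocab), p=pi) for pi in p])
                nxt = np.where(done, vocab.pad_idx, nxt)
                seqs[:, t] = nxt
                done |= nxt == vocab.end_idx
                if done.all():
                    break
                tok = nxt
        self.train(was_training)
        return [decode_row(seq, vocab) for seq in seqs]

    # ------------------------------------------------------------------ loss
    def batch_loss(self, rows: np.ndarray) -> Tensor:
        """Teacher-forced cross-entropy on one encoded batch."""
        pad = self.vocab.pad_idx
        # trim trailing all-pad timesteps
        T = int((rows != pad).any(axis=0).sum()) + 1
        rows = rows[:, :T]
        B = rows.shape[0]
        H = self.config.rnn_units
        z = self._encode_graph(rows)
        (h1, c1), (h2, c2) = self._init_states(z)
        emb = self.dec_embed(rows[:, :-1].T)  # (T-1, B, E)
        outs1, _ = self.dec_lstm1(emb, init_state=(h1, c1))
        outs1 = self._bn_seq(self.dec_bn1, outs1, H)
        outs2, _ = self.dec_lstm2(outs1, init_state=(h2, c2))
        flat = self.dec_bn2(outs2.reshape((T - 1) * B, H))
        logits = self.out(flat)  # ((T-1)*B, V)
        targets = rows[:, 1:].T.reshape(-1)
        mask = (targets != pad).astype(np.float64)
        return nn.cross_entropy_logits(logits, targets, mask)


def train_autoencoder(model: SmilesAutoencoder, corpus: list[str],
                      config: AutoencoderConfig | None = None, verbose: bool = False):
    """Train with teacher forcing; keep the best-validation-loss checkpoint.

    Returns ``(model, history)`` where history has per-epoch train/val loss.
    The validation split is a seeded random fraction at the molecule level.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    cfg = config or model.config
    rows = encode_dataset(corpus, model.vocab, cfg.max_len)
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(rows))
    n_val = max(1, int(round(cfg.val_fraction * len(rows))))
    val_rows, train_rows = rows[perm[:n_val]], rows[perm[n_val:]]
    if len(train_rows) == 0:
        raise ValueError("corpus too small for the requested validation fraction")
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state = np.inf, None
    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.lr * cfg.lr_decay ** epoch
        model.train()
        order = rng.permutation(len(train_rows))
        ep_loss, n_seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            batch = train_rows[order[i : i + cfg.batch_size]]
            loss = model.batch_loss(batch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(batch)
            n_seen += len(batch)
        model.eval()
        with no_grad():
            val_loss = 0.0
            for i in range(0, len(val_rows), cfg.batch_size):
                batch = val_rows[i : i + cfg.batch_size]
                val_loss += float(model.batch_loss(batch).data) * len(batch)
            val_loss /= len(val_rows)
        history["train_loss"].append(ep_loss / n_seen)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch + 1}: train {ep_loss / n_seen:.4f}  val {val_loss:.4f}")
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def reconstruction_report(model: SmilesAutoencoder, smiles_list: list[str]) -> dict:
    """Correct-reconstruction and validity percentages for a dataset.

    CR% counts decoded canonical SMILES identical to the input; validity%
    counts decoded strings that parse at all, so CR% <= validity% always.
    """
    from .chem_data import canonicalize, is_valid

    latents = model.encode(smiles_list)
    decoded = model.decode(latents, mode="greedy")
    n = len(smiles_list)
    n_valid, n_correct = 0, 0
    for inp, out in zip(smiles_list, decoded):
        if is_valid(out):
            n_valid += 1
            if canonicalize(out) == canonicalize(inp):
                n_correct += 1
    return {"cr_pct": 100.0 * n_correct / n, "validity_pct": 100.0 * n_valid / n}


def save_autoencoder(model: SmilesAutoencoder, path):
    """Checkpoint: npz weights plus a JSON sidecar with config + vocabulary."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {"config": asdict(model.config), "vocab_tokens": list(model.vocab.tokens)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_autoencoder(path) -> SmilesAutoencoder:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    vocab = Vocabulary.from_tokens(sidecar["vocab_tokens"])
    model = SmilesAutoencoder(AutoencoderConfig(**sidecar["config"]), vocab)
    with np.load(path.with_suffix(".npz")) as f:
        model.load_state_dict(dict(f))
    model.eval()
    return model
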