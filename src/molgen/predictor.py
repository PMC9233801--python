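"""Recurrent QSAR regressor: tokenized SMILES -> predicted pIC50.

Embedding, two LSTM layers and a dense layer (128 units each by default) with
a single linear output unit.  Trained with Adam (beta1=0.9, beta2=0.999),
early stopping on validation MSE, and k validation splits with one
independently trained model per split; reported metrics are the mean and
standard deviation across splits.

Reported metrics: mean squared error (MSE), coefficient of determination
(CD, the usual R^2), Lin's concordance correlation coefficient (CCC) and the
Matthews correlation coefficient (MCC) after binarizing activities at a
pIC50 threshold (default: the median training label — a regression model
reports MCC only relative to some active/inactive cut).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import matthews_corrcoef, mean_squared_error, r2_score

from . import nn
from .autodiff import Tensor, no_grad
from .chem_data import Vocabulary, tokenize


@dataclass
class PredictorConfig:
    embed_dim: int = 128
    rnn_units: int = 128
    dense_units: int = 128
    lr: float = 0.0001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 16
    max_epochs: int = 100
    early_stopping_patience: int = 10
    n_splits: int = 5
    char_level: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("embed_dim", "rnn_units", "dense_units", "batch_size",
                     "max_epochs", "n_splits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1/beta2 must be in (0, 1)")


class ActivityPredictor(nn.Module):
    def __init__(self, config: PredictorConfig, vocab: Vocabulary):
        super().__init__()
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        E, H, D = config.embed_dim, config.rnn_units, config.dense_units
        self.embed = nn.Embedding(len(vocab), E, rng)
        self.lstm1 = nn.LSTMLayer(E, H, rng)
        self.lstm2 = nn.LSTMLayer(H, H, rng)
        self.dense = nn.Dense(H, D, rng)
        self.out = nn.Dense(D, 1, rng)

    def _tokenize(self, smiles: str) -> list[str]:
        if self.config.char_level:
            return list(smiles)
        return tokenize(smiles)

    def _encode_batch(self, smiles_list: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Pad a batch to its own max length; returns (rows, lengths)."""
        vocab = self.vocab
        tok_rows = [self._tokenize(s) for s in smiles_list]
        lens = np.array([len(t) + 2 for t in tok_rows])
        T = int(lens.max())
        rows = np.full((len(tok_rows), T), vocab.pad_idx, dtype=np.int64)
        for r, toks in enumerate(tok_rows):
            idx = [vocab.start_idx]
            for t in toks:
                if t not in vocab:
                    raise KeyError(f"token {t!r} not in vocabulary")
                idx.append(vocab.index_of[t])
            idx.append(vocab.end_idx)
            rows[r, : len(idx)] = idx
        return rows, lens

    def _forward(self, rows: np.ndarray, lens: np.ndarray) -> Tensor:
        emb = self.embed(rows.T)  # (T, B, E)
        outs1, _ = self.lstm1(emb)
        outs2, _ = self.lstm2(outs1)
        # final state of each (variable-length) sequence
        last = outs2[lens - 1, np.arange(rows.shape[0])]
        hidden = self.dense(last).leaky_relu(0.0)  # plain ReLU
        return self.out(hidden).reshape(-1)

    def predict(self, smiles_list: list[str], batch: int = 256) -> np.ndarray:
        was_training = self.training
        self.eval()
        preds = []
        with no_grad():
            for i in range(0, len(smiles_list), batch):
                rows, lens = self._encode_batch(smiles_list[i : i + batch])
                preds.append(self._forward(rows, lens).data)
        self.train(was_training)
        return np.concatenate(preds) if preds else np.empty(0)

    def __call__(self, smiles_list: list[str]) -> np.ndarray:
        return self.predict(smiles_list)


def build_predictor(config: PredictorConfig, vocab: Vocabulary) -> ActivityPredictor:
    return ActivityPredictor(config, vocab)


def regression_metrics(y_true, y_pred, activity_threshold: float | None = None) -> dict:
    """MSE, CD (R^2), Lin's CCC, and MCC at an activity threshold.

    CCC = 2*cov(y, yhat) / (var y + var yhat + (mean y - mean yhat)^2), with
    population (ddof=0) moments.  MCC binarizes both vectors at the threshold
    (default: median of y_true).
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y.size < 2:
        raise ValueError("need at least two observations")
    vy, vp = y.var(), p.var()
    denom = vy + vp + (y.mean() - p.mean()) ** 2
    if denom == 0:
        raise ZeroDivisionError("CCC undefined: both vectors are identical constants")
    ccc = 2.0 * ((y - y.mean()) * (p - p.mean())).mean() / denom
    thr = float(np.median(y)) if activity_threshold is None else float(activity_threshold)
    ya, pa = (y > thr).astype(int), (p > thr).astype(int)
    return {
        "mse": float(mean_squared_error(y, p)),
        "cd": float(r2_score(y, p)),
        "ccc": float(ccc),
        "mcc": float(matthews_corrcoef(ya, pa)),
        "threshold": thr,
    }


def _train_single(model: ActivityPredictor, train_pairs, val_pairs, cfg, rng):
    opt = nn.Adam(model.parameters(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    best_val, best_state, patience = np.inf, None, 0
    stopped_epoch = cfg.max_epochs
    xs = [s for s, _ in train_pairs]
    ys = np.array([y for _, y in train_pairs])
    val_x = [s for s, _ in val_pairs]
    val_y = np.array([y for _, y in val_pairs])
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(len(xs))
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            rows, lens = model._encode_batch([xs[j] for j in sel])
            pred = model._forward(rows, lens)
            loss = ((pred - Tensor(ys[sel])) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_mse = float(np.mean((model.predict(val_x) - val_y) ** 2))
        if val_mse < best_val - 1e-9:
            best_val, best_state, patience = val_mse, model.state_dict(), 0
        else:
            patience += 1
            if patience >= cfg.early_stopping_patience:
                stopped_epoch = epoch + 1
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, stopped_epoch


class PredictorEnsemble:
    """One model per validation split; predictions are the split-model mean."""

    def __init__(self, models, report):
        self.models = models
        self.report = report

    def predict(self, smiles_list) -> np.ndarray:
        return np.mean([m.predict(smiles_list) for m in self.models], axis=0)

    __call__ = predict


def train_predictor(labeled_pairs, vocab: Vocabulary, config: PredictorConfig,
                    activity_threshold: float | None = None) -> PredictorEnsemble:
    """k-split cross-validated training; returns ensemble plus metric report.

    The report holds the per-split validation metrics (mean and std across
    splits) and the epoch each split stopped at.
    """
    cfg = config
    if len(labeled_pairs) < 2 * cfg.n_splits:
        raise ValueError(
            f"need at least {2 * cfg.n_splits} labeled molecules for {cfg.n_splits} splits"
        )
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(labeled_pairs))
    folds = np.array_split(perm, cfg.n_splits)
    if activity_threshold is None:
        activity_threshold = float(np.median([y for _, y in labeled_pairs]))
    models, split_metrics, stop_epochs = [], [], []
    for k, fold in enumerate(folds):
        val_idx = set(fold.tolist())
        train_pairs = [labeled_pairs[i] for i in perm if i not in val_idx]
        val_pairs = [labeled_pairs[i] for i in fold]
        model = ActivityPredictor(
            PredictorConfig(**{**cfg.__dict__, "seed": cfg.seed + k}), vocab
        )
        model, stopped = _train_single(model, train_pairs, val_pairs, cfg, rng)
        pred = model.predict([s for s, _ in val_pairs])
        split_metrics.append(
            regression_metrics([y for _, y in val_pairs], pred, activity_threshold)
        )
        stop_epochs.append(stopped)
        models.append(model)
    report = {}
    for key in ("mse", "cd", "ccc", "mcc"):
        vals = np.array([m[key] for m in split_metrics])
        report[key] = float(vals.mean())
        report[key + "_std"] = float(vals.std())
    report["stopped_epochs"] = stop_epochs
    report["threshold"] = activity_threshold
    return PredictorEnsemble(models, report)
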