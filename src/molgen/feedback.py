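"""The feedback-GAN optimization loop.

After the WGAN-GP has learned the unbiased latent distribution, the loop
retrains it while editing its "real data" pool: each epoch a fixed number of
valid molecules is sampled from the generator, scored under a multi-objective
score vector, and the Pareto-best `n = replace_fraction * sample_per_epoch`
of them replace the worst-ranked pool members.  The pool latents of inserted
molecules come from re-encoding their SMILES with the autoencoder, so the
pool stays on the encoder manifold.  Slowly, the learned distribution drifts
toward the desired property region.

Also provides the pool sub-sampling strategies used for sensitivity analysis:
Random, and the two internal-diversity extremes (Tani-Inf: most dissimilar
molecules; Tani-Sup: most similar), all stratified on activity so the sampled
label histogram tracks the original.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import DataStructs

from . import nn
from .chem_data import MoleculeRecord, Origin, canonicalize
from .evaluation import external_diversity, fingerprints, internal_diversity
from .latent_gan import LatentGAN, sample_molecules, train_wgan_epoch
from .objectives import ObjectiveSet, ScoreVector, rank_population, score_vector, select_best

log = logging.getLogger(__name__)


@dataclass
class FeedbackConfig:
    epochs: int = 500
    sample_per_epoch: int = 200
    replace_fraction: float = 0.10
    eval_interval: int = 50
    eval_sample: int = 1000
    max_draw_factor: int = 20  # sampling gives up after factor * n_valid draws
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.replace_fraction <= 1.0:
            raise ValueError("replace_fraction must be in [0, 1]")
        if self.sample_per_epoch <= 0 or self.eval_sample <= 0:
            raise ValueError("sample sizes must be positive")


@dataclass
class TrainingPool:
    """Fixed-capacity set of scored molecules backing the GAN's real data."""

    records: list[MoleculeRecord]
    latents: np.ndarray  # (capacity, latent_dim)
    scores: list[ScoreVector]
    capacity: int = 5000

    def __post_init__(self):
        if len(self.records) != self.capacity or len(self.latents) != self.capacity:
            raise ValueError("pool must hold exactly `capacity` records")

    def __len__(self):
        return len(self.records)


def _stratified_indices(values: np.ndarray, n: int, n_bins: int, rng,
                        pick=None) -> np.ndarray:
    """Choose n indices whose `values` histogram tracks the full distribution.

    Proportional (largest-remainder) allocation over equal-width bins; within
    a bin, `pick(indices, k)` selects (default: seeded uniform)."""
    edges = np.histogram_bin_edges(values, bins=n_bins)
    which = np.clip(np.digitize(values, edges[1:-1]), 0, n_bins - 1)
    quota = np.array([(which == b).sum() for b in range(n_bins)], dtype=float)
    exact = quota / quota.sum() * n
    alloc = np.floor(exact).astype(int)
    remainder = exact - alloc
    for b in np.argsort(-remainder)[: n - alloc.sum()]:
        alloc[b] += 1
    chosen = []
    for b in range(n_bins):
        idx = np.where(which == b)[0]
        k = min(alloc[b], len(idx))
        if k == 0:
            continue
        if pick is None:
            chosen.append(rng.choice(idx, size=k, replace=False))
        else:
            chosen.append(pick(idx, k))
    out = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
    # top up from anywhere if rounding starved some bins
    if len(out) < n:
        rest = np.setdiff1d(np.arange(len(values)), out)
        out = np.concatenate([out, rng.choice(rest, size=n - len(out), replace=False)])
    return out[:n]


def init_pool(records: list[MoleculeRecord], encoder_fn, scorer, objective_set: ObjectiveSet,
              capacity: int = 5000, n_bins: int = 10, seed: int = 0) -> TrainingPool:
    """Seeded activity-stratified pool preserving the source pIC50 histogram.

    `encoder_fn` maps a SMILES list to latent vectors; `scorer` maps a record
    to its activity (predictor or surrogate).
    """
    if len(records) < capacity:
        raise ValueError(f"dataset of {len(records)} is smaller than capacity {capacity}")
    rng = np.random.default_rng(seed)
    activities = np.array([float(scorer(r)) for r in records])
    if len(records) == capacity:
        idx = np.arange(capacity)
    else:
        idx = _stratified_indices(activities, capacity, n_bins, rng)
    chosen = [records[i] for i in idx]
    for r, a in zip(chosen, activities[idx]):
        r.properties["pIC50"] = float(a)
    latents = encoder_fn([r.smiles for r in chosen])
    scores = [score_vector(r, objective_set, scorer) for r in chosen]
    return TrainingPool(records=chosen, latents=np.asarray(latents), scores=scores,
                        capacity=capacity)


def sample_by_diversity(records: list[MoleculeRecord], n: int, mode: str = "Random",
                        activities=None, n_bins: int = 10, seed: int = 0):
    """Activity-stratified subsets: Random, Tani-Inf (most dissimilar first)
    or Tani-Sup (most similar first).

    A molecule's dissimilarity is its mean Tanimoto distance to the rest of
    the dataset — its contribution to the internal diversity.
    """
    if n > len(records):
        raise ValueError("n exceeds the dataset size")
    rng = np.random.default_rng(seed)
    if activities is None:
        activities = [r.properties.get("pIC50", 0.0) for r in records]
    activities = np.asarray(activities, dtype=float)
    if mode == "Random":
        pick = None
    elif mode in ("Tani-Inf", "Tani-Sup"):
        fps = fingerprints([r.smiles for r in records])
        m = len(fps)
        mean_dist = np.empty(m)
        for i, f in enumerate(fps):
            sims = np.array(DataStructs.BulkTanimotoSimilarity(f, fps))
            mean_dist[i] = 1.0 - (sims.sum() - 1.0) / max(m - 1, 1)
        order_sign = -1.0 if mode == "Tani-Inf" else 1.0

        def pick(idx, k):
            return idx[np.argsort(order_sign * mean_dist[idx], kind="stable")[:k]]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    idx = _stratified_indices(activities, n, n_bins, rng, pick=pick)
    return [records[i] for i in idx]


def _pool_worst(pool: TrainingPool, n: int) -> list[int]:
    """Indices of the n worst-ranked pool members (highest domination count,
    ties by ascending first objective — the reverse of the selection order)."""
    ranking = rank_population(pool.scores)
    vals = np.array([s.values for s in pool.scores])
    order = sorted(
        range(len(pool)),
        key=lambda i: (-ranking.domination_count[i], tuple(vals[i])),
    )
    return order[:n]


def feedback_epoch(gan: LatentGAN, autoencoder, pool: TrainingPool, scorer,
                   objective_set: ObjectiveSet, config: FeedbackConfig,
                   opt_c, opt_g) -> dict:
    """One optimization epoch: sample, score, replace, retrain. Pool size conserved."""
    n_replace = int(round(config.replace_fraction * config.sample_per_epoch))
    stats = {"n_replaced": 0, "sample_validity": 1.0}
    if n_replace > 0:
        generated, validity = sample_molecules(
            gan, autoencoder.decode, config.sample_per_epoch,
            max_draws=config.max_draw_factor * config.sample_per_epoch,
        )
        stats["sample_validity"] = validity
        if len(generated) < config.sample_per_epoch:
            log.warning("epoch proceeded with %d/%d valid molecules",
                        len(generated), config.sample_per_epoch)
        if generated:
            # duplicates would fill several pool slots with one molecule
            seen, unique = set(), []
            for r in generated:
                if r.smiles not in seen:
                    seen.add(r.smiles)
                    unique.append(r)
            generated = unique
            gen_scores = [score_vector(r, objective_set, scorer) for r in generated]
            k = min(n_replace, len(generated))
            best = select_best(gen_scores, k)
            worst = _pool_worst(pool, k)
            new_records = [generated[i] for i in best]
            new_latents = autoencoder.encode([r.smiles for r in new_records])
            for slot, j in zip(worst, range(k)):
                pool.records[slot] = new_records[j]
                pool.scores[slot] = gen_scores[best[j]]
                pool.latents[slot] = new_latents[j]
            stats["n_replaced"] = k
    train_stats = train_wgan_epoch(gan, pool.latents, gan.config, opt_c, opt_g, gan.rng)
    stats.update(train_stats)
    return stats


def _checkpoint_row(epoch, gan, autoencoder, pool, scorer, objective_set, config,
                    reference_smiles) -> dict:
    molecules, validity = sample_molecules(
        gan, autoencoder.decode, config.eval_sample,
        max_draws=config.max_draw_factor * config.eval_sample,
    )
    row = {"epoch": epoch, "pct_valid": 100.0 * validity}
    if not molecules:
        log.warning("checkpoint %d: no valid molecules sampled", epoch)
        return {**row, "pct_unique": 0.0}
    smis = [r.smiles for r in molecules]
    primary = objective_set.components[0][0]
    vals = []
    for r in molecules:
        if primary == "pIC50":
            vals.append(float(scorer(r)))
        else:
            vals.append(float(score_vector(r, objective_set, scorer).values[0]
                              * objective_set.components[0][1]))
    vals = np.array(vals)
    uniq = {canonicalize(s) for s in smis}
    row.update({
        "pct_unique": 100.0 * len(uniq) / len(smis),
        f"max_{primary}": float(vals.max()),
        f"mean_{primary}": float(vals.mean()),
        f"min_{primary}": float(vals.min()),
        "int_div": internal_diversity(smis),
        "ext_div": external_diversity(smis, reference_smiles),
    })
    return row


def run_optimization(gan: LatentGAN, autoencoder, pool: TrainingPool, scorer,
                     objective_set: ObjectiveSet, config: FeedbackConfig,
                     verbose: bool = False):
    """Full feedback loop; returns the gan and the optimization trace.

    The trace (one row at epoch 0 — the unbiased model — and one per
    `eval_interval`) records the sampled objective distribution (max/mean/min),
    validity, uniqueness and internal/external diversity: the machine-readable
    account of how the generated distribution shifts during optimization.
    """
    opt_c = nn.Adam(gan.critic.parameters(), lr=gan.config.lr)
    opt_g = nn.Adam(gan.generator.parameters(), lr=gan.config.lr)
    reference = [r.smiles for r in pool.records]
    rows = [_checkpoint_row(0, gan, autoencoder, pool, scorer, objective_set,
                            config, reference)]
    if verbose:
        print(f"epoch 0 (unbiased): {rows[-1]}")
    for epoch in range(1, config.epochs + 1):
        feedback_epoch(gan, autoencoder, pool, scorer, objective_set, config,
                       opt_c, opt_g)
        assert len(pool) == pool.capacity
        if epoch % config.eval_interval == 0 or epoch == config.epochs:
            rows.append(_checkpoint_row(epoch, gan, autoencoder, pool, scorer,
                                        objective_set, config, reference))
            if verbose:
                print(f"epoch {epoch}: {rows[-1]}")
    trace = pd.DataFrame(rows).drop_duplicates(subset="epoch").reset_index(drop=True)
    return gan, trace
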