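"""Feedback-loop mechanics: pool construction, diversity sampling, replacement."""

import numpy as np
import pytest

from molgen import chem_data as cd
from molgen import nn
from molgen.feedback import (FeedbackConfig, TrainingPool, _pool_worst,
                             feedback_epoch, init_pool, sample_by_diversity)
from molgen.latent_gan import GANConfig, build_gan
from molgen.objectives import ObjectiveSet, ScoreVector, score_vector

LATENT_DIM = 8
SINGLEISH = ObjectiveSet("surrogate2", (("pIC50", +1), ("pIC50", +1)))


class StubAutoencoder:
    """Decodes latents to a canned SMILES stream; encodes to seeded vectors."""

    def __init__(self, stream):
        self.stream = list(stream)
        self.pos = 0
        self.rng = np.random.default_rng(0)

    def decode(self, latents, **kw):
        out = []
        for _ in range(len(latents)):
            out.append(self.stream[self.pos % len(self.stream)])
            self.pos += 1
        return out

    def encode(self, smiles_list):
        return self.rng.normal(size=(len(smiles_list), LATENT_DIM))


def make_records(n, seed=0):
    cfg = cd.ToyLibraryConfig(n_molecules=n, seed=seed, max_heavy_atoms=9,
                              allow_stereo=False)
    return cd.generate_toy_library(cfg)


def make_pool(records, capacity, seed=0):
    enc = StubAutoencoder([])
    return init_pool(records, enc.encode, cd.surrogate_activity, SINGLEISH,
                     capacity=capacity, seed=seed)


def tiny_gan(seed=0):
    cfg = GANConfig(z_dim=4, critic_units=(8, 8, 8), gen_units=(8, 8), dropout=0.0,
                    batch_size=16, n_critic=2, seed=seed)
    return build_gan(cfg, LATENT_DIM)


class TestInitPool:
    def test_capacity_equals_dataset(self):
        records = make_records(40)
        pool = make_pool(records, 40)
        assert len(pool) == 40
        assert {r.smiles for r in pool.records} == {r.smiles for r in records}

    def test_too_small_dataset_raises(self):
        with pytest.raises(ValueError):
            make_pool(make_records(10), 20)

    def test_same_seed_same_pool(self):
        records = make_records(60)
        a = make_pool(records, 30, seed=4)
        b = make_pool(records, 30, seed=4)
        assert [r.smiles for r in a.records] == [r.smiles for r in b.records]

    def test_stratification_tracks_bimodal_distribution(self):
        """Per-bin allocation within +/-2 molecules of proportionality."""
        rng = np.random.default_rng(0)
        records = make_records(200)
        lo = rng.normal(4.5, 0.1, size=100)
        hi = rng.normal(9.0, 0.1, size=100)
        fake_activity = dict(zip([r.smiles for r in records],
                                 np.concatenate([lo, hi])))
        enc = StubAutoencoder([])
        pool = init_pool(records, enc.encode,
                         lambda r: fake_activity[r.smiles], SINGLEISH,
                         capacity=100, n_bins=2, seed=0)
        acts = np.array([fake_activity[r.smiles] for r in pool.records])
        assert abs((acts < 6.0).sum() - 50) <= 2
        assert abs((acts > 6.0).sum() - 50) <= 2


class TestDiversitySampling:
    def test_outlier_found_by_tani_inf(self):
        near_dups = ["CCCCCCCC", "CCCCCCCCC", "CCCCCCCCCC", "CCCCCCCCCCC"]
        outlier = "O=[N+]([O-])c1ccccc1"
        records = [cd.MoleculeRecord.from_smiles(s) for s in near_dups + [outlier]]
        picked = sample_by_diversity(records, 1, mode="Tani-Inf", n_bins=1)
        assert picked[0].smiles == cd.canonicalize(outlier)

    def test_tani_sup_picks_a_near_duplicate(self):
        near_dups = ["CCCCCCCC", "CCCCCCCCC", "CCCCCCCCCC", "CCCCCCCCCCC"]
        outlier = "O=[N+]([O-])c1ccccc1"
        records = [cd.MoleculeRecord.from_smiles(s) for s in near_dups + [outlier]]
        picked = sample_by_diversity(records, 1, mode="Tani-Sup", n_bins=1)
        assert picked[0].smiles in {cd.canonicalize(s) for s in near_dups}

    def test_random_reproducible(self):
        records = make_records(50)
        a = sample_by_diversity(records, 10, mode="Random", seed=3)
        b = sample_by_diversity(records, 10, mode="Random", seed=3)
        assert [r.smiles for r in a] == [r.smiles for r in b]

    def test_n_too_large_and_bad_mode(self):
        records = make_records(10)
        with pytest.raises(ValueError):
            sample_by_diversity(records, 11)
        with pytest.raises(ValueError):
            sample_by_diversity(records, 2, mode="nope")


class TestFeedbackEpoch:
    def _setup(self, pool_n=12, stream=None):
        records = make_records(pool_n)
        pool = make_pool(records, pool_n)
        gan = tiny_gan()
        ae = StubAutoencoder(stream or [r.smiles for r in make_records(40, seed=9)])
        opt_c = nn.Adam(gan.critic.parameters(), lr=1e-4)
        opt_g = nn.Adam(gan.generator.parameters(), lr=1e-4)
        return pool, gan, ae, opt_c, opt_g

    def test_pool_size_conserved_and_worst_removed(self):
        pool, gan, ae, oc, og = self._setup()
        before = sorted(s.values[0] for s in pool.scores)
        cfg = FeedbackConfig(epochs=1, sample_per_epoch=20, replace_fraction=0.1,
                             eval_interval=1, eval_sample=5)
        stats = feedback_epoch(gan, ae, pool, cd.surrogate_activity, SINGLEISH,
                               cfg, oc, og)
        assert len(pool) == pool.capacity
        assert stats["n_replaced"] == 2
        after = sorted(s.values[0] for s in pool.scores)
        # single-objective: the pool minimum never decreases
        assert after[0] >= before[0]

    def test_replace_fraction_zero_keeps_pool(self):
        pool, gan, ae, oc, og = self._setup()
        smiles_before = [r.smiles for r in pool.records]
        cfg = FeedbackConfig(epochs=1, sample_per_epoch=20, replace_fraction=0.0,
                             eval_interval=1, eval_sample=5)
        stats = feedback_epoch(gan, ae, pool, cd.surrogate_activity, SINGLEISH,
                               cfg, oc, og)
        assert [r.smiles for r in pool.records] == smiles_before
        assert stats["n_replaced"] == 0
        assert "critic_loss" in stats  # adversarial training still ran

    def test_dominating_generated_molecules_enter_pool(self):
        """Two strictly dominating molecules displace the two worst members."""
        pool, gan, ae, oc, og = self._setup(pool_n=10)
        strong_a = cd.MoleculeRecord.from_smiles("CCO")
        strong_b = cd.MoleculeRecord.from_smiles("CCN")
        # inflate their activity far above anything the surrogate produces
        boosted = {strong_a.smiles: 99.0, strong_b.smiles: 98.0}

        def scorer(rec):
            return boosted.get(rec.smiles, cd.surrogate_activity(rec))

        pool.scores = [score_vector(r, SINGLEISH, scorer) for r in pool.records]
        worst_two = {pool.records[i].smiles for i in _pool_worst(pool, 2)}
        ae.stream = [strong_a.smiles, strong_b.smiles]
        cfg = FeedbackConfig(epochs=1, sample_per_epoch=20, replace_fraction=0.1,
                             eval_interval=1, eval_sample=5)
        feedback_epoch(gan, ae, pool, scorer, SINGLEISH, cfg, oc, og)
        smiles_now = {r.smiles for r in pool.records}
        assert {strong_a.smiles, strong_b.smiles} <= smiles_now
        assert worst_two & smiles_now == set()
        assert len(pool) == 10

    def test_exact_replacement_count_200_at_10pct(self):
        pool, gan, ae, oc, og = self._setup(pool_n=30)
        cfg = FeedbackConfig(epochs=1, sample_per_epoch=200, replace_fraction=0.10,
                             eval_interval=1, eval_sample=5)
        stats = feedback_epoch(gan, ae, pool, cd.surrogate_activity, SINGLEISH,
                               cfg, oc, og)
        assert stats["n_replaced"] == 20


class TestConfig:
    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            FeedbackConfig(replace_fraction=1.5)
        with pytest.raises(ValueError):
            FeedbackConfig(sample_per_epoch=0)

    def test_pool_invariant(self):
        with pytest.raises(ValueError):
            TrainingPool(records=[], latents=np.empty((0, 2)), scores=[], capacity=3)
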