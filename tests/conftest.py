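"""Shared fixtures: toy molecule corpora and (session-scoped) trained models.

The trained autoencoder and the downstream feedback-loop runs are expensive,
so they are built once per session and shared across the tests that need
them.  All randomness is seeded.
"""

import numpy as np
import pytest

from molgen import chem_data as cd
from molgen.autoencoder import AutoencoderConfig, SmilesAutoencoder, train_autoencoder

# the small-grammar study conditions for the desk-scale reconstruction runs
TOY_ELEMENTS = ("C", "C", "C", "C", "N", "O", "F")
AE_SEED = 0


@pytest.fixture(scope="session")
def toy_corpus():
    """2200 distinct small molecules over a 10-token linear/branched grammar
    (2000 train + 200 held out), token length <= 20."""
    cfg = cd.ToyLibraryConfig(
        n_molecules=2200, seed=11, max_heavy_atoms=8, allow_stereo=False,
        elements=TOY_ELEMENTS, max_rings=0,
    )
    return [r.smiles for r in cd.generate_toy_library(cfg)]


@pytest.fixture(scope="session")
def stereo_corpus():
    """Molecules with stereocenters and charges for tokenizer round-trips."""
    cfg = cd.ToyLibraryConfig(
        n_molecules=300, seed=23, max_heavy_atoms=12, allow_stereo=True,
        allow_charge=True,
    )
    return [r.smiles for r in cd.generate_toy_library(cfg)]


@pytest.fixture(scope="session")
def toy_vocab(toy_corpus):
    return cd.build_vocabulary(toy_corpus)


@pytest.fixture(scope="session")
def trained_ae(toy_corpus, toy_vocab):
    """Autoencoder trained on the 2000-molecule toy corpus (reduced widths)."""
    cfg = AutoencoderConfig(
        embed_dim=32, rnn_units=64, latent_dim=32, batch_size=64,
        lr=0.004, lr_decay=0.97, max_epochs=60, max_len=24, seed=AE_SEED,
    )
    model = SmilesAutoencoder(cfg, toy_vocab)
    model, _ = train_autoencoder(model, toy_corpus[:2000])
    return model


@pytest.fixture(scope="session")
def toy_heldout(toy_corpus):
    return toy_corpus[2000:]
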