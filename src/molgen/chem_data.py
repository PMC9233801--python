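"""SMILES handling: canonicalization, stereochemistry-aware tokenization,
vocabulary construction, integer encoding, dataset I/O and the seeded toy
molecule generator with its deterministic surrogate-activity oracle.

Tokenization keeps every bracketed atom environment (``[C@@H]``, ``[N+]``,
``[NH3+]`` ...) as a single token so that chirality and charge survive the
round trip through the sequence models, instead of being split into
meaningless characters.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

PAD, START, END = "<pad>", "G", "A"

# bracket environments and two-character lexemes must win over single chars
_TOKEN_RE = re.compile(r"(\[[^\]]*\]|%\d{2}|Cl|Br|.)")


class SmilesError(ValueError):
    """Raised for SMILES that cannot be parsed or tokenized; carries the string."""

    def __init__(self, smiles: str, reason: str = "cannot be parsed"):
        self.smiles = smiles
        super().__init__(f"SMILES {smiles!r} {reason}")


def canonicalize(smiles: str) -> str:
    """Toolkit-canonical SMILES, stereo descriptors preserved. Idempotent."""
    if not smiles:
        raise SmilesError(smiles, "is empty")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(smiles)
    return Chem.MolToSmiles(mol)


def is_valid(smiles: str) -> bool:
    return bool(smiles) and Chem.MolFromSmiles(smiles) is not None


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into chemistry-preserving tokens.

    Bracket environments, two-letter halogens (Cl/Br) and two-digit ``%NN``
    ring closures are single tokens; everything else is one character.
    """
    if "[" in smiles:
        # reject unclosed brackets before the catch-all regex hides them
        depth = 0
        for ch in smiles:
            if ch == "[":
                depth += 1
                if depth > 1:
                    raise SmilesError(smiles, "has nested '['")
            elif ch == "]":
                depth -= 1
                if depth < 0:
                    raise SmilesError(smiles, "has unmatched ']'")
        if depth != 0:
            raise SmilesError(smiles, "has an unclosed '['")
    return _TOKEN_RE.findall(smiles)


def detokenize(tokens: list[str]) -> str:
    return "".join(t for t in tokens if t not in (PAD, START, END))


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token set with specials first (pad=0, G=1, A=2)."""

    tokens: tuple[str, ...]
    index_of: dict[str, int] = field(compare=False)

    pad_idx = 0
    start_idx = 1
    end_idx = 2

    def __len__(self):
        return len(self.tokens)

    def __contains__(self, tok):
        return tok in self.index_of

    @classmethod
    def from_tokens(cls, observed) -> "Vocabulary":
        body = sorted(set(observed) - {PAD, START, END})
        tokens = (PAD, START, END, *body)
        return cls(tokens=tokens, index_of={t: i for i, t in enumerate(tokens)})


def build_vocabulary(corpus: list[str]) -> Vocabulary:
    """Vocabulary of every token observed in `corpus` plus the specials."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    observed = set()
    for s in corpus:
        observed.update(tokenize(s))
    return Vocabulary.from_tokens(observed)


def encode_dataset(corpus: list[str], vocab: Vocabulary, max_len: int = 100) -> np.ndarray:
    """Integer matrix of shape (n, max_len): rows are [G, tokens..., A, pad...].

    Over-length molecules and out-of-vocabulary tokens raise; silent
    truncation would produce chemically different molecules.
    """
    out = np.full((len(corpus), max_len), vocab.pad_idx, dtype=np.int64)
    for r, smi in enumerate(corpus):
        toks = tokenize(smi)
        if len(toks) + 2 > max_len:
            raise ValueError(
                f"SMILES with {len(toks)} tokens exceeds max_len={max_len}: {smi!r}"
            )
        row = [vocab.start_idx]
        for t in toks:
            if t not in vocab:
                raise KeyError(f"token {t!r} (from {smi!r}) is not in the vocabulary")
            row.append(vocab.index_of[t])
        row.append(vocab.end_idx)
        out[r, : len(row)] = row
    return out


def decode_row(row, vocab: Vocabulary) -> str:
    """Inverse of one `encode_dataset` row: strip specials, join tokens."""
    toks = []
    for i in row:
        i = int(i)
        if i == vocab.end_idx:
            break
        if i in (vocab.pad_idx, vocab.start_idx):
            continue
        toks.append(vocab.tokens[i])
    return "".join(toks)


def one_hot(encoded: np.ndarray, vocab: Vocabulary) -> np.ndarray:
    """One-hot view (n, max_len, |V|) of an integer-encoded matrix."""
    eye = np.eye(len(vocab))
    return eye[encoded]


class Origin(str, Enum):
    POOL = "pool"
    GENERATED = "generated"


@dataclass
class MoleculeRecord:
    smiles: str  # canonical
    properties: dict[str, float] = field(default_factory=dict)
    origin: Origin = Origin.POOL

    @classmethod
    def from_smiles(cls, smiles: str, origin: Origin = Origin.POOL) -> "MoleculeRecord":
        return cls(smiles=canonicalize(smiles), origin=origin)


# --------------------------------------------------------------------------
# dataset I/O
# --------------------------------------------------------------------------

def read_smiles_file(path) -> list[MoleculeRecord]:
    """Read a one-SMILES-per-line file (optional second ID column ignored).

    Invalid or multi-fragment ('.') lines are logged with their line number
    and skipped; duplicates by canonical SMILES are removed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records, seen, n_skipped, n_dup = [], set(), 0, 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        smi = line.split()[0]
        if "." in smi:
            log.warning("line %d: multi-fragment SMILES skipped: %s", lineno, smi)
            n_skipped += 1
            continue
        try:
            canon = canonicalize(smi)
        except SmilesError:
            log.warning("line %d: invalid SMILES skipped: %s", lineno, smi)
            n_skipped += 1
            continue
        if canon in seen:
            n_dup += 1
            continue
        seen.add(canon)
        records.append(MoleculeRecord(smiles=canon))
    if n_skipped or n_dup:
        log.info("%s: skipped %d invalid, removed %d duplicates", path, n_skipped, n_dup)
    return records


def read_labeled_csv(path) -> list[tuple[str, float]]:
    """Read a CSV with columns `smiles,pIC50` (extras ignored); dedup + validate."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("smiles", "pIC50"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    pairs, seen, n_skipped = [], set(), 0
    for lineno, (smi, y) in enumerate(zip(df["smiles"], df["pIC50"]), start=2):
        try:
            canon = canonicalize(str(smi))
        except SmilesError:
            log.warning("line %d: invalid SMILES skipped: %s", lineno, smi)
            n_skipped += 1
            continue
        if canon in seen or not np.isfinite(y):
            continue
        seen.add(canon)
        pairs.append((canon, float(y)))
    if n_skipped:
        log.info("%s: skipped %d invalid rows", path, n_skipped)
    return pairs


# --------------------------------------------------------------------------
# toy molecule generator
# --------------------------------------------------------------------------

@dataclass
class ToyLibraryConfig:
    n_molecules: int = 1000
    seed: int = 0
    max_heavy_atoms: int = 12
    allow_stereo: bool = True
    allow_charge: bool = False
    # element draw pool (repeats weight the draw); shrink for smaller grammars
    elements: tuple = ("C", "C", "C", "C", "C", "N", "O", "S", "F", "Cl")
    max_rings: int = 2

    def __post_init__(self):
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if self.max_heavy_atoms < 3:
            raise ValueError("max_heavy_atoms must be at least 3")


_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1}
_ELEMENTS = ["C", "C", "C", "C", "C", "N", "O", "S", "F", "Cl"]


def _assemble_random_molecule(rng, cfg: ToyLibraryConfig) -> str | None:
    """One random small organic molecule as canonical SMILES, or None on failure."""
    n_heavy = int(rng.integers(3, cfg.max_heavy_atoms + 1))
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom("C"))
    free = {0: 4}
    for _ in range(n_heavy - 1):
        hosts = [i for i, v in free.items() if v >= 1]
        if not hosts:
            break
        host = int(rng.choice(hosts))
        el = str(rng.choice(list(cfg.elements)))
        order = Chem.BondType.SINGLE
        used = 1
        if free[host] >= 2 and _VALENCE[el] >= 2 and rng.random() < 0.15:
            order = Chem.BondType.DOUBLE
            used = 2
        idx = mol.AddAtom(Chem.Atom(el))
        mol.AddBond(host, idx, order)
        free[host] -= used
        free[idx] = _VALENCE[el] - used
    # ring closures between non-adjacent atoms with spare valence
    for _ in range(int(rng.integers(0, cfg.max_rings + 1))):
        cands = [i for i, v in free.items() if v >= 1]
        rng.shuffle(cands)
        made = False
        for a in cands:
            for b in cands:
                if b <= a or mol.GetBondBetweenAtoms(a, b):
                    continue
                path = Chem.GetShortestPath(mol, a, b)
                if 3 <= len(path) <= 7:
                    mol.AddBond(a, b, Chem.BondType.SINGLE)
                    free[a] -= 1
                    free[b] -= 1
                    made = True
                    break
            if made:
                break
    if cfg.allow_charge and rng.random() < 0.3:
        ns = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N"]
        if ns:
            mol.GetAtomWithIdx(int(rng.choice(ns))).SetFormalCharge(1)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if cfg.allow_stereo:
        centers = Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
        unassigned = [i for i, tag in centers if tag == "?"]
        if unassigned and rng.random() < 0.7:
            tag = (
                Chem.ChiralType.CHI_TETRAHEDRAL_CW
                if rng.random() < 0.5
                else Chem.ChiralType.CHI_TETRAHEDRAL_CCW
            )
            mol.GetAtomWithIdx(int(rng.choice(unassigned))).SetChiralTag(tag)
    return Chem.MolToSmiles(mol)


def generate_toy_library(config: ToyLibraryConfig) -> list[MoleculeRecord]:
    """Seeded library of distinct, valid small organic molecules.

    Molecules are assembled atom by atom (C/N/O/S/F/Cl, occasional double
    bonds, up to two rings); with `allow_stereo` a fraction carry an assigned
    tetrahedral center and canonicalize to SMILES containing ``[C@H]`` or
    ``[C@@H]``. Fully reproducible from `config.seed`.
    """
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    max_attempts = 200 * config.n_molecules
    attempts = 0
    while len(records) < config.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"toy generator exhausted after {max_attempts} attempts "
                f"({len(records)}/{config.n_molecules} distinct molecules)"
            )
        smi = _assemble_random_molecule(rng, config)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        records.append(MoleculeRecord(smiles=smi))
    return records


def surrogate_activity(record: MoleculeRecord | str) -> float:
    """Deterministic pIC50-like oracle on a [4, 10] scale.

    A fixed smooth function of computed descriptors: Gaussian bumps centred on
    a drug-like region (logP near 2.5, TPSA near 60, MW near 300) plus a ring
    bonus, clamped to [4, 10].  Identical canonical SMILES always score
    identically, which makes the feedback loop's objective reproducible.
    """
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(smiles)
    logp = Crippen.MolLogP(mol)
    tpsa = Descriptors.TPSA(mol)
    mw = Descriptors.MolWt(mol)
    rings = mol.GetRingInfo().NumRings()
    score = (
        4.0
        + 2.5 * np.exp(-(((logp - 2.5) / 1.5) ** 2))
        + 2.0 * np.exp(-(((tpsa - 60.0) / 30.0) ** 2))
        + 0.5 * min(rings, 2)
        + 0.5 * np.exp(-(((mw - 300.0) / 100.0) ** 2))
    )
    return float(np.clip(score, 4.0, 10.0))
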