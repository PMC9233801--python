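"""Generation-quality metrics: validity / uniqueness / novelty, a
KL-divergence distribution-learning score over a fixed descriptor panel, and
Tanimoto-based internal/external diversity.

The KL score follows the distribution-learning convention popularized by the
Guacamol benchmark: for each of k features compute D_KL(reference || generated)
between the two value distributions and report

    S = (1/k) * sum_i exp(-D_KL_i),    0 < S <= 1,

so identical distributions give S = 1.  Nine RDKit descriptors plus the
distribution of maximum nearest-neighbour ECFP4 similarities to the reference
set make k = 10.

Diversity of two molecule sets A and B is the mean Tanimoto *distance* over
all |A|x|B| ordered pairs of ECFP4 fingerprints (self-pairs included for
Div(A,A), matching the plain double sum; excluding the diagonal is available
as an option and changes values by O(1/|A|)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors
from rdkit.Chem import rdFingerprintGenerator

from .chem_data import canonicalize, is_valid

log = logging.getLogger(__name__)

# ECFP4: circular fingerprint, radius 2; bit length fixed for reproducibility
_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

# the 9-descriptor panel for the KL score (NumHDonors: see docs/methods.md)
KL_DESCRIPTORS = {
    "NumRotatableBonds": Descriptors.NumRotatableBonds,
    "MolLogP": Crippen.MolLogP,
    "MolWt": Descriptors.MolWt,
    "BertzCT": Descriptors.BertzCT,
    "TPSA": Descriptors.TPSA,
    "NumHAcceptors": Descriptors.NumHAcceptors,
    "NumHDonors": Descriptors.NumHDonors,
    "NumAliphaticRings": Descriptors.NumAliphaticRings,
    "NumAromaticRings": Descriptors.NumAromaticRings,
}
_DISCRETE = {
    "NumRotatableBonds", "NumHAcceptors", "NumHDonors",
    "NumAliphaticRings", "NumAromaticRings",
}


def basic_metrics(generated: list[str], reference: list[str]) -> dict:
    """Validity, uniqueness and novelty percentages.

    Validity over all generated strings; uniqueness over the valid ones (by
    canonical SMILES, stereo-sensitive); novelty over the unique valid ones
    against the canonicalized reference set.
    """
    if not generated:
        raise ValueError("empty generated list")
    valid = [s for s in generated if is_valid(s)]
    unique = {canonicalize(s) for s in valid}
    ref = {canonicalize(s) for s in reference if is_valid(s)}
    novel = unique - ref
    return {
        "validity_pct": 100.0 * len(valid) / len(generated),
        "uniqueness_pct": 100.0 * len(unique) / len(valid) if valid else 0.0,
        "novelty_pct": 100.0 * len(novel) / len(unique) if unique else 0.0,
    }


def _mols(smiles_list):
    out = []
    for s in smiles_list:
        m = Chem.MolFromSmiles(s)
        if m is None:
            log.warning("skipping unparsable SMILES in evaluation: %s", s)
            continue
        out.append(m)
    return out


def fingerprints(smiles_list):
    return [_FP_GEN.GetFingerprint(m) for m in _mols(smiles_list)]


def tanimoto_similarity(a: str, b: str) -> float:
    fa, fb = fingerprints([a, b])
    return float(DataStructs.TanimotoSimilarity(fa, fb))


def diversity(A: list[str], B: list[str], include_self_pairs: bool = True) -> float:
    """Div(A, B): mean Tanimoto distance over all ordered pairs of A x B."""
    fa, fb = fingerprints(A), fingerprints(B)
    if not fa or not fb:
        raise ValueError("diversity requires non-empty molecule sets")
    sims = np.array([DataStructs.BulkTanimotoSimilarity(f, fb) for f in fa])
    if not include_self_pairs and A is B:
        n = len(fa)
        off = ~np.eye(n, dtype=bool)
        return float((1.0 - sims)[off].mean()) if n > 1 else 0.0
    return float((1.0 - sims).mean())


def internal_diversity(A: list[str]) -> float:
    return diversity(A, A)


def external_diversity(A: list[str], B_train: list[str]) -> float:
    return diversity(A, B_train)


def max_nn_similarities(query: list[str], reference: list[str],
                        leave_one_out: bool = False) -> np.ndarray:
    """Per-query maximum Tanimoto similarity to the reference set.

    With `leave_one_out` (used when query IS the reference), each molecule's
    self-match is excluded so the feature is not identically 1.
    """
    fq, fr = fingerprints(query), fingerprints(reference)
    out = np.empty(len(fq))
    for i, f in enumerate(fq):
        sims = np.array(DataStructs.BulkTanimotoSimilarity(f, fr))
        if leave_one_out:
            sims[i] = -1.0
        out[i] = sims.max()
    return out


def _kl_divergence(p_ref: np.ndarray, q_gen: np.ndarray) -> float:
    """Discrete D_KL(ref || gen) of two aligned probability vectors."""
    return float(np.sum(p_ref * np.log(p_ref / q_gen)))


def histogram_kl(ref_values, gen_values, discrete: bool = False,
                 n_bins: int = 50, smoothing: float = 1e-10) -> float:
    """KL divergence between two samples via shared-support histograms.

    Continuous features use `n_bins` equal bins over the pooled range;
    integer-valued features use one bin per observed value.  Additive
    smoothing keeps the divergence finite on empty bins.
    """
    ref = np.asarray(ref_values, dtype=float)
    gen = np.asarray(gen_values, dtype=float)
    if ref.size == 0 or gen.size == 0:
        raise ValueError("empty sample for KL estimation")
    if discrete:
        support = np.unique(np.concatenate([ref, gen]))
        p = np.array([(ref == v).sum() for v in support], dtype=float)
        q = np.array([(gen == v).sum() for v in support], dtype=float)
    else:
        lo = min(ref.min(), gen.min())
        hi = max(ref.max(), gen.max())
        if lo == hi:
            return 0.0
        edges = np.linspace(lo, hi, n_bins + 1)
        p, _ = np.histogram(ref, bins=edges)
        q, _ = np.histogram(gen, bins=edges)
        p, q = p.astype(float), q.astype(float)
    p = (p + smoothing) / (p + smoothing).sum()
    q = (q + smoothing) / (q + smoothing).sum()
    return _kl_divergence(p, q)


def kl_score(generated: list[str], reference: list[str], n_bins: int = 50,
             smoothing: float = 1e-10) -> float:
    """S = mean over features of exp(-D_KL(reference || generated))."""
    gen_mols, ref_mols = _mols(generated), _mols(reference)
    if not gen_mols or not ref_mols:
        raise ValueError("kl_score requires non-empty valid molecule sets")
    divergences = []
    for name, fn in KL_DESCRIPTORS.items():
        ref_vals = [fn(m) for m in ref_mols]
        gen_vals = [fn(m) for m in gen_mols]
        divergences.append(
            histogram_kl(ref_vals, gen_vals, discrete=name in _DISCRETE,
                         n_bins=n_bins, smoothing=smoothing)
        )
    ref_smis = [Chem.MolToSmiles(m) for m in ref_mols]
    gen_smis = [Chem.MolToSmiles(m) for m in gen_mols]
    loo = len(ref_smis) > 1
    ref_nn = max_nn_similarities(ref_smis, ref_smis, leave_one_out=loo)
    # when the two multisets coincide, score the generated side the same way,
    # so that a perfect reproduction of the reference yields S = 1
    gen_nn = max_nn_similarities(gen_smis, ref_smis,
                                 leave_one_out=loo and gen_smis == ref_smis)
    divergences.append(histogram_kl(ref_nn, gen_nn, n_bins=n_bins, smoothing=smoothing))
    return float(np.mean(np.exp(-np.array(divergences))))


@dataclass
class EvalReport:
    validity_pct: float
    uniqueness_pct: float
    novelty_pct: float
    kl_score: float
    int_div: float
    ext_div: float

    def as_dict(self) -> dict:
        return {
            "validity_pct": self.validity_pct,
            "uniqueness_pct": self.uniqueness_pct,
            "novelty_pct": self.novelty_pct,
            "kl_score": self.kl_score,
            "int_div": self.int_div,
            "ext_div": self.ext_div,
        }


def evaluation_report(generated: list[str], reference: list[str],
                      activity_fn=None) -> tuple[EvalReport, "pd.DataFrame"]:
    """Full metric panel plus a per-molecule descriptor table.

    The table carries the descriptor panel, QED/SAS/logP/MW (scatter-plot
    views) and, when `activity_fn` is given, the predicted activity.
    """
    import pandas as pd

    from .objectives import compute_properties

    basics = basic_metrics(generated, reference)
    valid = [canonicalize(s) for s in generated if is_valid(s)]
    if not valid:
        raise ValueError("no valid generated molecules to evaluate")
    report = EvalReport(
        validity_pct=basics["validity_pct"],
        uniqueness_pct=basics["uniqueness_pct"],
        novelty_pct=basics["novelty_pct"],
        kl_score=kl_score(valid, reference),
        int_div=internal_diversity(valid),
        ext_div=external_diversity(valid, reference),
    )
    rows = []
    for s in valid:
        mol = Chem.MolFromSmiles(s)
        row = {"smiles": s}
        row.update({name: fn(mol) for name, fn in KL_DESCRIPTORS.items()})
        row.update(compute_properties(s))
        if activity_fn is not None:
            row["pIC50"] = float(activity_fn(s))
        rows.append(row)
    return report, pd.DataFrame(rows)
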