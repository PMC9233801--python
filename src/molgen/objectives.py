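"""Molecular property computation, multi-objective score vectors, Pareto
dominance and NSGA-II style non-dominated ranking.

Every objective set is expressed in a single maximization convention: each
component is a (property, sign) pair and the sign is applied before any
comparison, e.g. ``(pIC50, +1), (SAS, -1)`` scores a molecule as
``(pIC50, -SAS)``.  Ranking follows the domination-count scheme of fast
non-dominated sorting: a molecule's rank is the number of population members
that dominate it, and fronts are peeled iteratively (front 1 = non-dominated).
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, QED

from .chem_data import MoleculeRecord, SmilesError

log = logging.getLogger(__name__)

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (Ertl-Schuffenhauer synthetic accessibility)

_PROPERTY_CACHE: dict[str, dict[str, float]] = {}


def compute_properties(smiles: str) -> dict[str, float]:
    """Standard descriptor profile {logP, TPSA, SAS, MW, QED} for one molecule.

    Deterministic per canonical SMILES; results are cached.
    """
    if smiles in _PROPERTY_CACHE:
        return dict(_PROPERTY_CACHE[smiles])
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(smiles)
    props = {
        "logP": float(Crippen.MolLogP(mol)),
        "TPSA": float(Descriptors.TPSA(mol)),
        "SAS": float(sascorer.calculateScore(mol)),
        "MW": float(Descriptors.MolWt(mol)),
        "QED": float(QED.qed(mol)),
    }
    _PROPERTY_CACHE[smiles] = props
    return dict(props)


@dataclass(frozen=True)
class ObjectiveSet:
    """Named list of (property, sign) components, maximization convention."""

    name: str
    components: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if len(self.components) < 2:
            raise ValueError("an objective set needs at least two components")
        if any(sign not in (+1, -1) for _, sign in self.components):
            raise ValueError("signs must be +1 or -1")

    @property
    def arity(self) -> int:
        return len(self.components)


# the three built-in score-vector definitions
PIC50_SAS = ObjectiveSet("PIC50_SAS", (("pIC50", +1), ("SAS", -1)))
PIC50_TPSA = ObjectiveSet("PIC50_TPSA", (("pIC50", +1), ("TPSA", -1)))
LOGP_SAS = ObjectiveSet("LOGP_SAS", (("logP", -1), ("SAS", -1)))

BUILTIN_OBJECTIVES = {o.name: o for o in (PIC50_SAS, PIC50_TPSA, LOGP_SAS)}


@dataclass
class ScoreVector:
    values: tuple[float, ...]
    molecule: MoleculeRecord | None = None

    def __post_init__(self):
        if not all(np.isfinite(v) for v in self.values):
            raise ValueError("score vector has non-finite entries")

    def __len__(self):
        return len(self.values)


def score_vector(record: MoleculeRecord, objective_set: ObjectiveSet,
                 activity_fn=None) -> ScoreVector:
    """Signed objective tuple for one molecule (larger always better).

    pIC50 comes from `activity_fn` (a trained predictor or the surrogate
    oracle) unless already present in the record's properties; the remaining
    properties come from `compute_properties`.
    """
    props = dict(record.properties)
    needed = {name for name, _ in objective_set.components}
    if "pIC50" in needed and "pIC50" not in props:
        if activity_fn is None:
            raise KeyError("pIC50 requested but no activity function provided")
        props["pIC50"] = float(activity_fn(record))
    missing = needed - props.keys() - {"pIC50"}
    if missing:
        props.update(compute_properties(record.smiles))
    for name, _ in objective_set.components:
        if name not in props:
            raise KeyError(f"property {name!r} unavailable for {record.smiles}")
    record.properties.update(props)
    return ScoreVector(
        values=tuple(sign * props[name] for name, sign in objective_set.components),
        molecule=record,
    )


def dominates(u, v) -> bool:
    """True iff u >= v componentwise with at least one strict > (maximization)."""
    uv = u.values if isinstance(u, ScoreVector) else tuple(u)
    vv = v.values if isinstance(v, ScoreVector) else tuple(v)
    if len(uv) != len(vv):
        raise ValueError("score vectors have different arities")
    ge = all(a >= b for a, b in zip(uv, vv))
    gt = any(a > b for a, b in zip(uv, vv))
    return ge and gt


@dataclass
class ParetoRanking:
    domination_count: np.ndarray  # per molecule: #dominators, in [0, P-1]
    fronts: list[list[int]] = field(default_factory=list)  # front 1 first


def rank_population(scores) -> ParetoRanking:
    """Domination counts and Pareto fronts by iterative peeling.

    Pairwise comparison of all P^2 ordered pairs; front k+1 contains the
    members dominated only by fronts <= k.
    """
    vals = np.array([s.values if isinstance(s, ScoreVector) else tuple(s) for s in scores],
                    dtype=float)
    P = len(vals)
    if P == 0:
        raise ValueError("empty population")
    # dom[i, j] True iff i dominates j
    ge = (vals[:, None, :] >= vals[None, :, :]).all(axis=2)
    gt = (vals[:, None, :] > vals[None, :, :]).any(axis=2)
    dom = ge & gt
    counts = dom.sum(axis=0)
    fronts = []
    assigned = np.zeros(P, dtype=bool)
    cur = counts.astype(int).copy()
    while not assigned.all():
        front = np.where(~assigned & (cur == 0))[0]
        fronts.append(front.tolist())
        assigned[front] = True
        # peeling a front decrements the counts of everything it dominates
        cur = cur - dom[front].sum(axis=0)
        cur[assigned] = -1
    return ParetoRanking(domination_count=counts, fronts=fronts)


DEFAULT_DRUG_LIKE_BOUNDS = {
    "QED": (0.5, np.inf),
    "SAS": (-np.inf, 5.0),
    "MW": (-np.inf, 600.0),
    "logP": (-2.0, 6.0),
}


def drug_like_filter(record: MoleculeRecord, bounds: dict | None = None) -> bool:
    """Box filter on the drug-like region (configurable per-property bounds)."""
    bounds = DEFAULT_DRUG_LIKE_BOUNDS if bounds is None else bounds
    props = dict(record.properties)
    if not all(name in props for name in bounds):
        props.update(compute_properties(record.smiles))
    return all(lo <= props[name] <= hi for name, (lo, hi) in bounds.items())


def _tie_break_order(vals: np.ndarray, indices) -> list[int]:
    """Within-front order: descending first objective, then lexicographic."""
    keys = [tuple(-vals[i]) for i in indices]
    return [i for _, i in sorted(zip(keys, indices))]


def select_best(scores, k: int, use_filter: bool = False,
                bounds: dict | None = None) -> list[int]:
    """Indices of the k best molecules, taken front by front.

    Optionally pre-filters to the drug-like box; ties within a front are
    broken by descending first objective, then lexicographically.  Returns an
    empty selection (with a warning) if the filter removes everything.
    """
    scores = list(scores)
    if k > len(scores):
        raise ValueError("k exceeds the population size")
    vals = np.array([s.values for s in scores], dtype=float)
    eligible = list(range(len(scores)))
    if use_filter:
        eligible = [
            i for i in eligible
            if scores[i].molecule is not None and drug_like_filter(scores[i].molecule, bounds)
        ]
        if not eligible:
            log.warning("drug-like filter removed the entire population")
            return []
    ranking = rank_population([scores[i] for i in eligible])
    selected: list[int] = []
    for front in ranking.fronts:
        members = [eligible[j] for j in front]
        for i in _tie_break_order(vals, members):
            if len(selected) == k:
                return selected
            selected.append(i)
    return selected
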