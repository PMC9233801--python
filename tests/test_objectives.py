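"""Property computation, score vectors, Pareto dominance and NSGA-II ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from molgen import chem_data as cd
from molgen import objectives as ob


def brute_force_ranking(vals):
    """O(n^3) dominance oracle: counts and fronts by direct definition."""
    P = len(vals)

    def dom(u, v):
        return all(a >= b for a, b in zip(u, v)) and any(a > b for a, b in zip(u, v))

    counts = [sum(dom(vals[j], vals[i]) for j in range(P)) for i in range(P)]
    remaining, fronts = set(range(P)), []
    while remaining:
        front = sorted(
            i for i in remaining if not any(dom(vals[j], vals[i]) for j in remaining)
        )
        fronts.append(front)
        remaining -= set(front)
    return counts, fronts


class TestProperties:
    def test_deterministic(self):
        assert ob.compute_properties("CCO") == ob.compute_properties("CCO")

    def test_tpsa_of_alkane_is_zero(self):
        assert ob.compute_properties("CCCC")["TPSA"] == 0.0

    def test_matches_independent_recomputation(self):
        from rdkit import Chem
        from rdkit.Chem import Crippen, Descriptors, QED

        for smi in ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "CCN", "C1CCCCC1O"]:
            mol = Chem.MolFromSmiles(smi)
            props = ob.compute_properties(smi)
            assert props["logP"] == pytest.approx(Crippen.MolLogP(mol))
            assert props["TPSA"] == pytest.approx(Descriptors.TPSA(mol))
            assert props["MW"] == pytest.approx(Descriptors.MolWt(mol))
            assert props["QED"] == pytest.approx(QED.qed(mol))
            assert 1.0 <= props["SAS"] <= 10.0

    def test_invalid_molecule_raises(self):
        with pytest.raises(cd.SmilesError):
            ob.compute_properties("C((")


class TestScoreVector:
    def test_sign_application(self):
        rec = cd.MoleculeRecord.from_smiles("CCO")
        rec.properties.update({"pIC50": 7.0, "SAS": 3.0})
        sv = ob.score_vector(rec, ob.PIC50_SAS)
        assert sv.values == (7.0, -3.0)

    def test_logp_sas_both_negated(self):
        rec = cd.MoleculeRecord.from_smiles("CCO")
        rec.properties.update({"logP": 2.0, "SAS": 4.0})
        assert ob.score_vector(rec, ob.LOGP_SAS).values == (-2.0, -4.0)

    def test_custom_three_objective(self):
        custom = ob.ObjectiveSet(
            "custom", (("pIC50", +1), ("TPSA", -1), ("QED", +1))
        )
        rec = cd.MoleculeRecord.from_smiles("CCO")
        rec.properties["pIC50"] = 6.0
        sv = ob.score_vector(rec, custom)
        assert len(sv.values) == 3

    def test_activity_from_surrogate(self):
        rec = cd.MoleculeRecord.from_smiles("CCO")
        sv = ob.score_vector(rec, ob.PIC50_SAS, cd.surrogate_activity)
        assert sv.values[0] == pytest.approx(cd.surrogate_activity("CCO"))


class TestDominance:
    @pytest.mark.parametrize("u,v,expected", [
        ((2, 2), (1, 1), True),
        ((2, 1), (1, 2), False),
        ((1, 2), (2, 1), False),
        ((2, 2), (2, 2), False),
        ((2, 2), (2, 1), True),
    ])
    def test_definition(self, u, v, expected):
        assert ob.dominates(u, v) is expected

    def test_arity_mismatch(self):
        with pytest.raises(ValueError):
            ob.dominates((1, 2), (1, 2, 3))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5), st.integers(0, 5)),
                    min_size=3, max_size=3))
    def test_irreflexive_and_transitive(self, vecs):
        u, v, w = vecs
        assert not ob.dominates(u, u)
        if ob.dominates(u, v) and ob.dominates(v, w):
            assert ob.dominates(u, w)


class TestRanking:
    def test_chain(self):
        r = ob.rank_population([(2, 2), (1, 1), (0, 0)])
        assert list(r.domination_count) == [0, 1, 2]
        assert r.fronts == [[0], [1], [2]]

    def test_all_identical_single_front(self):
        r = ob.rank_population([(1, 1)] * 5)
        assert list(r.domination_count) == [0] * 5
        assert r.fronts == [[0, 1, 2, 3, 4]]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ob.rank_population([])

    def test_counts_bounded_and_front1_undominated(self):
        rng = np.random.default_rng(5)
        vals = [tuple(v) for v in rng.integers(0, 10, size=(60, 2))]
        r = ob.rank_population(vals)
        assert r.domination_count.max() <= len(vals) - 1
        assert all(r.domination_count[i] == 0 for i in r.fronts[0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(2, 150))
            arity = int(rng.integers(2, 4))
            vals = [tuple(v) for v in rng.integers(0, 8, size=(n, arity))]
            r = ob.rank_population(vals)
            counts, fronts = brute_force_ranking(vals)
            assert list(r.domination_count) == counts
            assert [sorted(f) for f in r.fronts] == fronts

    def test_peeling_front1_promotes_front2(self):
        rng = np.random.default_rng(7)
        vals = [tuple(v) for v in rng.integers(0, 6, size=(40, 2))]
        r = ob.rank_population(vals)
        survivors = [i for i in range(len(vals)) if i not in set(r.fronts[0])]
        r2 = ob.rank_population([vals[i] for i in survivors])
        assert [survivors[j] for j in r2.fronts[0]] == r.fronts[1]

    def test_negation_swaps_dominance_direction(self):
        """Negating all objectives turns i-dominates-j into j-dominates-i, so
        the negated domination count equals the original out-degree."""
        rng = np.random.default_rng(9)
        vals = [tuple(v) for v in rng.normal(size=(30, 2))]
        r_neg = ob.rank_population([tuple(-x for x in v) for v in vals])
        out_degree = [
            sum(ob.dominates(vals[i], vals[j]) for j in range(len(vals)))
            for i in range(len(vals))
        ]
        assert list(r_neg.domination_count) == out_degree


class TestSelection:
    def test_exact_front_returned(self):
        scores = [ob.ScoreVector(v) for v in [(3, 0), (0, 3), (0, 0)]]
        assert set(ob.select_best(scores, 2)) == {0, 1}

    def test_spans_two_fronts(self):
        scores = [ob.ScoreVector(v) for v in [(3, 3), (1, 1), (0, 0)]]
        sel = ob.select_best(scores, 2)
        assert sel == [0, 1]

    def test_filter_excluding_front1(self):
        good = cd.MoleculeRecord.from_smiles("CC(C)Cc1ccc(cc1)C(C)C(=O)O")  # ibuprofen
        bad = cd.MoleculeRecord.from_smiles("C" * 60)  # MW > 600
        s_bad = ob.ScoreVector((9.0, 9.0), molecule=bad)
        s_good = ob.ScoreVector((1.0, 1.0), molecule=good)
        sel = ob.select_best([s_bad, s_good], 1, use_filter=True)
        assert sel == [1]

    def test_filter_removes_everything(self):
        bad = cd.MoleculeRecord.from_smiles("C" * 60)
        sel = ob.select_best([ob.ScoreVector((1.0, 1.0), molecule=bad)], 1,
                             use_filter=True)
        assert sel == []

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            ob.select_best([ob.ScoreVector((1.0, 2.0))], 2)
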