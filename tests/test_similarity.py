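"""Similarity primitives: hand-derived oracles and structural invariants."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandit.data_io import BinaryFeatures, DrugRecord
from bandit.evaluation import cross_type_correlation
from bandit.similarity import (
    binary_jaccard,
    build_similarity_matrix,
    dice_similarity,
    profile_pearson,
    smiles_to_atompair_fp,
)
from bandit.synthetic_data import (
    UniverseConfig,
    generate_universe,
    structure_fixture_set,
)


def pearson_oracle(x, y):
    """Direct evaluation of the Pearson formula (independent of the
    vectorized implementation)."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


class TestProfilePearson:
    def test_self_correlation_is_one(self):
        assert profile_pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert profile_pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_against_hand_coded_formula(self):
        x, y = [1, 2, 3, 4], [1, 2, 3, 10]
        assert profile_pearson(x, y) == pytest.approx(pearson_oracle(x, y),
                                                      abs=1e-12)

    def test_fewer_than_three_shared_observations_undefined(self):
        x = [1.0, 2.0, np.nan, np.nan]
        y = [np.nan, 5.0, 6.0, 7.0]
        assert profile_pearson(x, y) is None

    def test_constant_restricted_profile_undefined(self):
        assert profile_pearson([1, 1, 1], [1, 2, 3]) is None

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=20),
           st.floats(0.1, 10), st.floats(-5, 5))
    def test_invariant_to_positive_affine_transform(self, xs, slope, shift):
        rng = np.random.default_rng(0)
        ys = rng.normal(size=len(xs))
        base = profile_pearson(xs, ys)
        transformed = profile_pearson([slope * v + shift for v in xs], ys)
        if base is None:
            assert transformed is None
        else:
            assert transformed == pytest.approx(base, abs=1e-8)


class TestBinaryJaccard:
    def _bf(self, positives, tested=None):
        pos = frozenset(positives)
        return BinaryFeatures(pos, pos | frozenset(tested or ()))

    def test_identity(self):
        a = self._bf({"p1", "p2"})
        assert binary_jaccard(a, a) == pytest.approx(1.0)

    def test_disjoint_nonempty(self):
        assert binary_jaccard(self._bf({"p1"}), self._bf({"p2"})) == 0.0

    def test_one_third_overlap(self):
        a, b = self._bf({"p1", "p2"}), self._bf({"p2", "p3"})
        assert binary_jaccard(a, b) == pytest.approx(1 / 3)

    def test_empty_union_undefined(self):
        a = self._bf(set(), {"t1"})
        assert binary_jaccard(a, a) is None

    def test_cotested_precondition(self):
        a = self._bf({"p1"}, {"t1"})
        b = self._bf({"p2"}, {"t2"})
        assert binary_jaccard(a, b, require_cotested=True) is None
        assert binary_jaccard(a, b, require_cotested=False) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(st.sets(st.integers(0, 30), min_size=1, max_size=15),
           st.sets(st.integers(0, 30), min_size=1, max_size=15))
    def test_removing_shared_features_never_increases(self, sa, sb):
        a = self._bf({str(v) for v in sa})
        b = self._bf({str(v) for v in sb})
        score = binary_jaccard(a, b)
        shared = a.positives & b.positives
        if shared:
            drop = next(iter(sorted(shared)))
            smaller = binary_jaccard(
                self._bf(set(a.positives) - {drop}) if len(a.positives) > 1 else a,
                b)
            if len(a.positives) > 1 and smaller is not None:
                assert smaller <= score + 1e-12


class TestAtomPairFingerprint:
    FIXTURES = dict((name, smi) for name, smi in structure_fixture_set())

    def test_methane_is_empty(self):
        assert smiles_to_atompair_fp(self.FIXTURES["methane"]) == Counter()

    def test_ethane_single_feature(self):
        fp = smiles_to_atompair_fp(self.FIXTURES["ethane"])
        assert fp == Counter({(("C", 1, False), ("C", 1, False), 1): 1})

    def test_propane_hand_enumeration(self):
        fp = smiles_to_atompair_fp(self.FIXTURES["propane"])
        assert fp == Counter({
            (("C", 1, False), ("C", 2, False), 1): 2,
            (("C", 1, False), ("C", 1, False), 2): 1,
        })

    def test_atom_order_invariance(self):
        # same molecule (isopentane) written from different starting atoms
        a = smiles_to_atompair_fp("CCC(C)C")
        b = smiles_to_atompair_fp("CC(C)CC")
        assert a == b

    def test_aromatic_flag_distinguishes_benzene_from_cyclohexane(self):
        benzene = smiles_to_atompair_fp(self.FIXTURES["benzene"])
        cyclohexane = smiles_to_atompair_fp("C1CCCCC1")
        assert set(benzene) != set(cyclohexane)

    def test_unparseable_smiles_raises(self):
        with pytest.raises(ValueError, match="unparseable"):
            smiles_to_atompair_fp("C(")

    def test_all_fixture_smiles_parse(self):
        for _, smi in structure_fixture_set():
            smiles_to_atompair_fp(smi)  # must not raise


class TestDice:
    def test_identical_nonempty_is_one(self):
        fp = smiles_to_atompair_fp("CCO")
        assert dice_similarity(fp, fp) == pytest.approx(1.0)

    def test_methane_vs_ethane_is_zero(self):
        a = smiles_to_atompair_fp("C")
        b = smiles_to_atompair_fp("CC")
        assert dice_similarity(a, b) == 0.0

    def test_propane_butane_four_ninths(self):
        a = smiles_to_atompair_fp("CCC")
        b = smiles_to_atompair_fp("CCCC")
        assert dice_similarity(a, b) == pytest.approx(4 / 9)

    def test_both_empty_undefined(self):
        assert dice_similarity(Counter(), Counter()) is None

    @settings(deadline=None, max_examples=50)
    @given(st.dictionaries(st.integers(0, 20), st.integers(1, 5),
                           min_size=1, max_size=10),
           st.dictionaries(st.integers(0, 20), st.integers(1, 5),
                           min_size=1, max_size=10))
    def test_range_and_symmetry(self, da, db):
        fa, fb = Counter(da), Counter(db)
        s = dice_similarity(fa, fb)
        assert 0.0 <= s <= 1.0
        assert s == dice_similarity(fb, fa)


class TestBuildSimilarityMatrix:
    def test_matrix_matches_per_pair_ops(self, small_universe):
        records = small_universe.records[:12]
        for channel, op in [
            ("gi50", lambda a, b: profile_pearson(a, b)),
            ("bioassay", lambda a, b: binary_jaccard(a, b, require_cotested=True)),
            ("sideeffect", lambda a, b: binary_jaccard(a, b)),
            ("structure", lambda a, b: dice_similarity(a, b)),
        ]:
            sim = build_similarity_matrix(records, channel)
            for i, a in enumerate(records):
                for j, b in enumerate(records):
                    if i >= j:
                        continue
                    if channel in a.features and channel in b.features:
                        expected = op(a.features[channel], b.features[channel])
                    else:
                        expected = None
                    if expected is None:
                        assert not sim.defined[i, j], (channel, a.drug_id, b.drug_id)
                    else:
                        assert sim.values[i, j] == pytest.approx(expected, abs=1e-9)
                    assert sim.defined[i, j] == sim.defined[j, i]
                    if sim.defined[i, j]:
                        assert sim.values[i, j] == pytest.approx(
                            sim.values[j, i], abs=1e-12)
                        lo, hi = sim.score_range
                        assert lo - 1e-9 <= sim.values[i, j] <= hi + 1e-9

    def test_drug_without_channel_fully_masked(self):
        records = [
            DrugRecord("a", features={"gi50": np.arange(5.0)}),
            DrugRecord("b", features={"gi50": np.arange(5.0) * 2}),
            DrugRecord("c", features={}),
        ]
        sim = build_similarity_matrix(records, "gi50")
        assert not sim.defined[2, :].any()

    def test_unknown_data_type_is_hard_error(self, small_universe):
        with pytest.raises(ValueError, match="unknown data type"):
            build_similarity_matrix(small_universe.records, "nmr")


def test_cross_type_correlation_near_zero_without_planted_signal():
    """With signal 0 every channel is independent noise, so cross-channel
    correlation of similarity scores should vanish."""
    u = generate_universe(UniverseConfig(n_drugs=80, signal=0.0,
                                         missingness=0.0, seed=5))
    sims = {c: build_similarity_matrix(u.records, c)
            for c in ("gi50", "cmap", "structure")}
    for a, b in [("gi50", "cmap"), ("gi50", "structure"), ("cmap", "structure")]:
        pcc, r2, n = cross_type_correlation(sims[a], sims[b])
        assert n >= 1000
        assert abs(pcc) < 0.1
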