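"""Evaluation machinery vs brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bandit.bayes_engine import PairLabel
from bandit.data_io import TargetTable
from bandit.evaluation import (
    cross_type_correlation,
    ks_separation,
    loo_target_accuracy,
    pooled_cv_tlr,
    roc_auc,
    screen_enrichment,
    stratified_pair_cv,
    tp_fp_ratio_curve,
)


def _labels(n_st: int, n_non: int) -> list[PairLabel]:
    out = []
    k = 0
    for flag, count in [(True, n_st), (False, n_non)]:
        for _ in range(count):
            out.append(PairLabel(f"a{k}", f"b{k}", flag))
            k += 1
    return out


class TestStratifiedPairCV:
    def test_stratification_arithmetic(self):
        folds = stratified_pair_cv(_labels(10, 90), k=5, seed=0)
        for fold in range(5):
            test = folds.fold_pairs(fold, train=False)
            assert len(test) == 20
            assert sum(p.shared_target for p in test) == 2

    def test_same_seed_identical_folds(self):
        labels = _labels(13, 87)
        a = stratified_pair_cv(labels, k=5, seed=42)
        b = stratified_pair_cv(labels, k=5, seed=42)
        assert np.array_equal(a.fold_of, b.fold_of)

    def test_folds_partition_the_pairs(self):
        labels = _labels(10, 40)
        folds = stratified_pair_cv(labels, k=5, seed=1)
        seen = [p for fold in range(5)
                for p in folds.fold_pairs(fold, train=False)]
        assert sorted(p.pair for p in seen) == sorted(p.pair for p in labels)

    def test_small_class_is_hard_error(self):
        with pytest.raises(ValueError, match="fewer than"):
            stratified_pair_cv(_labels(3, 50), k=5, seed=0)

    def test_drug_disjoint_mode_separates_drug_identities(self, default_labels):
        folds = stratified_pair_cv(default_labels, k=5, seed=0,
                                   drug_disjoint=True)
        for fold in range(folds.k):
            test_drugs = {d for p in folds.fold_pairs(fold, train=False)
                          for d in (p.drug_a, p.drug_b)}
            train_drugs = {d for p in folds.fold_pairs(fold, train=True)
                           for d in (p.drug_a, p.drug_b)}
            assert test_drugs and train_drugs
            assert not (test_drugs & train_drugs)


def auroc_bruteforce(scores, labels):
    """All-pairs concordance count with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_hand_example(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.6],
                       [True, False, True, False]) == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.3
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 12, 200).astype(float)  # many ties
        labels = rng.random(200) < 0.4
        assert roc_auc(scores, labels) == pytest.approx(
            auroc_bruteforce(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = rng.normal(size=500)
        labels = scores + rng.normal(size=500) > 0
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_hard_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])


def ks_bruteforce(a, b):
    """Max |ECDF_a - ECDF_b| evaluated at every sample point."""
    pts = sorted(set(a) | set(b))
    best = 0.0
    for x in pts:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        best = max(best, abs(fa - fb))
    return best


class TestKsSeparation:
    def test_identical_samples_zero(self):
        r = ks_separation([1, 2, 3], [1, 2, 3])
        assert r.d_statistic == 0.0

    def test_disjoint_samples_one(self):
        r = ks_separation([1, 2], [10, 20])
        assert r.d_statistic == 1.0

    def test_interleaved_hand_value(self):
        assert ks_separation([1, 3], [2, 4]).d_statistic == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 80)
        b = rng.normal(0.5, 1.3, 120)
        assert ks_separation(a, b).d_statistic == pytest.approx(
            ks_bruteforce(list(a), list(b)), abs=1e-12)


class TestTpFpRatioCurve:
    TLRS = np.array([0.1, 0.5, 2.0, 10.0, 50.0, 200.0])
    FLAGS = np.array([False, False, True, False, True, True])

    def test_cutoff_below_min_gives_base_ratio(self):
        rows = tp_fp_ratio_curve(self.TLRS, self.FLAGS, [0.01])
        assert rows[0]["tp"] == 3 and rows[0]["fp"] == 3
        assert rows[0]["ratio"] == pytest.approx(1.0)

    def test_cutoff_above_max_degenerate(self):
        rows = tp_fp_ratio_curve(self.TLRS, self.FLAGS, [1e6])
        assert rows[0]["degenerate"]
        assert rows[0]["tp"] == rows[0]["fp"] == 0

    def test_counts_at_interior_cutoff(self):
        rows = tp_fp_ratio_curve(self.TLRS, self.FLAGS, [1.0, 20.0])
        assert (rows[0]["tp"], rows[0]["fp"]) == (3, 1)
        assert (rows[1]["tp"], rows[1]["fp"]) == (2, 0)
        assert rows[1]["ratio"] == np.inf

    def test_non_ascending_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            tp_fp_ratio_curve(self.TLRS, self.FLAGS, [5.0, 1.0])


class TestLooTargetAccuracy:
    def test_constructed_certainty(self):
        # every drug's nearest neighbor shares its only target
        targets = TargetTable({
            "A1": frozenset({"TA"}), "A2": frozenset({"TA"}),
            "B1": frozenset({"TB"}), "B2": frozenset({"TB"}),
        })
        tlrs = {}
        for a, b in itertools.combinations(sorted(targets.drug_ids), 2):
            same = targets.targets_of(a) == targets.targets_of(b)
            tlrs[(a, b)] = 100.0 if same else 0.1
        rows = loo_target_accuracy(tlrs, targets, [1.0, 50.0])
        for row in rows:
            assert row["accuracy"] == 1.0
            assert row["n_evaluated"] == 4

    def test_cutoff_above_all_tlrs_all_abstain(self):
        targets = TargetTable({"A": frozenset({"T"}), "B": frozenset({"T"})})
        rows = loo_target_accuracy({("A", "B"): 10.0}, targets, [100.0])
        assert rows[0]["n_abstained"] == 2
        assert np.isnan(rows[0]["accuracy"])


class TestCrossTypeCorrelation:
    def test_self_correlation(self, default_sim_mats):
        sim = default_sim_mats["gi50"]
        pcc, r2, n = cross_type_correlation(sim, sim)
        assert pcc == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert n > 100

    def test_negation(self, default_sim_mats):
        import copy

        sim = default_sim_mats["gi50"]
        neg = copy.deepcopy(sim)
        neg.values = -neg.values
        pcc, r2, _ = cross_type_correlation(sim, neg)
        assert pcc == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)


class TestScreenEnrichment:
    def test_exact_small_sample_p(self):
        # fully separated 3-vs-3: one arrangement out of C(6,3)=20
        assert screen_enrichment([1, 2, 3], [10, 11, 12],
                                 "less") == pytest.approx(1 / 20)

    def test_direction_semantics(self):
        p_lower = screen_enrichment([1, 2, 3], [10, 11, 12], "less")
        p_swapped = screen_enrichment([10, 11, 12], [1, 2, 3], "less")
        assert p_lower < 0.06
        assert p_swapped > 0.9

    def test_null_behavior(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            x = rng.normal(size=12)
            ps.append(screen_enrichment(x[:6], x[6:], "less"))
        assert np.median(ps) == pytest.approx(0.5, abs=0.1)


class TestPooledCv:
    def test_fold_order_invariance(self, default_sim_mats, default_labels):
        """Pooled held-out AUROC is a set-level quantity: scoring folds in
        any order gives the same pooled result."""
        s1, f1 = pooled_cv_tlr(default_sim_mats, default_labels,
                               channels=["gi50"], k=5, seed=3)
        s2, f2 = pooled_cv_tlr(default_sim_mats, default_labels,
                               channels=["gi50"], k=5, seed=3)
        assert np.array_equal(s1, s2) and np.array_equal(f1, f2)
        assert roc_auc(s1, f1) == roc_auc(s2, f2)
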