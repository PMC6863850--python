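"""Validation machinery for the likelihood engine and the voting layer.

Covers: stratified pair-level cross-validation with per-fold model refits
and pooled held-out scores; AUROC (Mann-Whitney half-credit form); two-
sample Kolmogorov-Smirnov separation of ST vs non-ST scores; AUROC across
every channel subset under two availability policies; true/false-positive
ratio curves across TLR cutoffs; leave-one-out voting accuracy; cross-
channel similarity correlation; and rank-sum enrichment for external
activity screens.

Cross-validation is at the *pair* level: individual drugs can appear in
both train and test folds. That leakage is inherent to pairwise evaluation
of this design and is kept as the default to match the method being
validated; ``drug_disjoint=True`` offers a stricter split.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .bayes_engine import (
    PairLabel,
    fit_models_from_matrices,
    tlr_for_pairs,
)
from .data_io import TargetTable
from .similarity import SimilarityMatrix
from .target_voting import vote_targets

logger = logging.getLogger("bandit")


@dataclass
class FoldAssignment:
    """k-fold partition of labeled pairs, class-ratio preserved per fold.

    ``pair_groups`` is set only in drug-disjoint mode: the two drugs'
    group indices per pair, used to keep training pairs fully clear of
    the test group's drugs.
    """

    labels: list[PairLabel]
    fold_of: np.ndarray  # fold index per pair (-1 = dropped)
    k: int
    seed: int
    pair_groups: np.ndarray | None = None

    def fold_pairs(self, fold: int, train: bool) -> list[PairLabel]:
        if not train:
            want = self.fold_of == fold
        elif self.pair_groups is not None:
            want = (self.pair_groups != fold).all(axis=1)
        else:
            want = self.fold_of != fold
        return [p for p, w in zip(self.labels, want) if w]


def stratified_pair_cv(labels: list[PairLabel], k: int = 5,
                       seed: int = 0,
                       drug_disjoint: bool = False) -> FoldAssignment:
    """Split labeled pairs into k folds preserving the global ST:non-ST
    ratio per fold (within one pair). Deterministic given the seed.

    With ``drug_disjoint=True`` drugs (not pairs) are partitioned into k
    groups and a pair lands in fold i only when *both* drugs belong to
    group i; cross-group pairs are dropped (fold -1). This removes the
    drug-identity leakage of pair-level CV at the cost of discarding most
    pairs, and is off by default to match the protocol being evaluated.
    """
    if drug_disjoint:
        drugs = sorted({d for p in labels for d in (p.drug_a, p.drug_b)})
        rng = np.random.default_rng(seed)
        group = dict(zip(drugs, rng.permutation(len(drugs)) % k))
        pair_groups = np.array([[group[p.drug_a], group[p.drug_b]]
                                for p in labels], dtype=int)
        fold_of = np.where(pair_groups[:, 0] == pair_groups[:, 1],
                           pair_groups[:, 0], -1)
        for fold in range(k):
            kept = fold_of == fold
            flags = [p.shared_target for p, m in zip(labels, kept) if m]
            if not any(flags) or all(flags):
                raise ValueError(
                    f"drug-disjoint fold {fold} lost a class entirely")
        return FoldAssignment(labels=labels, fold_of=fold_of, k=k, seed=seed,
                              pair_groups=pair_groups)
    y = np.array([p.shared_target for p in labels], dtype=int)
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(
                f"class {'ST' if cls else 'non-ST'} has fewer than k={k} pairs")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), y)):
        fold_of[test_idx] = fold
    return FoldAssignment(labels=labels, fold_of=fold_of, k=k, seed=seed)


def pooled_cv_tlr(sim_mats: dict[str, SimilarityMatrix],
                  labels: list[PairLabel],
                  channels: list[str] | None = None,
                  k: int = 5, seed: int = 0,
                  policy: str = "impute",
                  folds: FoldAssignment | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Held-out TLRs pooled across folds.

    For each fold the likelihood models are refit on the training pairs
    only, then the held-out pairs are scored; the five test folds are
    combined into one (scores, st_flags) pair for a single ROC curve.
    Pairs that drop out under policy="require_all" are removed from both
    arrays.
    """
    channels = channels if channels is not None else sorted(sim_mats)
    mats = {c: sim_mats[c] for c in channels}
    folds = folds if folds is not None else stratified_pair_cv(labels, k, seed)
    scores = np.full(len(labels), np.nan)
    for fold in range(folds.k):
        train = folds.fold_pairs(fold, train=True)
        models = fit_models_from_matrices(mats, train)
        test_idx = np.flatnonzero(folds.fold_of == fold)
        test_pairs = [(labels[i].drug_a, labels[i].drug_b) for i in test_idx]
        scores[test_idx] = tlr_for_pairs(models, mats, test_pairs, policy=policy)
    flags = np.array([p.shared_target for p in labels])
    keep = np.isfinite(scores)
    return scores[keep], flags[keep]


def roc_auc(scores, labels) -> float:
    """AUROC: probability a random positive outscores a random negative,
    ties credited 1/2 (the Mann-Whitney U formulation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2 credit
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class SeparationReport:
    """Two-sample KS separation of ST vs non-ST score distributions."""

    data_type: str
    d_statistic: float
    p_value: float
    n_st: int
    n_non_st: int


def ks_separation(scores_st, scores_non_st,
                  data_type: str = "TLR",
                  exact: bool = False) -> SeparationReport:
    """KS D (max absolute ECDF difference) and two-sample p-value.

    The asymptotic p-value is the default (large pair collections); pass
    ``exact=True`` for small samples.
    """
    scores_st = np.asarray(scores_st, dtype=float)
    scores_non_st = np.asarray(scores_non_st, dtype=float)
    if scores_st.size == 0 or scores_non_st.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(scores_st, scores_non_st,
                         method="exact" if exact else "asymp")
    return SeparationReport(
        data_type=data_type,
        d_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_st=scores_st.size,
        n_non_st=scores_non_st.size,
    )


def auroc_by_subsets(sim_mats: dict[str, SimilarityMatrix],
                     labels: list[PairLabel],
                     k: int = 5, seed: int = 0,
                     policies: tuple[str, ...] = ("require_all", "impute"),
                     ) -> list[dict]:
    """AUROC for every nonempty channel subset, per availability policy.

    Returns one row per (subset, policy): {"channels", "n_channels",
    "policy", "auroc", "n_pairs", "note"}. A subset with no eligible pairs
    (or a single class) is flagged in "note", never dropped. The same fold
    assignment is reused across subsets so rows are comparable.
    """
    names = sorted(sim_mats)
    folds = stratified_pair_cv(labels, k, seed)
    rows: list[dict] = []
    for m in range(1, len(names) + 1):
        for subset in itertools.combinations(names, m):
            for policy in policies:
                row = {"channels": subset, "n_channels": m, "policy": policy,
                       "auroc": np.nan, "n_pairs": 0, "note": ""}
                try:
                    scores, flags = pooled_cv_tlr(
                        sim_mats, labels, channels=list(subset),
                        policy=policy, folds=folds)
                    row["n_pairs"] = int(scores.size)
                    row["auroc"] = roc_auc(scores, flags)
                except ValueError as exc:
                    row["note"] = str(exc)
                rows.append(row)
    return rows


def mean_auroc_by_size(rows: list[dict], policy: str = "impute"
                       ) -> dict[int, float]:
    """Mean AUROC over subsets of each size, one availability policy."""
    by_size: dict[int, list[float]] = {}
    for r in rows:
        if r["policy"] == policy and np.isfinite(r["auroc"]):
            by_size.setdefault(r["n_channels"], []).append(r["auroc"])
    return {m: float(np.mean(v)) for m, v in sorted(by_size.items())}


def tp_fp_ratio_curve(tlrs, st_flags, cutoffs) -> list[dict]:
    """TP and FP counts and their ratio at each ascending TLR cutoff.

    TP = ST pairs with TLR >= cutoff, FP = non-ST pairs with TLR >= cutoff.
    With FP = 0 the ratio is reported as inf (flagged degenerate when
    TP = 0 too).
    """
    tlrs = np.asarray(tlrs, dtype=float)
    st_flags = np.asarray(st_flags, dtype=bool)
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly ascending")
    rows = []
    for c in cutoffs:
        above = tlrs >= c
        tp = int((above & st_flags).sum())
        fp = int((above & ~st_flags).sum())
        ratio = np.inf if fp == 0 else tp / fp
        rows.append({"cutoff": c, "tp": tp, "fp": fp, "ratio": ratio,
                     "degenerate": tp == 0 and fp == 0})
    return rows


def loo_target_accuracy(tlrs: dict[tuple[str, str], float],
                        targets: TargetTable,
                        cutoffs,
                        weight: str = "tlr") -> list[dict]:
    """Leave-one-out top-1 voting accuracy across TLR cutoffs.

    For each annotated drug, vote over all *other* annotated drugs (its own
    annotation is withheld) and check whether the top-voted target is among
    its known targets. Per cutoff: accuracy over non-abstaining drugs, with
    the abstention count reported separately.
    """
    drugs = targets.annotated_drugs()
    # Precompute each drug's annotated partners sorted by TLR descending;
    # per-cutoff filtering is then a prefix scan instead of a dict sweep.
    partners: dict[str, list] = {d: [] for d in drugs}
    for (a, b), tlr in tlrs.items():
        ta, tb = targets.get(a), targets.get(b)
        if a in partners and tb:
            partners[a].append((tlr, b, tb))
        if b in partners and ta:
            partners[b].append((tlr, a, ta))
    for d in partners:
        partners[d].sort(key=lambda item: (-item[0], item[1]))
    from .target_voting import SharedTargetPrediction

    rows = []
    for cutoff in cutoffs:
        n_correct = 0
        n_eval = 0
        n_abstain = 0
        for d in drugs:
            preds = [SharedTargetPrediction(query=d, partner=p, tlr=t,
                                            partner_targets=pt)
                     for t, p, pt in partners[d] if t >= cutoff]
            tally = vote_targets(preds, weight=weight)
            if tally.top_target is None:
                n_abstain += 1
                continue
            n_eval += 1
            if tally.top_target in targets.targets_of(d):
                n_correct += 1
        rows.append({
            "cutoff": cutoff,
            "accuracy": (n_correct / n_eval) if n_eval else np.nan,
            "n_evaluated": n_eval,
            "n_abstained": n_abstain,
        })
    return rows


def cross_type_correlation(sim_a: SimilarityMatrix, sim_b: SimilarityMatrix,
                           pair_mask: np.ndarray | None = None
                           ) -> tuple[float, float, int]:
    """(PCC, R^2, n) between two channels' scores over jointly defined
    pairs (optionally restricted by a boolean pair mask aligned to the
    matrices). Fewer than 3 joint pairs -> undefined (hard error)."""
    if sim_a.drug_ids != sim_b.drug_ids:
        raise ValueError("similarity matrices must share drug ordering")
    n = len(sim_a.drug_ids)
    iu = np.triu_indices(n, k=1)
    joint = sim_a.defined[iu] & sim_b.defined[iu]
    if pair_mask is not None:
        joint &= pair_mask[iu]
    va = sim_a.values[iu][joint]
    vb = sim_b.values[iu][joint]
    if va.size < 3:
        raise ValueError("fewer than 3 jointly defined pairs")
    pcc = float(stats.pearsonr(va, vb).statistic)
    return pcc, pcc ** 2, int(va.size)


def screen_enrichment(predicted_values, other_values,
                      direction: str = "less") -> float:
    """One-sided Wilcoxon rank-sum p-value comparing an activity readout
    between predicted and non-predicted targets.

    direction="less" tests predicted < other (e.g. lower percent remaining
    kinase activity means stronger predicted inhibition). The exact null
    distribution is used when sample sizes permit, matching small-sample
    enumeration (3-vs-3 fully separated gives p = 1/20).
    """
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    predicted_values = np.asarray(predicted_values, dtype=float)
    other_values = np.asarray(other_values, dtype=float)
    if predicted_values.size == 0 or other_values.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(predicted_values, other_values,
                             alternative=direction)
    return float(res.pvalue)
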