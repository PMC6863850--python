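"""Similarity scores -> likelihood ratios -> Total Likelihood Ratio.

For each evidence channel, the likelihood ratio of a similarity score s is
the fraction of shared-target (ST) drug pairs with that score divided by
the fraction of non-ST pairs with it:

    L(s) = Pr(s | ST) / Pr(s | non-ST)

Scores are binned into 20 evenly spaced intervals over the channel's
natural score range and an exponential curve L(s) = a * exp(b * s) is fit
to the per-bin ratios (least squares on log ratios at bin centers, weighted
by bin occupancy; Laplace pseudocount alpha=1 keeps empty bins finite).

Assuming the channels are close to class-conditionally independent — which
the low cross-channel correlation of the underlying measurements supports —
the evidence multiplies naive-Bayes style into a Total Likelihood Ratio:

    TLR = L(s_1) * L(s_2) * ... * L(s_n)

proportional to the odds that the pair shares a binding target. A channel
the pair lacks contributes L(m), with m the median of all observed
similarity scores of that channel; imputation happens after the
similarity-to-likelihood conversion so missing data never skews the fit.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import TargetTable
from .similarity import SimilarityMatrix

logger = logging.getLogger("bandit")

N_BINS_DEFAULT = 20
ALPHA_DEFAULT = 1.0

#: Relative slack (fraction of range width) for clamping float-noise
#: out-of-range query scores before declaring a hard error.
CLAMP_SLACK = 0.01


@dataclass(frozen=True)
class PairLabel:
    """Unordered drug pair with its shared-target class."""

    drug_a: str
    drug_b: str
    shared_target: bool

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.drug_a, self.drug_b)))


def label_pairs(drug_ids: list[str], targets: TargetTable) -> list[PairLabel]:
    """Label every unordered pair of annotated drugs as ST / non-ST.

    A pair is ST iff the two target sets intersect. Drugs absent from the
    table or annotated with an empty set are orphans, not negatives: they
    are excluded with a warning.
    """
    usable: list[str] = []
    for d in drug_ids:
        t = targets.get(d)
        if not t:
            logger.warning("label_pairs: %s has no known targets — excluded "
                           "(orphan, not a negative)", d)
            continue
        usable.append(d)
    out = [
        PairLabel(a, b, bool(targets.targets_of(a) & targets.targets_of(b)))
        for a, b in itertools.combinations(usable, 2)
    ]
    n_st = sum(p.shared_target for p in out)
    logger.info("label_pairs: %d pairs (%d ST, %d non-ST)",
                len(out), n_st, len(out) - n_st)
    return out


@dataclass
class LikelihoodModel:
    """Fitted per-channel likelihood-ratio model.

    ``bin_ratios`` are the raw per-bin ratios L_b (with pseudocount);
    ``coef_a``/``coef_b`` parameterize the smoothed curve a*exp(b*s) used
    for new cases; ``median`` is the imputation value for pairs lacking the
    channel.
    """

    data_type: str
    score_range: tuple[float, float]
    bin_edges: np.ndarray
    bin_ratios: np.ndarray
    coef_a: float
    coef_b: float
    median: float
    alpha: float

    def likelihood(self, s):
        """Smoothed likelihood ratio a*exp(b*s) at score(s) ``s``.

        Scores marginally outside the range (within 1% of its width) are
        clamped with a warning; scores far outside are a hard error.
        """
        s = np.asarray(s, dtype=float)
        lo, hi = self.score_range
        slack = CLAMP_SLACK * (hi - lo)
        if np.any(s < lo - slack) or np.any(s > hi + slack):
            raise ValueError(
                f"{self.data_type}: score outside range [{lo}, {hi}]")
        if np.any(s < lo) or np.any(s > hi):
            warnings.warn(f"{self.data_type}: clamping score(s) marginally "
                          "outside the score range", stacklevel=2)
        s = np.clip(s, lo, hi)
        out = self.coef_a * np.exp(self.coef_b * s)
        return float(out) if out.ndim == 0 else out

    @property
    def imputation_likelihood(self) -> float:
        """Likelihood contributed by this channel when a pair lacks it."""
        return float(self.likelihood(self.median))


def fit_likelihood_model(scores: np.ndarray, labels: np.ndarray,
                         data_type: str,
                         score_range: tuple[float, float],
                         n_bins: int = N_BINS_DEFAULT,
                         alpha: float = ALPHA_DEFAULT) -> LikelihoodModel:
    """Fit the binned likelihood-ratio model for one channel.

    Parameters
    ----------
    scores, labels
        Defined similarity scores of labeled pairs and their ST flags
        (True = shared target). Needs at least one score per class.
    score_range
        The channel's natural range; bins are evenly spaced over it
        regardless of the observed extremes, so "evenly spaced" means the
        same thing across datasets.
    alpha
        Laplace pseudocount added per bin in both classes: with B bins,
        L_b = [(ST_b + a) / (N_ST + aB)] / [(nonST_b + a) / (N_nonST + aB)].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_st = int(labels.sum())
    n_non = int((~labels).sum())
    if n_st == 0 or n_non == 0:
        raise ValueError(f"{data_type}: need at least one ST and one non-ST score")
    lo, hi = score_range
    edges = np.linspace(lo, hi, n_bins + 1)
    st_counts, _ = np.histogram(scores[labels], bins=edges)
    non_counts, _ = np.histogram(scores[~labels], bins=edges)
    st_frac = (st_counts + alpha) / (n_st + alpha * n_bins)
    non_frac = (non_counts + alpha) / (n_non + alpha * n_bins)
    ratios = st_frac / non_frac

    centers = 0.5 * (edges[:-1] + edges[1:])
    occupancy = (st_counts + non_counts).astype(float)
    log_ratios = np.log(ratios)
    occupied = occupancy > 0
    if occupied.sum() >= 2 and np.ptp(centers[occupied]) > 0:
        # weighted least squares on log L_b: log L = log a + b * s
        b, log_a = np.polyfit(centers[occupied], log_ratios[occupied], 1,
                              w=np.sqrt(occupancy[occupied]))
    else:
        # degenerate: a single effective bin — constant likelihood
        b = 0.0
        log_a = float(np.average(log_ratios[occupied],
                                 weights=occupancy[occupied]))
    return LikelihoodModel(
        data_type=data_type,
        score_range=(float(lo), float(hi)),
        bin_edges=edges,
        bin_ratios=ratios,
        coef_a=float(np.exp(log_a)),
        coef_b=float(b),
        median=float(np.median(scores)),
        alpha=float(alpha),
    )


def fit_models_from_matrices(sim_mats: dict[str, SimilarityMatrix],
                             labels: list[PairLabel],
                             n_bins: int = N_BINS_DEFAULT,
                             alpha: float = ALPHA_DEFAULT
                             ) -> dict[str, LikelihoodModel]:
    """Fit one likelihood model per channel from labeled pairs.

    Per channel, only pairs whose score is defined enter the fit; the
    imputation median is likewise taken over the defined labeled scores.
    """
    models: dict[str, LikelihoodModel] = {}
    for name, sim in sim_mats.items():
        idx = {d: i for i, d in enumerate(sim.drug_ids)}
        scores, flags = [], []
        for p in labels:
            i, j = idx.get(p.drug_a), idx.get(p.drug_b)
            if i is None or j is None or not sim.defined[i, j]:
                continue
            scores.append(sim.values[i, j])
            flags.append(p.shared_target)
        models[name] = fit_likelihood_model(
            np.array(scores), np.array(flags), name, sim.score_range,
            n_bins=n_bins, alpha=alpha)
    return models


@dataclass
class TLRResult:
    """Total Likelihood Ratio for one drug pair with its evidence trail.

    ``evidence`` maps channel name -> (similarity, likelihood, imputed);
    similarity is None for imputed channels (the model median was used).
    """

    drug_a: str
    drug_b: str
    tlr: float
    evidence: dict[str, tuple[float | None, float, bool]] = field(
        default_factory=dict)

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.drug_a, self.drug_b)))

    @property
    def n_observed(self) -> int:
        return sum(1 for _, _, imp in self.evidence.values() if not imp)


def total_likelihood_ratio(models: dict[str, LikelihoodModel],
                           similarities: dict[str, float | None],
                           drug_a: str = "a", drug_b: str = "b") -> TLRResult:
    """TLR of one pair: product of per-channel likelihood ratios.

    ``similarities`` maps channel -> score or None (channel unavailable for
    this pair); unavailable channels contribute the likelihood at the
    channel's median score, flagged imputed. Requires >= 1 model.
    """
    if not models:
        raise ValueError("need at least one fitted likelihood model")
    evidence: dict[str, tuple[float | None, float, bool]] = {}
    tlr = 1.0
    for name, model in models.items():
        s = similarities.get(name)
        if s is None:
            lk = model.imputation_likelihood
            evidence[name] = (None, lk, True)
        else:
            lk = float(model.likelihood(s))
            evidence[name] = (float(s), lk, False)
        tlr *= lk
    if all(imp for _, _, imp in evidence.values()):
        logger.warning("total_likelihood_ratio: %s-%s has no observed channel; "
                       "TLR is purely imputed", drug_a, drug_b)
    return TLRResult(drug_a=drug_a, drug_b=drug_b, tlr=tlr, evidence=evidence)


# ---------------------------------------------------------------------------
# Vectorized scoring over many pairs (evaluation / network workloads)
# ---------------------------------------------------------------------------

def tlr_for_pairs(models: dict[str, LikelihoodModel],
                  sim_mats: dict[str, SimilarityMatrix],
                  pairs: list[tuple[str, str]],
                  policy: str = "impute") -> np.ndarray:
    """TLRs for many pairs at once.

    policy="impute": unavailable channels contribute L(median).
    policy="require_all": pairs lacking any modeled channel get NaN.
    """
    if policy not in ("impute", "require_all"):
        raise ValueError(f"unknown availability policy {policy!r}")
    n = len(pairs)
    log_tlr = np.zeros(n)
    ok = np.ones(n, dtype=bool)
    for name, model in models.items():
        sim = sim_mats[name]
        idx = {d: i for i, d in enumerate(sim.drug_ids)}
        s = np.full(n, np.nan)
        for k, (a, b) in enumerate(pairs):
            i, j = idx.get(a), idx.get(b)
            if i is not None and j is not None and sim.defined[i, j]:
                s[k] = sim.values[i, j]
        have = np.isfinite(s)
        lk = np.empty(n)
        if have.any():
            lk[have] = model.likelihood(s[have])
        lk[~have] = model.imputation_likelihood
        if policy == "require_all":
            ok &= have
        log_tlr += np.log(lk)
    out = np.exp(log_tlr)
    if policy == "require_all":
        out[~ok] = np.nan
    return out


def all_pair_tlrs(models: dict[str, LikelihoodModel],
                  sim_mats: dict[str, SimilarityMatrix],
                  drug_ids: list[str],
                  policy: str = "impute") -> dict[tuple[str, str], float]:
    """TLR for every unordered pair of ``drug_ids`` (NaN pairs dropped)."""
    pairs = list(itertools.combinations(drug_ids, 2))
    tlrs = tlr_for_pairs(models, sim_mats, pairs, policy=policy)
    return {tuple(sorted(p)): float(t)
            for p, t in zip(pairs, tlrs) if math.isfinite(t)}
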