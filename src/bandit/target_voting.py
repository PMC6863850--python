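"""Weighted target voting: pairwise TLRs -> specific protein-target calls.

For a query molecule, every annotated drug whose pairwise TLR clears the
cutoff is a *shared-target prediction*. Each known target of those partner
drugs receives a vote weighted by the TLR of the prediction it came from;
the top-voted target is the specific-target call. A stricter filter —
cutoff 500, top target present in a strict majority of predictions, and
present in the known targets of the single highest-TLR partner — yields the
high-confidence calls used for orphan screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .data_io import TargetTable

HIGH_CONFIDENCE_TLR = 500.0


@dataclass(frozen=True)
class SharedTargetPrediction:
    """One partner drug (with known targets) predicted to share a target
    with the query."""

    query: str
    partner: str
    tlr: float
    partner_targets: frozenset[str]

    def __post_init__(self) -> None:
        if not self.partner_targets:
            raise ValueError("partner must have known targets")


@dataclass
class TargetVoteTally:
    """Ranked targets for one query with TLR-weighted vote masses.

    ``ranking`` is sorted by vote mass descending; ties broken by higher
    supporting-prediction count, then higher max supporting TLR, then
    lexical target ID (deterministic). An empty ranking is an explicit
    abstention.
    """

    query: str
    ranking: list[tuple[str, float, int]]  # (target, vote_mass, n_support)

    @property
    def top_target(self) -> str | None:
        return self.ranking[0][0] if self.ranking else None

    def vote_mass(self, target: str) -> float:
        for t, mass, _ in self.ranking:
            if t == target:
                return mass
        return 0.0


def predict_shared_targets(query: str,
                           tlrs: dict[tuple[str, str], float],
                           targets: TargetTable,
                           cutoff: float) -> list[SharedTargetPrediction]:
    """All annotated partners of ``query`` with TLR >= cutoff, TLR
    descending. ``tlrs`` maps sorted unordered pairs to TLR values; a query
    appearing in no pair is a hard error."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    found_query = False
    out: list[SharedTargetPrediction] = []
    for (a, b), tlr in tlrs.items():
        if query == a:
            partner = b
        elif query == b:
            partner = a
        else:
            continue
        found_query = True
        partner_targets = targets.get(partner)
        if not partner_targets:
            continue  # orphans cannot donate target votes
        if tlr >= cutoff:
            out.append(SharedTargetPrediction(
                query=query, partner=partner, tlr=float(tlr),
                partner_targets=partner_targets))
    if not found_query:
        raise ValueError(f"query {query!r} appears in no TLR result")
    out.sort(key=lambda p: (-p.tlr, p.partner))
    return out


def vote_targets(predictions: list[SharedTargetPrediction],
                 weight: str = "tlr") -> TargetVoteTally:
    """TLR-weighted tally of the partners' known targets.

    ``weight="tlr"`` uses the raw TLR of the supporting prediction;
    ``weight="log_tlr"`` uses log(TLR) (floored at 0) for a gentler scale.
    Each partner contributes once per target. Empty input -> abstention.
    """
    if weight not in ("tlr", "log_tlr"):
        raise ValueError(f"unknown vote weight {weight!r}")
    query = predictions[0].query if predictions else ""
    mass: dict[str, float] = {}
    count: dict[str, int] = {}
    max_tlr: dict[str, float] = {}
    for p in predictions:
        w = p.tlr if weight == "tlr" else max(0.0, math.log(p.tlr))
        for t in p.partner_targets:
            mass[t] = mass.get(t, 0.0) + w
            count[t] = count.get(t, 0) + 1
            max_tlr[t] = max(max_tlr.get(t, 0.0), p.tlr)
    ranking = sorted(
        ((t, mass[t], count[t]) for t in mass),
        key=lambda item: (-item[1], -item[2], -max_tlr[item[0]], item[0]))
    return TargetVoteTally(query=query, ranking=ranking)


def high_confidence_filter(tally: TargetVoteTally,
                           predictions: list[SharedTargetPrediction]
                           ) -> str | None:
    """Confirm the top-voted target, or abstain.

    The call stands iff the top-voted target (i) is a known target of a
    strict majority of the shared-target predictions and (ii) is among the
    known targets of the single highest-TLR prediction. ``predictions``
    must already be filtered at the operating cutoff (typically 500).
    """
    top = tally.top_target
    if top is None or not predictions:
        return None
    n_support = sum(1 for p in predictions if top in p.partner_targets)
    if n_support * 2 <= len(predictions):
        return None
    best = max(predictions, key=lambda p: p.tlr)
    if top not in best.partner_targets:
        return None
    return top
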