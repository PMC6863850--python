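"""Per-channel drug-drug similarity scores.

Five evidence channels feed the likelihood engine:

* ``gi50`` — Pearson correlation of growth-inhibition profiles across the
  60-cell-line panel, over pairwise-complete observations;
* ``cmap`` — Pearson correlation of averaged post-treatment expression
  fold-change signatures;
* ``bioassay`` — Jaccard index over shared *positive* assay outcomes,
  defined only for pairs tested in at least one common assay;
* ``sideeffect`` — Jaccard index over shared side-effect preferred terms
  (presence/absence, full vocabulary tested);
* ``structure`` — DICE coefficient over atom-pair count fingerprints
  computed from isomeric SMILES.

Undefined scores are masked, never coerced to 0: zero is a meaningful
similarity and the likelihood layer handles missingness by median
imputation, not here.

The atom-pair fingerprint uses a deliberately simple atom descriptor —
(element, heavy-neighbor count, aromatic flag) — with uncapped shortest
topological bond-path lengths, so every unit-test fingerprint can be
enumerated by hand. RDKit handles SMILES parsing and path lengths.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .data_io import (
    CHANNEL_KINDS,
    KIND_RANGES,
    BinaryFeatures,
    DrugRecord,
)

#: Minimum jointly observed conditions for a profile correlation.
MIN_SHARED_OBS = 3

AtomDescriptor = tuple[str, int, bool]
AtomPairKey = tuple[AtomDescriptor, AtomDescriptor, int]


@dataclass
class SimilarityMatrix:
    """Symmetric drug x drug scores for one data type.

    ``values`` carries NaN wherever ``defined`` is False (pair not
    computable: missing channel data, <3 shared observations, constant
    profile, empty union, no co-tested assay, two empty fingerprints).
    """

    data_type: str
    drug_ids: list[str]
    values: np.ndarray
    defined: np.ndarray
    score_range: tuple[float, float]

    def __post_init__(self) -> None:
        n = len(self.drug_ids)
        assert self.values.shape == (n, n) and self.defined.shape == (n, n)

    def index_of(self, drug_id: str) -> int:
        return self.drug_ids.index(drug_id)

    def score(self, a: str, b: str) -> float | None:
        i, j = self.index_of(a), self.index_of(b)
        return float(self.values[i, j]) if self.defined[i, j] else None

    def defined_pair_scores(self) -> np.ndarray:
        """Upper-triangle defined scores (i<j), for medians and histograms."""
        iu = np.triu_indices(len(self.drug_ids), k=1)
        vals = self.values[iu]
        return vals[self.defined[iu]]


# ---------------------------------------------------------------------------
# Per-pair primitives
# ---------------------------------------------------------------------------

def profile_pearson(x, y) -> float | None:
    """Pearson correlation over the jointly observed conditions of two
    numeric profiles; None (undefined) with <3 shared observations or a
    constant restricted profile."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    joint = np.isfinite(x) & np.isfinite(y)
    if joint.sum() < MIN_SHARED_OBS:
        return None
    xs, ys = x[joint], y[joint]
    sx = xs - xs.mean()
    sy = ys - ys.mean()
    vx = float(sx @ sx)
    vy = float(sy @ sy)
    if vx <= 0.0 or vy <= 0.0:
        return None
    r = float(sx @ sy) / math.sqrt(vx * vy)
    return float(min(1.0, max(-1.0, r)))


def binary_jaccard(a: BinaryFeatures, b: BinaryFeatures,
                   require_cotested: bool = False) -> float | None:
    """Jaccard index over shared positive features.

    In bioassay mode (``require_cotested``) the pair must have been tested
    in at least one common assay, else the score is undefined. An empty
    positives union is undefined too — there is no evidence either way.
    """
    if require_cotested and not (a.tested & b.tested):
        return None
    union = a.positives | b.positives
    if not union:
        return None
    return len(a.positives & b.positives) / len(union)


def smiles_to_atompair_fp(smiles: str) -> Counter:
    """Atom-pair count fingerprint of a molecule.

    One feature per unordered pair of heavy atoms, keyed by the two atom
    descriptors (element symbol, heavy-neighbor count, aromatic flag;
    unordered) and the shortest topological bond-path length between them.
    Hydrogens are ignored. A single-heavy-atom molecule has an empty
    fingerprint, which is legal.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    atoms = list(mol.GetAtoms())
    descriptors: list[AtomDescriptor] = [
        (a.GetSymbol(), a.GetDegree(), a.GetIsAromatic()) for a in atoms
    ]
    dist = Chem.GetDistanceMatrix(mol)
    fp: Counter = Counter()
    n = len(atoms)
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dist[i][j])
            if not np.isfinite(dist[i][j]):
                continue  # disconnected fragments carry no pair feature
            di, dj = sorted((descriptors[i], descriptors[j]))
            fp[(di, dj, d)] += 1
    return fp


def dice_similarity(fa: Counter, fb: Counter) -> float | None:
    """DICE coefficient 2*sum(min)/(|a|+|b|) between count fingerprints;
    undefined when both fingerprints are empty."""
    ta = sum(fa.values())
    tb = sum(fb.values())
    if ta + tb == 0:
        return None
    shared = sum(min(c, fb[k]) for k, c in fa.items() if k in fb)
    return 2.0 * shared / (ta + tb)


# ---------------------------------------------------------------------------
# Vectorized matrix builders
# ---------------------------------------------------------------------------

def _profile_matrix(profiles: dict[str, np.ndarray], drug_ids: list[str],
                    n_conditions: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson over all drugs via masked sufficient
    statistics (5 matrix products instead of ~n^2/2 python loops)."""
    n = len(drug_ids)
    X = np.full((n, n_conditions), np.nan)
    has = np.zeros(n, dtype=bool)
    for i, d in enumerate(drug_ids):
        if d in profiles:
            X[i] = profiles[d]
            has[i] = True
    M = np.isfinite(X)
    X0 = np.where(M, X, 0.0)
    Mf = M.astype(float)
    nobs = Mf @ Mf.T
    Sx = X0 @ Mf.T          # sum of x_i over jointly observed conditions
    Sxx = (X0 * X0) @ Mf.T
    Sxy = X0 @ X0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sx.T / nobs
        varx = Sxx - Sx**2 / nobs
        vary = varx.T
        denom = np.sqrt(varx * vary)
        r = cov / denom
    defined = (nobs >= MIN_SHARED_OBS) & (varx > 1e-12) & (vary > 1e-12)
    defined &= has[:, None] & has[None, :]
    values = np.where(defined, np.clip(r, -1.0, 1.0), np.nan)
    return values, defined


def _binary_matrix(feats: dict[str, BinaryFeatures], drug_ids: list[str],
                   require_cotested: bool) -> tuple[np.ndarray, np.ndarray]:
    vocab = sorted(set().union(*(f.positives | f.tested for f in feats.values()))
                   ) if feats else []
    vidx = {v: i for i, v in enumerate(vocab)}
    n = len(drug_ids)
    P = np.zeros((n, len(vocab)), dtype=bool)
    T = np.zeros((n, len(vocab)), dtype=bool)
    has = np.zeros(n, dtype=bool)
    for i, d in enumerate(drug_ids):
        if d in feats:
            has[i] = True
            for f in feats[d].positives:
                P[i, vidx[f]] = True
            for f in feats[d].tested:
                T[i, vidx[f]] = True
    Pf = P.astype(float)
    inter = Pf @ Pf.T
    sizes = Pf.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    defined = (union > 0) & has[:, None] & has[None, :]
    if require_cotested:
        cotested = (T.astype(float) @ T.astype(float).T) > 0
        defined &= cotested
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(defined, inter / union, np.nan)
    return values, defined


def _fingerprint_matrix(fps: dict[str, Counter], drug_ids: list[str]
                        ) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(set().union(*fps.values())) if fps else []
    kidx = {k: i for i, k in enumerate(keys)}
    n = len(drug_ids)
    C = np.zeros((n, len(keys)))
    has = np.zeros(n, dtype=bool)
    for i, d in enumerate(drug_ids):
        if d in fps:
            has[i] = True
            for k, c in fps[d].items():
                C[i, kidx[k]] = c
    totals = C.sum(axis=1)
    shared = np.empty((n, n))
    for i in range(n):  # row-wise min-sum keeps memory at O(n*f)
        shared[i] = np.minimum(C[i][None, :], C).sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    defined = (denom > 0) & has[:, None] & has[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(defined, 2.0 * shared / denom, np.nan)
    return values, defined


def build_similarity_matrix(records: list[DrugRecord], data_type: str,
                            kind: str | None = None) -> SimilarityMatrix:
    """All pairwise scores of one channel over a drug collection.

    Drugs lacking the channel get fully masked rows. ``kind`` (profile /
    binary / binary_cotested / fingerprint) is looked up from the standard
    channel registry when not given; an unknown data type without an
    explicit kind is a hard error.
    """
    if kind is None:
        if data_type not in CHANNEL_KINDS:
            raise ValueError(
                f"unknown data type {data_type!r}; pass kind= explicitly "
                f"(known: {sorted(CHANNEL_KINDS)})")
        kind = CHANNEL_KINDS[data_type]
    if kind not in KIND_RANGES:
        raise ValueError(f"unknown similarity kind {kind!r}")
    drug_ids = [r.drug_id for r in records]
    if len(set(drug_ids)) != len(drug_ids):
        raise ValueError("duplicate drug IDs in record collection")
    payloads = {r.drug_id: r.features[data_type]
                for r in records if data_type in r.features}
    if len(payloads) < 2:
        raise ValueError(
            f"data type {data_type!r} present for {len(payloads)} drugs; "
            "need at least 2")

    if kind == "profile":
        lengths = {np.asarray(p, dtype=float).shape[-1] for p in payloads.values()}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent profile lengths for {data_type!r}")
        profiles = {d: np.asarray(p, dtype=float) for d, p in payloads.items()}
        values, defined = _profile_matrix(profiles, drug_ids, lengths.pop())
    elif kind in ("binary", "binary_cotested"):
        values, defined = _binary_matrix(payloads, drug_ids,
                                         require_cotested=(kind == "binary_cotested"))
    else:  # fingerprint
        values, defined = _fingerprint_matrix(payloads, drug_ids)

    # the diagonal keeps its natural value (max of range where defined);
    # consumers use defined_pair_scores(), which excludes self-pairs
    return SimilarityMatrix(
        data_type=data_type,
        drug_ids=drug_ids,
        values=values,
        defined=defined,
        score_range=KIND_RANGES[kind],
    )
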