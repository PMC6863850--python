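"""Readers, writers and the canonical in-memory data model.

On-disk conventions (the source databases the pipeline emulates publish no
single format, so minimal standard choices are fixed here):

* target annotations — two-column TSV ``drug_id<TAB>target_id``, one row per
  association, optional ``drug_id`` header;
* numeric profiles (growth-inhibition panels, expression signatures) — CSV
  with drug IDs in the first column and condition IDs in the header; blank
  cells are missing values, never zeros;
* binary feature tables (bioassay outcomes, side-effect terms) — TSV with
  columns ``drug_id``, ``positives``, ``tested``; sets are comma-joined,
  ``*`` in ``tested`` means the full vocabulary (presence/absence data);
* structures — whitespace-delimited SMILES files (``SMILES  drug_id``);
* fingerprint count tables — CSV, drugs x feature keys (used by the
  synthetic structure channel);
* fitted likelihood models — versioned JSON with full-precision floats;
* networks — GraphML; dendrograms — Newick.

Drug identifiers are opaque strings (upstream curation is assumed to have
already collapsed database records onto a single compound identifier).
Missing numeric cells stay missing at this layer; imputation is the
likelihood layer's job.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("bandit")

MODEL_FORMAT_VERSION = 1

#: The five evidence channels and the similarity kind each one uses.
CHANNEL_KINDS: dict[str, str] = {
    "gi50": "profile",
    "cmap": "profile",
    "bioassay": "binary_cotested",
    "sideeffect": "binary",
    "structure": "fingerprint",
}

#: Natural score range per similarity kind.
KIND_RANGES: dict[str, tuple[float, float]] = {
    "profile": (-1.0, 1.0),
    "binary": (0.0, 1.0),
    "binary_cotested": (0.0, 1.0),
    "fingerprint": (0.0, 1.0),
}


class ModelFormatError(ValueError):
    """Raised when a serialized model cannot be loaded."""


@dataclass(frozen=True)
class BinaryFeatures:
    """Positive and tested feature sets for one drug in one binary channel.

    ``tested`` must contain ``positives``; for presence/absence channels
    (side effects) ``tested`` is the whole vocabulary.
    """

    positives: frozenset[str]
    tested: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positives <= self.tested:
            raise ValueError("positives must be a subset of tested")


@dataclass
class DrugRecord:
    """One small molecule: identifier, optional structure, features, targets.

    A drug whose ``targets`` set is empty is an *orphan*: it has measured
    features but no known binding target. The ``features`` mapping may omit
    any channel; absence is meaningful (masked, not zero) downstream.
    """

    drug_id: str
    smiles: str | None = None
    targets: frozenset[str] = frozenset()
    features: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be nonempty")

    @property
    def is_orphan(self) -> bool:
        return len(self.targets) == 0


class TargetTable:
    """Mapping drug_id -> set of protein identifiers.

    Lookups distinguish a drug that is *absent* from the table from a drug
    recorded with an empty target set.
    """

    def __init__(self, mapping: dict[str, frozenset[str]] | None = None):
        self._map: dict[str, frozenset[str]] = {
            k: frozenset(v) for k, v in (mapping or {}).items()
        }

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TargetTable) and self._map == other._map

    def targets_of(self, drug_id: str) -> frozenset[str]:
        """Targets of ``drug_id``; raises KeyError if the drug is absent."""
        return self._map[drug_id]

    def get(self, drug_id: str) -> frozenset[str] | None:
        return self._map.get(drug_id)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self._map)

    @property
    def all_targets(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self._map.values():
            out |= t
        return frozenset(out)

    def annotated_drugs(self) -> list[str]:
        """Drugs with at least one known target."""
        return sorted(d for d, t in self._map.items() if t)

    def items(self):
        return self._map.items()


def read_target_table(path: str | Path) -> TargetTable:
    """Read a two-column drug->target association TSV.

    Duplicate associations are deduplicated silently (logged); any row that
    does not have exactly two nonempty fields is a hard error naming the
    line number.
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    n_dupes = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() in {"drug_id", "drug"}:
                continue
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"{path}:{lineno}: malformed association row {line!r} "
                    "(expected drug_id<TAB>target_id)"
                )
            drug, target = parts[0].strip(), parts[1].strip()
            bucket = mapping.setdefault(drug, set())
            if target in bucket:
                n_dupes += 1
            bucket.add(target)
    if n_dupes:
        logger.info("read_target_table: deduplicated %d repeated associations", n_dupes)
    return TargetTable({d: frozenset(t) for d, t in mapping.items()})


def write_target_table(table: TargetTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("drug_id\ttarget_id\n")
        for drug in table.drug_ids:
            for target in sorted(table.targets_of(drug)):
                fh.write(f"{drug}\t{target}\n")


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    """Read a drugs x conditions profile CSV.

    Blank cells load as NaN (missing), never zero. Ragged rows or
    non-numeric non-blank cells are hard errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False,
                         na_values=[""], skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # ragged rows land here
        raise ValueError(f"{path}: malformed profile matrix: {exc}") from exc
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in profile matrix: {exc}") from exc
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate drug IDs in profile matrix")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_profile_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, float_format="%.17g")


def read_binary_table(path: str | Path, vocabulary: set[str] | None = None
                      ) -> dict[str, BinaryFeatures]:
    """Read a drug_id / positives / tested TSV into BinaryFeatures rows.

    ``tested == "*"`` expands to the supplied ``vocabulary`` (or, if none is
    given, to the union of every feature seen in the file).
    """
    path = Path(path)
    rows: list[tuple[str, set[str], str]] = []
    seen_features: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "drug_id":
                continue
            if len(parts) != 3 or not parts[0].strip():
                raise ValueError(
                    f"{path}:{lineno}: malformed binary-feature row "
                    "(expected drug_id<TAB>positives<TAB>tested)"
                )
            drug = parts[0].strip()
            positives = {p for p in parts[1].split(",") if p}
            tested_field = parts[2].strip()
            seen_features |= positives
            if tested_field != "*":
                seen_features |= {t for t in tested_field.split(",") if t}
            rows.append((drug, positives, tested_field))
    vocab = frozenset(vocabulary) if vocabulary is not None else frozenset(seen_features)
    out: dict[str, BinaryFeatures] = {}
    for drug, positives, tested_field in rows:
        if drug in out:
            raise ValueError(f"{path}: duplicate drug ID {drug!r}")
        tested = vocab if tested_field == "*" else frozenset(
            t for t in tested_field.split(",") if t)
        out[drug] = BinaryFeatures(frozenset(positives), frozenset(tested) | frozenset(positives))
    return out


def write_binary_table(table: dict[str, BinaryFeatures], path: str | Path,
                       full_vocabulary: set[str] | None = None) -> None:
    """Write BinaryFeatures rows; tested sets equal to ``full_vocabulary``
    are compressed to ``*``."""
    vocab = frozenset(full_vocabulary) if full_vocabulary is not None else None
    with Path(path).open("w") as fh:
        fh.write("drug_id\tpositives\ttested\n")
        for drug in sorted(table):
            bf = table[drug]
            tested = "*" if (vocab is not None and bf.tested == vocab) else ",".join(
                sorted(bf.tested))
            fh.write(f"{drug}\t{','.join(sorted(bf.positives))}\t{tested}\n")


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a whitespace-delimited SMILES file into (drug_id, smiles) pairs.

    Unparseable SMILES are skipped with a warning (never silently dropped);
    duplicate drug IDs are a hard error. Parseability is checked with RDKit.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'SMILES drug_id', got {line!r}")
            smiles, drug_id = parts[0], parts[1]
            if drug_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate drug ID {drug_id!r}")
            seen.add(drug_id)
            if Chem.MolFromSmiles(smiles) is None:
                logger.warning("%s:%d: unparseable SMILES %r for %s — skipped",
                               path, lineno, smiles, drug_id)
                continue
            out.append((drug_id, smiles))
    return out


def write_smiles_file(records: list[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for drug_id, smiles in records:
            fh.write(f"{smiles} {drug_id}\n")


def read_fingerprint_table(path: str | Path) -> dict[str, Counter]:
    """Read a drugs x feature-keys count CSV into per-drug Counters.

    Zero counts are dropped (a fingerprint is a sparse multiset)."""
    df = pd.read_csv(path, index_col=0)
    out: dict[str, Counter] = {}
    for drug, row in df.iterrows():
        out[str(drug)] = Counter(
            {str(k): int(v) for k, v in row.items() if v > 0})
    return out


def write_fingerprint_table(fps: dict[str, Counter], path: str | Path) -> None:
    keys = sorted(set().union(*fps.values())) if fps else []
    df = pd.DataFrame(
        [[fps[d].get(k, 0) for k in keys] for d in sorted(fps)],
        index=sorted(fps), columns=keys, dtype=int)
    df.index.name = "drug_id"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------

def save_models(models: dict, path: str | Path, extra: dict | None = None) -> None:
    """Serialize a collection of fitted likelihood models to versioned JSON.

    Floats are stored via ``float.hex`` so every bin edge, ratio, fit
    coefficient and median round-trips bit-exactly.
    """
    def _hex(x) -> str | None:
        return None if x is None else float(x).hex()

    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "models": {
            name: {
                "data_type": m.data_type,
                "score_range": [_hex(m.score_range[0]), _hex(m.score_range[1])],
                "bin_edges": [_hex(e) for e in m.bin_edges],
                "bin_ratios": [_hex(r) for r in m.bin_ratios],
                "coef_a": _hex(m.coef_a),
                "coef_b": _hex(m.coef_b),
                "median": _hex(m.median),
                "alpha": _hex(m.alpha),
            }
            for name, m in models.items()
        },
    }
    if extra:
        payload["provenance"] = extra
    Path(path).write_text(json.dumps(payload, indent=1))


def load_models(path: str | Path) -> dict:
    """Load models written by :func:`save_models`; bit-exact round trip."""
    from .bayes_engine import LikelihoodModel  # deferred: avoid import cycle

    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelFormatError(f"{path}: cannot parse model file: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: model format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})")

    def _unhex(s):
        return None if s is None else float.fromhex(s)

    out = {}
    for name, m in payload["models"].items():
        out[name] = LikelihoodModel(
            data_type=m["data_type"],
            score_range=(_unhex(m["score_range"][0]), _unhex(m["score_range"][1])),
            bin_edges=np.array([_unhex(e) for e in m["bin_edges"]]),
            bin_ratios=np.array([_unhex(r) for r in m["bin_ratios"]]),
            coef_a=_unhex(m["coef_a"]),
            coef_b=_unhex(m["coef_b"]),
            median=_unhex(m["median"]),
            alpha=_unhex(m["alpha"]),
        )
    return out


# ---------------------------------------------------------------------------
# Similarity matrix CSV round trip
# ---------------------------------------------------------------------------

def write_similarity_matrix(sim, path: str | Path) -> None:
    """Write one channel's similarity matrix as dense CSV plus a mask CSV
    (``<path>.mask.csv``) marking which pairs are defined."""
    path = Path(path)
    values = pd.DataFrame(sim.values, index=sim.drug_ids, columns=sim.drug_ids)
    values.index.name = "drug_id"
    values.to_csv(path, float_format="%.17g")
    mask = pd.DataFrame(sim.defined.astype(int), index=sim.drug_ids,
                        columns=sim.drug_ids)
    mask.index.name = "drug_id"
    mask.to_csv(path.with_suffix(path.suffix + ".mask.csv"))


def read_similarity_matrix(path: str | Path, data_type: str):
    from .similarity import SimilarityMatrix

    path = Path(path)
    values = pd.read_csv(path, index_col=0)
    mask = pd.read_csv(path.with_suffix(path.suffix + ".mask.csv"), index_col=0)
    kind = CHANNEL_KINDS.get(data_type, "profile")
    vals = values.to_numpy(dtype=float)
    vals[~mask.to_numpy(dtype=bool)] = np.nan
    return SimilarityMatrix(
        data_type=data_type,
        drug_ids=[str(d) for d in values.index],
        values=vals,
        defined=mask.to_numpy(dtype=bool),
        score_range=KIND_RANGES[kind],
    )


def file_sha256(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
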