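"""End-to-end orchestration of the two operating scenarios.

Scenario 1 (*screen*): scan an orphan library for molecules whose
high-confidence predicted target equals a protein of interest.
Scenario 2 (*candidate*): take one development compound and report its
ranked predicted targets with the full evidence trail.

Both scenarios run: build per-channel similarity matrices -> fit likelihood
models on annotated pairs -> score query pairs -> vote -> filter. Every run
can write a manifest (config hash, seed, package version, input checksums)
sufficient to reproduce outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .bayes_engine import (
    LikelihoodModel,
    label_pairs,
    fit_models_from_matrices,
)
from .data_io import (
    CHANNEL_KINDS,
    DrugRecord,
    TargetTable,
    file_sha256,
    read_binary_table,
    read_fingerprint_table,
    read_profile_matrix,
    read_smiles_file,
    read_target_table,
)
from .similarity import SimilarityMatrix, build_similarity_matrix, smiles_to_atompair_fp
from .target_voting import (
    HIGH_CONFIDENCE_TLR,
    SharedTargetPrediction,
    TargetVoteTally,
    high_confidence_filter,
    predict_shared_targets,
    vote_targets,
)

logger = logging.getLogger("bandit")


@dataclass
class RunConfig:
    """Operating parameters for a pipeline run."""

    channels: tuple[str, ...] = tuple(sorted(CHANNEL_KINDS))
    pair_tlr_cutoff: float = 100.0
    high_confidence_cutoff: float = HIGH_CONFIDENCE_TLR
    min_channels: int = 3     # orphan eligibility: data in >= this many channels
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel must be configured")
        if self.pair_tlr_cutoff <= 0 or self.high_confidence_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


#: Conventional filenames inside a dataset directory.
DATASET_FILES = {
    "targets": "targets.tsv",
    "gi50": "gi50.csv",
    "cmap": "cmap.csv",
    "bioassay": "bioassay.tsv",
    "sideeffect": "sideeffect.tsv",
    "smiles": "drugs.smi",
    "structure_fp": "structure_fp.csv",
}


def load_dataset(data_dir: str | Path,
                 channels: tuple[str, ...] | None = None
                 ) -> tuple[list[DrugRecord], TargetTable]:
    """Load a dataset directory (conventional filenames) into drug records.

    A channel whose file is absent is simply unavailable. Structures come
    from ``drugs.smi`` (converted to atom-pair fingerprints) or, if
    present, directly from ``structure_fp.csv``.
    """
    data_dir = Path(data_dir)
    targets_path = data_dir / DATASET_FILES["targets"]
    if not targets_path.exists():
        raise FileNotFoundError(f"missing {targets_path}")
    targets = read_target_table(targets_path)

    features: dict[str, dict[str, object]] = {}

    def feed(channel: str, payloads: dict) -> None:
        for drug, payload in payloads.items():
            features.setdefault(drug, {})[channel] = payload

    want = set(channels) if channels else set(CHANNEL_KINDS)
    for channel in ("gi50", "cmap"):
        path = data_dir / DATASET_FILES[channel]
        if channel in want and path.exists():
            df = read_profile_matrix(path)
            feed(channel, {d: df.loc[d].to_numpy() for d in df.index})
    for channel in ("bioassay", "sideeffect"):
        path = data_dir / DATASET_FILES[channel]
        if channel in want and path.exists():
            feed(channel, read_binary_table(path))
    if "structure" in want:
        fp_path = data_dir / DATASET_FILES["structure_fp"]
        smi_path = data_dir / DATASET_FILES["smiles"]
        if fp_path.exists():
            feed("structure", read_fingerprint_table(fp_path))
        elif smi_path.exists():
            feed("structure", {d: smiles_to_atompair_fp(s)
                               for d, s in read_smiles_file(smi_path)})

    drug_ids = sorted(set(features) | set(targets.drug_ids))
    records = [
        DrugRecord(drug_id=d,
                   targets=targets.get(d) or frozenset(),
                   features=features.get(d, {}))
        for d in drug_ids
    ]
    for channel in sorted(want):
        n = sum(1 for r in records if channel in r.features)
        logger.info("load_dataset: channel %-10s covers %d/%d drugs",
                    channel, n, len(records))
    return records, targets


def build_all_similarity_matrices(records: list[DrugRecord],
                                  channels: tuple[str, ...]
                                  ) -> dict[str, SimilarityMatrix]:
    """Similarity matrices for every requested channel that at least two
    drugs carry; uncomputable channels are skipped with a log entry."""
    out: dict[str, SimilarityMatrix] = {}
    for channel in channels:
        try:
            out[channel] = build_similarity_matrix(records, channel)
        except ValueError as exc:
            logger.warning("skipping channel %s: %s", channel, exc)
    return out


def fit_pipeline(records: list[DrugRecord], targets: TargetTable,
                 config: RunConfig | None = None
                 ) -> tuple[dict[str, SimilarityMatrix], dict[str, LikelihoodModel]]:
    """Similarity matrices + likelihood models fit on all annotated pairs."""
    config = config or RunConfig()
    sim_mats = build_all_similarity_matrices(records, config.channels)
    labels = label_pairs([r.drug_id for r in records], targets)
    models = fit_models_from_matrices(sim_mats, labels)
    return sim_mats, models


def n_channels_of(record: DrugRecord, channels: tuple[str, ...]) -> int:
    return sum(1 for c in channels if c in record.features)


def query_pair_tlrs(query: str, partners: list[str],
                    models: dict[str, LikelihoodModel],
                    sim_mats: dict[str, SimilarityMatrix]
                    ) -> dict[tuple[str, str], float]:
    """TLRs of ``query`` against each partner (median imputation policy)."""
    from .bayes_engine import tlr_for_pairs

    pairs = [(query, p) for p in partners if p != query]
    tlrs = tlr_for_pairs(models, sim_mats, pairs)
    return {tuple(sorted(p)): float(t) for p, t in zip(pairs, tlrs)}


@dataclass
class CandidateReport:
    """Scenario-2 output: full tally + supporting evidence for one query."""

    query: str
    tally: TargetVoteTally
    predictions: list[SharedTargetPrediction]
    confirmed_target: str | None
    imputed_channels: tuple[str, ...]


def run_candidate(query: str,
                  records: list[DrugRecord],
                  targets: TargetTable,
                  sim_mats: dict[str, SimilarityMatrix],
                  models: dict[str, LikelihoodModel],
                  config: RunConfig | None = None) -> CandidateReport:
    """Predict targets for a single development candidate."""
    config = config or RunConfig()
    record = next((r for r in records if r.drug_id == query), None)
    if record is None or n_channels_of(record, config.channels) == 0:
        raise ValueError(f"query {query!r} has no data in any configured channel")
    annotated = targets.annotated_drugs()
    partners = [d for d in annotated if d != query]
    tlrs = query_pair_tlrs(query, partners, models, sim_mats)
    predictions = predict_shared_targets(query, tlrs, targets,
                                         config.pair_tlr_cutoff)
    tally = vote_targets(predictions)
    hc_preds = [p for p in predictions if p.tlr >= config.high_confidence_cutoff]
    confirmed = high_confidence_filter(vote_targets(hc_preds), hc_preds)
    imputed = tuple(sorted(c for c in models if c not in record.features))
    return CandidateReport(query=query, tally=tally, predictions=predictions,
                           confirmed_target=confirmed,
                           imputed_channels=imputed)


def run_screen(target_of_interest: str,
               records: list[DrugRecord],
               targets: TargetTable,
               sim_mats: dict[str, SimilarityMatrix],
               models: dict[str, LikelihoodModel],
               config: RunConfig | None = None
               ) -> list[tuple[str, float]]:
    """Scenario 1: orphans whose confirmed high-confidence predicted target
    equals ``target_of_interest``, ranked by vote mass descending.

    Only orphans with data in at least ``config.min_channels`` channels are
    eligible. An unknown target is a hard error listing the nearest IDs.
    """
    config = config or RunConfig()
    known = sorted(targets.all_targets)
    if target_of_interest not in known:
        near = difflib.get_close_matches(target_of_interest, known, n=5)
        raise ValueError(
            f"unknown target {target_of_interest!r}; nearest known: {near}")
    eligible = [r for r in records
                if r.is_orphan
                and n_channels_of(r, config.channels) >= config.min_channels]
    annotated = targets.annotated_drugs()
    hits: list[tuple[str, float]] = []
    for orphan in eligible:
        tlrs = query_pair_tlrs(orphan.drug_id, annotated, models, sim_mats)
        preds = predict_shared_targets(orphan.drug_id, tlrs, targets,
                                       config.high_confidence_cutoff)
        tally = vote_targets(preds)
        confirmed = high_confidence_filter(tally, preds)
        if confirmed == target_of_interest:
            hits.append((orphan.drug_id, tally.vote_mass(confirmed)))
    if not hits:
        logger.warning("run_screen: no orphan confirmed for %s at cutoff %g",
                       target_of_interest, config.high_confidence_cutoff)
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def write_manifest(out_dir: str | Path, config: RunConfig, seed: int,
                   inputs: dict[str, str | Path]) -> Path:
    """Reproducibility manifest: config hash, seed, version, input digests."""
    cfg = dataclasses.asdict(config)
    cfg["channels"] = list(cfg["channels"])
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "inputs": {name: {"path": str(p), "sha256": file_sha256(p)}
                   for name, p in inputs.items() if Path(p).exists()},
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
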