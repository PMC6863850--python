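"""Synthetic drug universes with planted targets for end-to-end testing.

The generator emulates the statistical structure the evidence-integration
method relies on, with fully known ground truth:

* each protein target carries an independent latent signature per channel
  (a latent profile vector for the growth-inhibition and expression
  channels, a latent positive-feature set for the bioassay and side-effect
  channels, a latent fingerprint count template for the structure channel);
* each drug's channel payload mixes its targets' signatures at a
  configurable signal strength and adds independent noise, so pairs that
  share a target are stochastically more similar in every channel while the
  channels stay class-conditionally independent (the naive-Bayes regime);
* orphan drugs get payloads but their planted targets are withheld from the
  emitted annotation table (kept in the truth table for scoring);
* per-channel missingness removes whole payloads; the growth-inhibition
  panel additionally gets sparse per-cell gaps.

The structure channel is generated directly as fingerprint count vectors
(latent template + insertion/deletion noise) rather than as synthetic
SMILES: generating molecules with controlled pairwise DICE similarity is a
research problem of its own, and the real-SMILES fixtures below cover the
SMILES-to-fingerprint path.

Signal strength 0 in a channel makes it pure noise; 0.8 (the default) gives
the strong separation regime the acceptance properties are stated in.
Regeneration from the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bayes_engine import PairLabel
from .data_io import (
    BinaryFeatures,
    DrugRecord,
    TargetTable,
    write_binary_table,
    write_fingerprint_table,
    write_profile_matrix,
    write_target_table,
)

CHANNELS = ("gi50", "cmap", "bioassay", "sideeffect", "structure")


@dataclass(frozen=True)
class UniverseConfig:
    """Knobs of the synthetic universe (defaults = the stated test world).

    ``signal`` is the per-channel signal strength in [0, 1]: the
    probability/weight with which a drug inherits its targets' latent
    signature in that channel. ``mechanism_split`` plants two
    sub-mechanisms inside the first target (partially overlapping
    signatures) for mechanism-clustering tests.
    """

    n_drugs: int = 200
    n_targets: int = 10
    extra_targets_rate: float = 0.3      # targets per drug = 1 + Poisson(rate)
    orphan_fraction: float = 0.15
    signal: float | dict[str, float] = 0.8
    missingness: float | dict[str, float] = 0.10
    n_cell_lines: int = 60               # growth-inhibition panel width
    n_genes: int = 978                   # expression-signature width
    n_assays: int = 500
    n_side_effects: int = 300
    n_fp_keys: int = 400
    assay_tested_fraction: float = 0.6
    latent_feature_rate: float = 0.15    # binary channels
    background_positive_rate: float = 0.05
    fp_latent_rate: float = 0.10
    fp_background_rate: float = 0.03
    fp_template_extra_counts: float = 2.0
    gi50_cell_missingness: float = 0.05
    mechanism_split: bool = False
    mechanism_overlap: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 2 or self.n_targets < 1:
            raise ValueError("need n_drugs >= 2 and n_targets >= 1")
        for name, frac in [("orphan_fraction", self.orphan_fraction),
                           ("assay_tested_fraction", self.assay_tested_fraction),
                           ("latent_feature_rate", self.latent_feature_rate),
                           ("background_positive_rate", self.background_positive_rate),
                           ("gi50_cell_missingness", self.gi50_cell_missingness),
                           ("mechanism_overlap", self.mechanism_overlap)]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for ch in CHANNELS:
            if not 0.0 <= self.signal_for(ch) <= 1.0:
                raise ValueError(f"signal for {ch} must be in [0, 1]")
            if not 0.0 <= self.missingness_for(ch) <= 1.0:
                raise ValueError(f"missingness for {ch} must be in [0, 1]")

    def signal_for(self, channel: str) -> float:
        if isinstance(self.signal, dict):
            return float(self.signal.get(channel, 0.8))
        return float(self.signal)

    def missingness_for(self, channel: str) -> float:
        if isinstance(self.missingness, dict):
            return float(self.missingness.get(channel, 0.0))
        return float(self.missingness)


@dataclass
class SyntheticUniverse:
    """Generated drugs plus the planted ground truth.

    ``target_table`` holds only the annotations an analyst would see
    (orphans withheld); ``truth`` holds every planted assignment.
    ``mechanism_of`` labels drugs of the split target with their planted
    sub-mechanism.
    """

    records: list[DrugRecord]
    target_table: TargetTable
    truth: TargetTable
    mechanism_of: dict[str, str]
    config: UniverseConfig

    @property
    def drug_ids(self) -> list[str]:
        return [r.drug_id for r in self.records]

    @property
    def orphan_ids(self) -> list[str]:
        return [r.drug_id for r in self.records if r.is_orphan]

    def record(self, drug_id: str) -> DrugRecord:
        return next(r for r in self.records if r.drug_id == drug_id)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """One splittable stream per generation stage, so adding a channel
    never perturbs another channel's draws."""
    names = ("assign", "orphans", "mechanism", "gi50", "cmap", "bioassay",
             "sideeffect", "structure", "missing")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_universe(config: UniverseConfig) -> SyntheticUniverse:
    """Generate a complete universe from a config (deterministic)."""
    rngs = _rngs(config.seed)
    n, t = config.n_drugs, config.n_targets
    drug_ids = [f"D{i:04d}" for i in range(n)]
    target_ids = [f"T{i:02d}" for i in range(t)]

    # --- planted target assignments -----------------------------------
    rng = rngs["assign"]
    assignments: dict[str, frozenset[str]] = {}
    for d in drug_ids:
        k = min(t, 1 + rng.poisson(config.extra_targets_rate))
        chosen = rng.choice(target_ids, size=k, replace=False)
        assignments[d] = frozenset(str(t_id) for t_id in chosen)

    # --- sub-mechanisms within the first target -----------------------
    mechanism_of: dict[str, str] = {}
    if config.mechanism_split:
        rng = rngs["mechanism"]
        split_target = target_ids[0]
        carriers = [d for d in drug_ids if split_target in assignments[d]]
        for d in carriers:
            mechanism_of[d] = "A" if rng.random() < 0.5 else "B"

    # --- latent signatures per channel --------------------------------
    def profile_latents(rng: np.random.Generator, dim: int) -> dict[str, np.ndarray]:
        lat = {tid: rng.standard_normal(dim) for tid in target_ids}
        if config.mechanism_split:
            za = lat[target_ids[0]]
            rho = config.mechanism_overlap
            lat["__B__"] = rho * za + np.sqrt(1 - rho**2) * rng.standard_normal(dim)
        return lat

    def set_latents(rng: np.random.Generator, vocab: list[str], rate: float
                    ) -> dict[str, frozenset[str]]:
        lat = {tid: frozenset(v for v in vocab if rng.random() < rate)
               for tid in target_ids}
        if config.mechanism_split:
            base = sorted(lat[target_ids[0]])
            keep = frozenset(v for v in base
                             if rng.random() < config.mechanism_overlap)
            fresh = frozenset(v for v in vocab
                              if v not in lat[target_ids[0]]
                              and rng.random() < rate * (1 - config.mechanism_overlap))
            lat["__B__"] = keep | fresh
        return lat

    def count_latents(rng: np.random.Generator, keys: list[str]
                      ) -> dict[str, dict[str, int]]:
        def draw() -> dict[str, int]:
            return {k: 1 + int(rng.poisson(config.fp_template_extra_counts))
                    for k in keys if rng.random() < config.fp_latent_rate}
        lat = {tid: draw() for tid in target_ids}
        if config.mechanism_split:
            base = lat[target_ids[0]]
            kept = {k: c for k, c in base.items()
                    if rng.random() < config.mechanism_overlap}
            fresh = {k: 1 + int(rng.poisson(config.fp_template_extra_counts))
                     for k in keys
                     if k not in base
                     and rng.random() < config.fp_latent_rate
                     * (1 - config.mechanism_overlap)}
            lat["__B__"] = {**fresh, **kept}
        return lat

    def latent_key(drug: str, target: str) -> str:
        if (config.mechanism_split and target == target_ids[0]
                and mechanism_of.get(drug) == "B"):
            return "__B__"
        return target

    # --- profile channels ---------------------------------------------
    def profile_payloads(channel: str, dim: int) -> dict[str, np.ndarray]:
        rng = rngs[channel]
        lat = profile_latents(rng, dim)
        s = config.signal_for(channel)
        out = {}
        for d in drug_ids:
            tids = sorted(assignments[d])
            base = sum(lat[latent_key(d, tid)] for tid in tids) / np.sqrt(len(tids))
            out[d] = s * base + np.sqrt(max(0.0, 1 - s**2)) * rng.standard_normal(dim)
        return out

    gi50 = profile_payloads("gi50", config.n_cell_lines)
    cmap = profile_payloads("cmap", config.n_genes)

    # sparse per-cell gaps in the growth-inhibition panel
    rng = rngs["gi50"]
    if config.gi50_cell_missingness > 0:
        for d in drug_ids:
            holes = rng.random(config.n_cell_lines) < config.gi50_cell_missingness
            gi50[d] = np.where(holes, np.nan, gi50[d])

    # --- binary channels ----------------------------------------------
    def binary_payloads(channel: str, vocab_size: int, full_tested: bool
                        ) -> dict[str, BinaryFeatures]:
        rng = rngs[channel]
        vocab = [f"{channel[:2].upper()}{i:04d}" for i in range(vocab_size)]
        lat = set_latents(rng, vocab, config.latent_feature_rate)
        s = config.signal_for(channel)
        full = frozenset(vocab)
        out = {}
        for d in drug_ids:
            inherited: set[str] = set()
            for tid in sorted(assignments[d]):
                for v in sorted(lat[latent_key(d, tid)]):
                    if rng.random() < s:
                        inherited.add(v)
            background = {v for v in vocab
                          if rng.random() < config.background_positive_rate}
            positives = frozenset(inherited | background)
            if full_tested:
                tested = full
            else:
                tested = frozenset(
                    v for v in vocab
                    if rng.random() < config.assay_tested_fraction) | positives
            out[d] = BinaryFeatures(positives=positives, tested=tested)
        return out

    bioassay = binary_payloads("bioassay", config.n_assays, full_tested=False)
    sideeffect = binary_payloads("sideeffect", config.n_side_effects,
                                 full_tested=True)

    # --- structure channel (fingerprint count vectors) ----------------
    rng = rngs["structure"]
    keys = [f"K{i:04d}" for i in range(config.n_fp_keys)]
    lat_counts = count_latents(rng, keys)
    s = config.signal_for("structure")
    structure: dict[str, Counter] = {}
    for d in drug_ids:
        fp: Counter = Counter()
        for tid in sorted(assignments[d]):
            for k, c in sorted(lat_counts[latent_key(d, tid)].items()):
                if rng.random() < s:
                    fp[k] += c
        for k in keys:
            if rng.random() < config.fp_background_rate:
                fp[k] += 1 + int(rng.poisson(1.0))
        structure[d] = fp

    payloads: dict[str, dict] = {"gi50": gi50, "cmap": cmap,
                                 "bioassay": bioassay,
                                 "sideeffect": sideeffect,
                                 "structure": structure}

    # --- whole-payload missingness ------------------------------------
    rng = rngs["missing"]
    for channel in CHANNELS:
        miss = config.missingness_for(channel)
        dropped = [d for d in drug_ids if rng.random() < miss]
        if len(drug_ids) - len(dropped) < 2:  # keep the channel computable
            dropped = dropped[: len(drug_ids) - 2]
        for d in dropped:
            del payloads[channel][d]

    # --- orphans -------------------------------------------------------
    rng = rngs["orphans"]
    n_orphans = int(round(config.orphan_fraction * n))
    orphans = ({str(d) for d in rng.choice(drug_ids, size=n_orphans,
                                           replace=False)}
               if n_orphans else set())

    records = []
    for d in drug_ids:
        features = {ch: payloads[ch][d] for ch in CHANNELS if d in payloads[ch]}
        records.append(DrugRecord(
            drug_id=d,
            targets=frozenset() if d in orphans else assignments[d],
            features=features))
    target_table = TargetTable({d: assignments[d] for d in drug_ids
                                if d not in orphans})
    truth = TargetTable(dict(assignments))
    return SyntheticUniverse(records=records, target_table=target_table,
                             truth=truth, mechanism_of=mechanism_of,
                             config=config)


def planted_pair_labels(universe: SyntheticUniverse) -> list[PairLabel]:
    """ST / non-ST labels from the full planted truth (orphans included),
    for scoring predictions against ground truth."""
    ids = universe.drug_ids
    truth = universe.truth
    return [
        PairLabel(a, b, bool(truth.targets_of(a) & truth.targets_of(b)))
        for a, b in itertools.combinations(ids, 2)
    ]


def expected_st_fraction(config: UniverseConfig, tail: int = 60) -> float:
    """Closed-form probability two independently assigned drugs share at
    least one target under the (1 + Poisson) assignment model."""
    from math import comb, exp, factorial

    t = config.n_targets
    lam = config.extra_targets_rate

    def pmf(k: int) -> float:  # targets-per-drug = min(t, 1 + Poisson(lam))
        if k < 1 or k > t:
            return 0.0
        p = exp(-lam) * lam ** (k - 1) / factorial(k - 1)
        if k == t:  # capped mass
            p = 1.0 - sum(exp(-lam) * lam ** j / factorial(j)
                          for j in range(t - 1))
        return p

    total = 0.0
    for k1 in range(1, t + 1):
        for k2 in range(1, t + 1):
            if comb(t, k2) == 0:
                continue
            p_disjoint = comb(t - k1, k2) / comb(t, k2) if t - k1 >= k2 else 0.0
            total += pmf(k1) * pmf(k2) * (1.0 - p_disjoint)
    return total


def mechanism_universe_config(seed: int = 7, n_drugs: int = 60) -> UniverseConfig:
    """Config for the mechanism-clustering scenario.

    Emulates a curated mechanism study: a set of well-characterized drugs
    that all bind one target class and split into two sub-mechanisms
    (e.g. microtubule stabilizers vs destabilizers), plus a second target's
    drugs as the non-shared-target background the likelihood fit needs.
    Drugs are single-target (the clustered class is defined by its target)
    and fully covered in every channel (curated sets are well annotated):
    mechanism recovery from 1/TLR distances is exquisitely sensitive to a
    single weak pair, so coverage gaps or polypharmacology in the clustered
    set test coverage robustness, not the clustering machinery.
    """
    return UniverseConfig(
        n_drugs=n_drugs, n_targets=2, extra_targets_rate=0.0,
        orphan_fraction=0.0, missingness=0.0, mechanism_split=True,
        seed=seed)


def structure_fixture_set() -> list[tuple[str, str]]:
    """Small real molecules with hand-checkable atom-pair fingerprints."""
    return [
        ("methane", "C"),
        ("ethane", "CC"),
        ("propane", "CCC"),
        ("butane", "CCCC"),
        ("benzene", "c1ccccc1"),
        ("toluene", "Cc1ccccc1"),
        ("ethanol", "CCO"),
    ]


def write_universe(universe: SyntheticUniverse, out_dir: str | Path) -> None:
    """Write the universe in the pipeline's on-disk formats, truth under
    ``truth/``, plus a config echo for provenance."""
    import pandas as pd

    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    cfg = universe.config
    write_target_table(universe.target_table, out / "targets.tsv")
    write_target_table(universe.truth, out / "truth" / "targets_truth.tsv")
    if universe.mechanism_of:
        with (out / "truth" / "mechanisms.tsv").open("w") as fh:
            fh.write("drug_id\tmechanism\n")
            for d in sorted(universe.mechanism_of):
                fh.write(f"{d}\t{universe.mechanism_of[d]}\n")

    for channel, width, prefix in [("gi50", cfg.n_cell_lines, "CL"),
                                   ("cmap", cfg.n_genes, "G")]:
        rows = {r.drug_id: r.features[channel] for r in universe.records
                if channel in r.features}
        df = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=[f"{prefix}{i:04d}" for i in range(width)])
        df.index.name = "drug_id"
        write_profile_matrix(df, out / f"{channel}.csv")

    for channel, vocab_size, vprefix in [("bioassay", cfg.n_assays, "BI"),
                                         ("sideeffect", cfg.n_side_effects, "SI")]:
        table = {r.drug_id: r.features[channel] for r in universe.records
                 if channel in r.features}
        vocab = {f"{vprefix}{i:04d}" for i in range(vocab_size)}
        write_binary_table(table, out / f"{channel}.tsv", full_vocabulary=vocab)

    fps = {r.drug_id: r.features["structure"] for r in universe.records
           if "structure" in r.features}
    write_fingerprint_table(fps, out / "structure_fp.csv")

    echo = dataclasses.asdict(cfg)
    (out / "generation_log.json").write_text(json.dumps(echo, indent=1))

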