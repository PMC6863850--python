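"""Shared fixtures: synthetic universes at the sizes the test tiers need.

Session scope keeps the expensive 200-drug universe (similarity matrices,
labels) shared across evaluation and acceptance tests.
"""

from __future__ import annotations

import logging

import pytest
from hypothesis import settings

from bandit.bayes_engine import label_pairs

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from bandit.pipeline import build_all_similarity_matrices
from bandit.synthetic_data import UniverseConfig, generate_universe

logging.getLogger("bandit").setLevel(logging.ERROR)

ALL_CHANNELS = ("bioassay", "cmap", "gi50", "sideeffect", "structure")


@pytest.fixture(scope="session")
def default_universe():
    """The 200-drug, five-channel, signal-0.8 universe (the stated world)."""
    return generate_universe(UniverseConfig(seed=7))


@pytest.fixture(scope="session")
def default_sim_mats(default_universe):
    return build_all_similarity_matrices(default_universe.records, ALL_CHANNELS)


@pytest.fixture(scope="session")
def default_labels(default_universe):
    """ST/non-ST labels over the annotated (non-orphan) drugs."""
    return label_pairs(default_universe.drug_ids,
                       default_universe.target_table)


@pytest.fixture(scope="session")
def small_universe():
    """A 60-drug universe for cheaper unit-level checks."""
    return generate_universe(UniverseConfig(n_drugs=60, n_targets=5, seed=11))
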