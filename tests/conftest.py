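"""Shared fixtures: published tables and cached synthetic bundles."""

from __future__ import annotations

import pytest

from mitocomparator import datasets, synthetic_data as syn


@pytest.fixture(scope="session")
def calanus_table():
    return datasets.calanus_feature_table()


@pytest.fixture(scope="session")
def declared_claims():
    return datasets.calanus_declared_claims()


@pytest.fixture(scope="session")
def divergence_table():
    return datasets.copepod_divergence_table()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One study-shaped annotated genome with sequence (seed fixed)."""
    return syn.gen_annotated_genome(seed=11)


@pytest.fixture(scope="session")
def population_bundle(synthetic_genome):
    """(alignment, truth) for the default population configuration."""
    return syn.gen_population_alignment(reference=synthetic_genome, seed=11)
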