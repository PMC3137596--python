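"""Shared fixtures: tiny hand-built proteins and synthetic datasets."""

from __future__ import annotations

import pytest
from hypothesis import settings

from snopred.sequence_io import (
    ProteinRecord,
    SiteAnnotation,
    build_dataset,
    extract_window,
)
from snopred.synthetic import PlantedRule, SyntheticSpec, generate

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def toy_protein() -> ProteinRecord:
    # cysteines at 1-based positions 6, 11, 17
    return ProteinRecord(id="P1", sequence="MKALWCDDEHCRKFAGCLLV")


@pytest.fixture
def toy_dataset(toy_protein):
    # one annotated site; the other two cysteines become negatives
    annos = [SiteAnnotation("P1", 6)]
    return build_dataset([toy_protein], annos, n=5)


@pytest.fixture
def toy_windows(toy_protein):
    return [
        extract_window(toy_protein, pos, 5)
        for pos in toy_protein.cysteine_positions()
    ]


@pytest.fixture(scope="session")
def planted_dataset():
    """Medium synthetic dataset with one strong dependent motif."""
    spec = SyntheticSpec(
        n_proteins=120,
        n_positives=240,
        rules=(PlantedRule(-2, "basic", 0.9, partner=(3, "acid")),),
        seed=11,
    )
    dataset, manifest = generate(spec)
    return dataset, manifest


@pytest.fixture(scope="session")
def null_dataset():
    """Synthetic dataset with no planted structure at all."""
    spec = SyntheticSpec(
        n_proteins=100, n_positives=200, rules=(), asa_model=None, seed=5
    )
    dataset, manifest = generate(spec)
    return dataset, manifest
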