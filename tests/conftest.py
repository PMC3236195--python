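from __future__ import annotations

import random

import pytest

from panorth.align import AlignmentEngine
from panorth.pipeline import run_pipeline
from panorth.simulate import AA, CladeSpec, simulate_clade


@pytest.fixture
def engine():
    return AlignmentEngine()


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


@pytest.fixture(scope="session")
def small_clade():
    """A cheap clade (2 genera x 2 species x 2 genomes, 30 ancestral genes)
    for structural tests."""
    return simulate_clade(
        CladeSpec(n_genes=30, length_range=(40, 80), seed=7)
    )


@pytest.fixture(scope="session")
def small_clade_run(small_clade):
    engine = AlignmentEngine()
    result = run_pipeline(
        small_clade.genomes, small_clade.taxonomy, small_clade.cds_map, engine
    )
    return small_clade, result, engine
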