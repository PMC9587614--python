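"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import pytest

from ltdrscan.config import RunConfig
from ltdrscan.core import GenomeSequence
from ltdrscan.simulate import (
    ElementModel,
    SimulationConfig,
    make_element,
    simulate_dataset,
)


def part_library(models) -> list[GenomeSequence]:
    records = []
    for m in models:
        records.append(GenomeSequence(f"{m.family_id}:LTDR", m.ltdr_seq))
        records.append(GenomeSequence(f"{m.family_id}:INT", m.int_seq))
    return records


@pytest.fixture(scope="session")
def small_model() -> ElementModel:
    return make_element("FAM450", ltdr_len=473, int_len=1691, tir_len=14, tsd_len=4, seed=7)


@pytest.fixture(scope="session")
def mixed_dataset():
    """~13 insertions of every architecture at divergence 0 on 150 kb."""
    cfg = SimulationConfig(
        genome_length=150_000,
        divergence=0.0,
        min_spacing=1_500,
        counts={
            "MONOMER": 3,
            "SOLO_LTDR": 3,
            "MULTIMER_SHARED": 2,
            "TANDEM_INT": 2,
            "LTDR_INT": 1,
            "INT_LTDR": 1,
            "SOLO_INT": 1,
        },
    )
    genomes, truths, models = simulate_dataset(cfg, seed=5)
    return genomes, truths, models, part_library(models)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()
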