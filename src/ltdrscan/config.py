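"""Flat run configuration: every tunable of the pipeline in one place.

Serialized as a flat YAML mapping; unknown keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from ltdrscan.errors import ConfigError
from ltdrscan.simulate import SimulationConfig


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Simulation fields describe the planted study conditions; scanning,
    classification, consensus and footprint fields mirror the parameters
    documented on the corresponding functions.
    """

    seed: int = 0
    out_dir: str = "ltdrscan_out"

    # simulation
    genome_length: int = 2_000_000
    gc: float = 0.36
    divergence: float = 0.02
    min_spacing: int = 2_000
    count_monomer: int = 25
    count_solo_ltdr: int = 30
    count_multimer: int = 15
    count_tandem_int: int = 6
    count_ltdr_int: int = 10
    count_int_ltdr: int = 10
    count_solo_int: int = 4
    multimer_n_max: int = 4
    random_strand: bool = True

    # scanning
    scan_min_identity: float = 0.75
    scan_min_coverage: float = 0.5
    scan_word_size: int = 12
    merge_max_gap: int = 30

    # locus clustering / classification
    locus_gap: int = 200
    flank_len: int = 50
    tsd_k_min: int = 3
    tsd_k_max: int = 6
    tsd_max_mismatch: int = 0

    # consensus building
    cluster_min_identity: float = 0.75
    cluster_min_coverage: float = 0.75
    consensus_flank: int = 5_000
    consensus_max_rounds: int = 10
    consensus_max_copies: int = 10
    consensus_support_threshold: float = 0.7
    consensus_drop_run: int = 20
    termini_search: int = 10

    # footprints
    footprint_flank_len: int = 100
    footprint_max_deleted: int = 5

    def simulation(self) -> SimulationConfig:
        return SimulationConfig(
            genome_length=self.genome_length,
            gc=self.gc,
            divergence=self.divergence,
            min_spacing=self.min_spacing,
            counts={
                "MONOMER": self.count_monomer,
                "SOLO_LTDR": self.count_solo_ltdr,
                "MULTIMER_SHARED": self.count_multimer,
                "TANDEM_INT": self.count_tandem_int,
                "LTDR_INT": self.count_ltdr_int,
                "INT_LTDR": self.count_int_ltdr,
                "SOLO_INT": self.count_solo_int,
            },
            multimer_n_max=self.multimer_n_max,
            random_strand=self.random_strand,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
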