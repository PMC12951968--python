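"""Pipeline configuration with the published thresholds as defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class Config:
    """Tunable thresholds of the protocol.

    Defaults reproduce the published contract: clusters and hotspots count
    as tunable when within 5 Å of a functional site; cluster inclusion at
    5% significance with a highly-significant tier at 0.5%; conserved-site
    prediction gated at conservation > 0.9 in alignments with DOPS > 70;
    Grantham impact tiers above the matrix median (64) and upper quartile
    (109); polymorphism zeroing above population VAF 1e-7; duplication
    timing split at mutation copy number 1.5; FIE retention at total score
    >= 3; diversity extrapolation to 2n with 200 bootstrap replicates.
    """

    site_distance_cutoff: float = 5.0
    cluster_sig: float = 0.05
    cluster_high_sig: float = 0.005
    conservation_threshold: float = 0.9
    dops_threshold: float = 70.0
    hotspot_min_patients: int = 2
    grantham_medium: int = 64
    grantham_high: int = 109
    polymorphism_vaf: float = 1e-7
    timing_cn_threshold: float = 1.5
    fie_score_threshold: int = 3
    extrapolation_factor: int = 2
    bootstrap_reps: int = 200
    cluster_radius: float = 5.0
    n_permutations: int = 999
    min_plddt: Optional[float] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "site_distance_cutoff cluster_sig cluster_high_sig "
            "conservation_threshold dops_threshold hotspot_min_patients "
            "grantham_medium grantham_high polymorphism_vaf "
            "timing_cn_threshold fie_score_threshold extrapolation_factor "
            "bootstrap_reps cluster_radius n_permutations"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.cluster_high_sig >= self.cluster_sig:
            raise ValueError("cluster_high_sig must be below cluster_sig")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))
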