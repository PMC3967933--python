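"""Pipeline configuration with paper-grade defaults and YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chimera_detection import FilterConfig
from .junction_support import JunctionCriteria


@dataclass
class PipelineConfig:
    """All tunable thresholds of the discovery workflow.

    Defaults follow the published workflow where it states a value (Q15
    quality trimming, 45 bp minimum read length, >=2 supporting pairs,
    5 bp clonal-duplicate separation, 0 transcriptome-tier mismatches for
    chimeric pairs, junction criteria 6/2/0, alpha 0.05); the remainder
    (predominance 0.8, homology k=31 at 0.05, 100 kb neighbor gap,
    genome-tier tolerance 2) are surfaced here because the workflow
    leaves them unquantified.
    """

    # read QC
    min_quality: int = 15
    min_length: int = 45
    # mapping
    seed_length: int = 16
    transcriptome_max_mismatches: int = 0
    genome_max_mismatches: int = 2
    # filter cascade
    min_support: int = 2
    min_separation: int = 5
    predominance_threshold: float = 0.8
    homology_k: int = 31
    homology_threshold: float = 0.05
    neighbor_max_gap: int = 100_000
    # junction criteria
    junction_min_flank: int = 6
    junction_max_mismatches: int = 2
    junction_flank_mismatch_allowance: int = 0
    # cohort selection / stats
    selection_min_samples: int = 2
    selection_min_pairs: int = 3
    alpha: float = 0.05
    # simulation
    sim_n_chrom: int = 3
    sim_genes_per_chrom: int = 3
    sim_exons_per_gene: tuple[int, int] = (2, 5)
    sim_read_length: int = 75
    sim_fragment_mean: float = 300.0
    sim_fragment_sd: float = 50.0
    sim_depth: int = 30
    sim_error_rate: float = 0.0
    sim_duplicate_rate: float = 0.0
    seed: int = 0

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_support=self.min_support,
            min_separation=self.min_separation,
            predominance_threshold=self.predominance_threshold,
            homology_k=self.homology_k,
            homology_threshold=self.homology_threshold,
            neighbor_max_gap=self.neighbor_max_gap,
        )

    def junction_criteria(self) -> JunctionCriteria:
        return JunctionCriteria(
            min_flank=self.junction_min_flank,
            max_mismatches=self.junction_max_mismatches,
            flank_mismatch_allowance=self.junction_flank_mismatch_allowance,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim_exons_per_gene"] = list(self.sim_exons_per_gene)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim_exons_per_gene" in data:
            data = {**data, "sim_exons_per_gene": tuple(data["sim_exons_per_gene"])}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
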