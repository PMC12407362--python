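"""Schema-validated pipeline configuration.

One YAML document drives the whole run; unknown keys are rejected and every
random process carries an explicit seed so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenomeSection(_Strict):
    chromosomes: dict[str, int] = Field(default={"chr5": 400_000})
    inversions: list[list] = Field(default=[["chr5", 150_000, 250_000]])
    snp_rate: float = 0.002


class SatelliteSection(_Strict):
    chrom: str = "chr5"
    start: int = 180_000
    monomer_length: int = 139
    copies: int = 200
    mutation_rate: float = 0.02


class ReadsSection(_Strict):
    depth: float = 20.0
    read_len: int = 150
    insert_mean: int = 350
    insert_sd: int = 50
    error_rate: float = 0.0
    n_same_a: int = 2       # samples sequenced from the A arrangement
    n_same_b: int = 2
    n_het: int = 2          # one haplotype of each arrangement


class PopulationSection(_Strict):
    n_inland: int = 31
    n_coastal: int = 20
    n_sites: int = 4_000
    chrom: str = "chr5"
    chrom_length: int = 400_000
    freq_lo: float = 0.05
    freq_hi: float = 0.95
    f_background: float = 0.05
    f_block: float = 0.6
    block: list[int] = Field(default=[140_000, 280_000])
    marker_positions: list[int] = Field(default=[150_000, 250_000])
    causal_positions: list[int] = Field(default=[200_000, 200_400, 200_900, 201_500])
    tolerant_freq_coastal: float = 0.55
    missing_rate: float = 0.02


class PhenotypeSection(_Strict):
    tolerant_mean: float = 91.83
    sensitive_mean: float = 1.11
    tolerant_sd: float = 2.25
    sensitive_sd: float = 1.57


class ChipSection(_Strict):
    fold: float = 5.0
    depth: float = 20.0
    window: int = 10_000
    centromere: list[int] = Field(default=[160_000, 260_000])
    fold_threshold: float = 2.0
    min_length: int = 50_000
    max_gap: int = 1


class GenotypingSection(_Strict):
    flank: int = 150
    min_overlap: int = 20


class ScanSection(_Strict):
    maf_min: float = 0.03
    missing_max: float = 0.1
    window: int = 40_000
    step: int = 4_000
    gdr_quantile: float = 0.95


class GwasSection(_Strict):
    n_components: int = 2
    alpha: float = 0.05
    n_eff: int | None = None


class PipelineConfig(_Strict):
    seed: int = 1
    genome: GenomeSection = Field(default_factory=GenomeSection)
    satellite: SatelliteSection = Field(default_factory=SatelliteSection)
    reads: ReadsSection = Field(default_factory=ReadsSection)
    population: PopulationSection = Field(default_factory=PopulationSection)
    phenotype: PhenotypeSection = Field(default_factory=PhenotypeSection)
    chip: ChipSection = Field(default_factory=ChipSection)
    genotyping: GenotypingSection = Field(default_factory=GenotypingSection)
    scan: ScanSection = Field(default_factory=ScanSection)
    gwas: GwasSection = Field(default_factory=GwasSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
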