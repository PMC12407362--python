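"""Genotype matrix container shared across the scan and association modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites with additive dosages {0, 1, 2} and -1 for missing.

    Coordinates are 0-based internally; conversion to/from the 1-based VCF
    convention happens only in the readers/writers.
    """

    dosages: np.ndarray            # (n_samples, n_sites) int8
    chroms: np.ndarray             # (n_sites,) str
    positions: np.ndarray          # (n_sites,) int64, 0-based
    samples: list[str]
    ref: np.ndarray | None = None  # (n_sites,) single-base str
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        if self.dosages.shape != (len(self.samples), len(self.positions)):
            raise ValueError("dosage shape inconsistent with samples/positions")
        bad = (self.dosages > 2) | (self.dosages < MISSING)
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            chroms=self.chroms[index],
            positions=self.positions[index],
            samples=list(self.samples),
            ref=None if self.ref is None else self.ref[index],
            alt=None if self.alt is None else self.alt[index],
        )

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per site over non-missing calls (NaN if none)."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.chroms, other.chroms)
        )
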