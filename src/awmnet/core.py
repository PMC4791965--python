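"""Shared in-memory containers: genotype matrix and pedigree.

Dosages are coded 0/1/2 copies of the B (alternate) allele with ``NaN``
for missing calls, stored densely as float64 — desk-scale panels (hundreds
of animals, up to a few hundred thousand SNPs) fit comfortably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAP_COLUMNS = ("snp", "chrom", "bp")
PED_COLUMNS = (
    "animal",
    "sire",
    "dam",
    "role",
    "lineage",
    "mtdna",
    "cg",
    "origin",
    "birth_year",
)

#: placeholder for an unknown parent (PLINK convention)
UNKNOWN = "0"


@dataclass
class GenotypeMatrix:
    """Animals x SNPs allele-dosage table with a physical marker map.

    Parameters
    ----------
    dosages
        ``(n_animals, n_snps)`` float array; entries in {0, 1, 2, NaN}.
    samples
        Animal identifiers, one per row.
    snp_map
        DataFrame with columns ``snp`` (id), ``chrom`` (label) and ``bp``
        (1-based physical position), one row per dosage column.
    """

    dosages: np.ndarray
    samples: list[str]
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = list(self.samples)
        self.snp_map = self.snp_map.reset_index(drop=True)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (animals x SNPs)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("row count does not match number of samples")
        if self.dosages.shape[1] != len(self.snp_map):
            raise ValueError("column count does not match marker map")
        missing = set(MAP_COLUMNS) - set(self.snp_map.columns)
        if missing:
            raise ValueError(f"snp_map lacks columns: {sorted(missing)}")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp"].to_numpy()

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the B allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def snp_callrate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_callrate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def map_is_sorted(self) -> bool:
        """True when bp positions are non-decreasing within each chromosome."""
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if not grp["bp"].is_monotonic_increasing:
                return False
        return True

    def subset(
        self,
        samples: np.ndarray | list | None = None,
        snps: np.ndarray | list | None = None,
    ) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index arrays."""
        rows = np.arange(self.n_animals) if samples is None else np.asarray(samples)
        cols = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(rows, cols)],
            samples=[self.samples[i] for i in rows],
            snp_map=self.snp_map.iloc[cols],
        )


@dataclass
class Pedigree:
    """Animal records for a half-sib design.

    Wraps a DataFrame with one row per sire and per sib (dams are
    referenced by id but ungenotyped and carry no record).  Columns follow
    :data:`PED_COLUMNS`; unknown parents are ``"0"``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(PED_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree lacks columns: {sorted(missing)}")
        if self.table["animal"].duplicated().any():
            raise ValueError("duplicate animal ids in pedigree")
        self.table = self.table.reset_index(drop=True)

    @property
    def animals(self) -> list[str]:
        return self.table["animal"].tolist()

    @property
    def sires(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "sire"]

    @property
    def sibs(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "sib"]

    def __len__(self) -> int:
        return len(self.table)

    def contemporary_groups(self) -> pd.Series:
        """Contemporary-group label per animal (origin x birth-year)."""
        return self.table.set_index("animal")["cg"]
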