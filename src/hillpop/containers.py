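"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`GenotypeMatrix`: a samples x sites matrix of
alternate-allele dosages (0/1/2, with -1 encoding a missing call) together
with per-site metadata (chromosome, position, alleles) and per-site quality
annotations. Sites are biallelic autosomal SNPs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Per-site quality annotations consumed by the hard filters.
ANNOTATION_FIELDS = ("QD", "MQ", "QUAL", "FS", "MQRankSum", "ReadPosRankSum", "DP")


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with aligned site metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_sites)`` int8 array of alternate-allele counts per
        genotype; ``-1`` marks a missing call.
    samples
        Sample identifiers, one per row.
    sites
        Per-site table with at least columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``. Quality-annotation columns (``QD``, ``MQ``,
        ``QUAL``, ``FS``, ``MQRankSum``, ``ReadPosRankSum``, ``DP``) are
        carried here when available; ``NaN`` marks a missing annotation.
    """

    dosages: np.ndarray
    samples: list[str]
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} sample IDs but {self.dosages.shape[0]} dosage rows"
            )
        if self.dosages.shape[1] != len(self.sites):
            raise ValueError(
                f"{len(self.sites)} site records but {self.dosages.shape[1]} dosage columns"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 for missing")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.dosages != MISSING

    def masked(self) -> np.ma.MaskedArray:
        """Dosages as a float masked array (missing calls masked)."""
        return np.ma.masked_array(
            self.dosages.astype(float), mask=self.dosages == MISSING
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (or boolean mask), keeping order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given sample indices (or boolean mask), keeping order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            samples=[self.samples[i] for i in index],
            sites=self.sites,
        )

    def annotations(self) -> pd.DataFrame:
        """The quality-annotation columns present in the site table."""
        cols = [c for c in ANNOTATION_FIELDS if c in self.sites.columns]
        return self.sites[cols]


@dataclass
class PopulationMap:
    """sample -> population -> species assignment."""

    table: pd.DataFrame  # columns: sample_id, population, species

    def __post_init__(self) -> None:
        required = {"sample_id", "population", "species"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"population map needs columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample IDs in population map")
        self.table = self.table.reset_index(drop=True)

    def population_of(self, sample: str) -> str:
        return self._lookup(sample, "population")

    def species_of(self, sample: str) -> str:
        return self._lookup(sample, "species")

    def _lookup(self, sample: str, col: str) -> str:
        rows = self.table.loc[self.table["sample_id"] == sample, col]
        if rows.empty:
            raise KeyError(f"sample {sample!r} not in population map")
        return rows.iloc[0]

    def members(self, population: str) -> list[str]:
        return list(
            self.table.loc[self.table["population"] == population, "sample_id"]
        )

    def species_members(self, species: str) -> list[str]:
        return list(self.table.loc[self.table["species"] == species, "sample_id"])

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.table["species"]))


@dataclass
class GeneIntervals:
    """Gene annotation as 0-based half-open intervals, sorted within chromosome."""

    table: pd.DataFrame  # columns: chrom, start, end, gene_id

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "gene_id"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"gene intervals need columns {sorted(required)}")
        t = self.table.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )
        for _, grp in t.groupby("chrom", sort=False):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError("gene intervals overlap within a chromosome")
        self.table = t

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.table.loc[self.table["chrom"] == chrom].reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])
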