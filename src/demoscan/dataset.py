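"""Core in-memory containers for genotype data grouped into target regions.

The central object is :class:`GenotypeDataset`: a diploid dosage matrix
(sites x samples) plus three aligned tables — per-site metadata (region id,
within-region position), per-sample metadata (stand and slope labels), and
per-region metadata (length in bases, including invariant sites).  All
statistics in the package consume this container; VCF input/output lives in
:mod:`demoscan.vcfio`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: canonical stand labels of the four-stand sampling design
STANDS = ("N3", "N4", "S1", "S5")

#: slope (mountain side) each stand belongs to
SLOPE_OF = {"N3": "N", "N4": "N", "S1": "S", "S5": "S"}

#: the six unordered stand pairs, in canonical order
STAND_PAIRS = (
    ("N3", "N4"), ("N3", "S1"), ("N3", "S5"),
    ("N4", "S1"), ("N4", "S5"), ("S1", "S5"),
)


def pair_label(a: str, b: str) -> str:
    return f"{a}-{b}"


@dataclass
class GenotypeDataset:
    """Diploid genotypes with site, sample and region annotations.

    Parameters
    ----------
    genotypes
        ``(n_sites, n_samples)`` integer array of alternate-allele dosages
        (0, 1, 2); missing genotypes are coded :data:`MISSING`.
    samples
        Data frame with columns ``sample_id``, ``stand`` and ``slope``;
        one row per column of ``genotypes``.
    sites
        Data frame with columns ``region`` and ``pos`` (1-based position
        within the region); one row per row of ``genotypes``.
    regions
        Data frame indexed by region id with a ``length`` column (bases,
        including invariant sites).  Optional extra columns (e.g.
        ``source_set`` for compiled simulated data) are carried along.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    sites: pd.DataFrame
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (sites x samples) array")
        n_sites, n_samples = self.genotypes.shape
        if len(self.sites) != n_sites:
            raise ValueError(
                f"sites table has {len(self.sites)} rows for {n_sites} genotype rows"
            )
        if len(self.samples) != n_samples:
            raise ValueError(
                f"samples table has {len(self.samples)} rows for {n_samples} genotype columns"
            )
        missing_regions = set(self.sites["region"]) - set(self.regions.index)
        if missing_regions:
            some = sorted(missing_regions)[:3]
            raise ValueError(f"sites reference regions with unknown length: {some}")
        self.samples = self.samples.reset_index(drop=True)
        self.sites = self.sites.reset_index(drop=True)

    # -- basic shape ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def stands(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples["stand"]:
            if s not in seen:
                seen.append(s)
        return seen

    def stand_columns(self, stand: str) -> np.ndarray:
        cols = np.flatnonzero((self.samples["stand"] == stand).to_numpy())
        if cols.size == 0:
            raise KeyError(f"unknown stand label: {stand!r}")
        return cols

    # -- allele counting -------------------------------------------------
    def allele_counts(self, stand: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called chromosome count).

        Missing genotypes contribute to neither count.  With ``stand`` given,
        only that stand's samples are counted.
        """
        g = self.genotypes if stand is None else self.genotypes[:, self.stand_columns(stand)]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1)
        n_chrom = 2 * called.sum(axis=1)
        return alt.astype(np.int64), n_chrom.astype(np.int64)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        return (self.genotypes == MISSING).mean(axis=1)

    # -- subsetting ------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        kept_regions = self.regions.loc[
            self.regions.index.isin(set(self.sites["region"].to_numpy()[index]))
        ]
        return GenotypeDataset(
            genotypes=self.genotypes[index].copy(),
            samples=self.samples.copy(),
            sites=self.sites.iloc[index].copy(),
            regions=kept_regions.copy(),
        )

    def take_samples(self, columns: np.ndarray) -> "GenotypeDataset":
        columns = np.asarray(columns)
        return GenotypeDataset(
            genotypes=self.genotypes[:, columns].copy(),
            samples=self.samples.iloc[columns].copy(),
            sites=self.sites.copy(),
            regions=self.regions.copy(),
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            genotypes=self.genotypes.copy(),
            samples=self.samples.copy(),
            sites=self.sites.copy(),
            regions=self.regions.copy(),
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.samples.equals(other.samples)
            and self.sites.equals(other.sites)
            and self.regions.equals(other.regions)
        )

    def site_labels(self) -> pd.Series:
        """Unique per-site labels ``region:pos``."""
        return self.sites["region"].astype(str) + ":" + self.sites["pos"].astype(str)


def concat_datasets(parts: Sequence[GenotypeDataset]) -> GenotypeDataset:
    """Stack datasets over sites; sample tables must be identical."""
    if not parts:
        raise ValueError("nothing to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if not p.samples.equals(first.samples):
            raise ValueError("sample tables differ between concatenated datasets")
    return GenotypeDataset(
        genotypes=np.vstack([p.genotypes for p in parts]),
        samples=first.samples.copy(),
        sites=pd.concat([p.sites for p in parts], ignore_index=True),
        regions=pd.concat([p.regions for p in parts]),
    )


def make_sample_table(samples_per_stand: Mapping[str, int] | Sequence[int]) -> pd.DataFrame:
    """Build a sample table for the four-stand design.

    ``samples_per_stand`` is either a mapping stand->count or a sequence of
    four counts in canonical stand order.
    """
    if not isinstance(samples_per_stand, Mapping):
        samples_per_stand = dict(zip(STANDS, samples_per_stand))
    rows = []
    for stand, count in samples_per_stand.items():
        slope = SLOPE_OF.get(stand, stand[0])
        for i in range(count):
            rows.append((f"{stand}_{i:03d}", stand, slope))
    return pd.DataFrame(rows, columns=["sample_id", "stand", "slope"])
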