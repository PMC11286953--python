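"""Post-variant-calling curation of capture data.

Implements the filter chain applied after variant calling: removal of whole
target regions with excessive variant density (more than one variant every
20 bases by default) or carrying only heterozygous genotypes (a paralogue
signature), removal of sites with too many missing genotypes, removal of
monomorphic sites, per-pair subsetting, coordinate liftover through a
region-to-scaffold correspondence table, and a chi-square test of the
regions' conformity to a Poisson spatial distribution along chromosomes.

Filtering never modifies a genotype value — it only drops rows (sites of
removed regions) and, for pair subsetting, columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, poisson

from .dataset import GenotypeDataset


@dataclass
class FilterReport:
    """Per-rule counts and itemised removals of the filter chain."""

    steps: list[dict] = field(default_factory=list)
    removed_regions: list[tuple[str, str]] = field(default_factory=list)  # (region, reason)
    removed_sites: list[tuple[str, int, str]] = field(default_factory=list)  # (region, pos, reason)

    def add_step(self, rule: str, before: GenotypeDataset, after: GenotypeDataset) -> None:
        step = {
            "rule": rule,
            "variants_before": before.n_sites,
            "variants_after": after.n_sites,
            "regions_before": int(before.sites["region"].nunique()),
            "regions_after": int(after.sites["region"].nunique()),
        }
        if step["variants_after"] > step["variants_before"]:
            raise ValueError("filter chain must be monotonically non-increasing")
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def log_text(self) -> str:
        lines = []
        for s in self.steps:
            lines.append(
                f"{s['rule']}: variants {s['variants_before']} -> {s['variants_after']}, "
                f"regions {s['regions_before']} -> {s['regions_after']}"
            )
        for region, reason in self.removed_regions:
            lines.append(f"  removed region {region} ({reason})")
        for region, pos, reason in self.removed_sites:
            lines.append(f"  removed site {region}:{pos} ({reason})")
        return "\n".join(lines)


def sieve(
    data: GenotypeDataset,
    var_density_threshold: float = 0.05,
    het_threshold: float = 1.0,
    max_missing: float = 0.2,
) -> tuple[GenotypeDataset, FilterReport]:
    """Region-density, all-heterozygous and missingness filters, in order.

    Whole regions are removed when ``#variants / region length`` exceeds
    ``var_density_threshold``, or when the proportion of heterozygous calls
    among all called genotypes across the region's SNPs reaches
    ``het_threshold`` (1.0 = every call heterozygous, the paralogue
    signature).  Individual sites with a missing-genotype proportion above
    ``max_missing`` are then removed.
    """
    report = FilterReport()
    regions = data.sites["region"]

    lengths = data.regions["length"]
    bad_len = lengths.index[~(lengths > 0) | lengths.isna()]
    used = set(regions)
    bad_used = [r for r in bad_len if r in used]
    if bad_used:
        raise ValueError(f"region with unknown length: {bad_used[0]}")

    # 1. variant density per region (variants per base of full region length)
    n_var = regions.value_counts()
    density = n_var / lengths.reindex(n_var.index)
    dense = set(density.index[density > var_density_threshold])
    keep = ~regions.isin(dense).to_numpy()
    after = data.take_sites(keep)
    report.add_step("density", data, after)
    report.removed_regions += [(r, "density") for r in sorted(dense)]
    data = after

    # 2. regions where (essentially) every called genotype is heterozygous
    regions = data.sites["region"]
    called = data.genotypes >= 0
    het = data.genotypes == 1
    frame = pd.DataFrame(
        {"region": regions, "called": called.sum(axis=1), "het": het.sum(axis=1)}
    )
    sums = frame.groupby("region", sort=False).sum()
    with np.errstate(invalid="ignore"):
        het_prop = sums["het"] / sums["called"]
    allhet = set(sums.index[(sums["called"] > 0) & (het_prop >= het_threshold)])
    keep = ~regions.isin(allhet).to_numpy()
    after = data.take_sites(keep)
    report.add_step("all-het", data, after)
    report.removed_regions += [(r, "all-het") for r in sorted(allhet)]
    data = after

    # 3. per-site missingness
    miss = data.missing_fraction()
    keep = miss <= max_missing
    after = data.take_sites(keep)
    report.add_step("missingness", data, after)
    for i in np.flatnonzero(~keep):
        report.removed_sites.append(
            (data.sites["region"].iat[i], int(data.sites["pos"].iat[i]), "missingness")
        )
    return after, report


def mono_remove(data: GenotypeDataset) -> GenotypeDataset:
    """Drop sites with fewer than two observed alleles among called genotypes."""
    alt, n_chrom = data.allele_counts()
    keep = (alt > 0) & (alt < n_chrom)
    return data.take_sites(keep)


def subset_pair(
    data: GenotypeDataset, stand_a: str, stand_b: str
) -> GenotypeDataset:
    """Retain the pair's individuals, then drop sites monomorphic in the pair."""
    cols = np.concatenate([data.stand_columns(stand_a), data.stand_columns(stand_b)])
    return mono_remove(data.take_samples(cols))


class NoHitError(KeyError):
    """The queried (region, position) has no scaffold placement."""


class AmbiguousRegionError(KeyError):
    """The queried region maps to more than one scaffold location."""


class CorrespondenceTable:
    """Mapping of (target-region id, within-region position) to scaffold coordinates.

    Built from a table with columns ``region``, ``region_pos``, ``scaffold``,
    ``scaffold_pos`` (1-based positions on both sides, matching the VCF
    convention).  Regions whose positions map to more than one scaffold
    location are flagged ambiguous and refuse lookups.
    """

    COLUMNS = ("region", "region_pos", "scaffold", "scaffold_pos")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"correspondence table missing columns {missing}")
        dup = table.duplicated(subset=["region", "region_pos"], keep=False)
        distinct = table[dup].drop_duplicates(subset=list(self.COLUMNS))
        counts = distinct.groupby(["region", "region_pos"]).size()
        self.ambiguous_regions = set(
            idx[0] for idx in counts.index[counts > 1]
        )
        clean = table[~table["region"].isin(self.ambiguous_regions)]
        self._map = {
            (r.region, int(r.region_pos)): (r.scaffold, int(r.scaffold_pos))
            for r in clean.itertuples(index=False)
        }
        self.table = table

    @classmethod
    def identity(cls, regions: Mapping[str, int]) -> "CorrespondenceTable":
        """Identity table: each region is its own scaffold."""
        rows = [
            (region, p, region, p)
            for region, length in regions.items()
            for p in range(1, int(length) + 1)
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def from_tsv(cls, path) -> "CorrespondenceTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def liftover(self, region_id: str, position: int) -> tuple[str, int]:
        """Scaffold coordinate of a within-region position (1-based)."""
        if region_id in self.ambiguous_regions:
            raise AmbiguousRegionError(
                f"region {region_id} maps ambiguously to multiple scaffold locations"
            )
        try:
            return self._map[(region_id, int(position))]
        except KeyError:
            raise NoHitError(
                f"no scaffold hit for {region_id}:{position}"
            ) from None


def liftover(table: CorrespondenceTable, region_id: str, position: int) -> tuple[str, int]:
    return table.liftover(region_id, position)


def region_poisson_test(
    region_positions: Mapping[str, Sequence[float]],
    window_bp: float | None = None,
    chrom_lengths: Mapping[str, float] | None = None,
    min_expected: float = 1.0,
) -> tuple[float, int, float]:
    """Chi-square conformity of per-window region counts to a Poisson law.

    Regions are binned into non-overlapping windows per chromosome (default
    window: chromosome length / 50); the distribution of counts per window is
    compared to a Poisson with the observed mean.  Cells with expected count
    below ``min_expected`` are pooled with their neighbours; degrees of
    freedom are ``cells - 2`` (the mean is estimated).  Returns
    ``(statistic, df, p)``.
    """
    counts: list[int] = []
    for chrom, positions in region_positions.items():
        positions = np.asarray(positions, dtype=float)
        if chrom_lengths and chrom in chrom_lengths:
            length = float(chrom_lengths[chrom])
        else:
            length = float(positions.max()) + 1.0 if len(positions) else 0.0
        if length <= 0:
            continue
        w = window_bp if window_bp is not None else length / 50.0
        if w <= 0:
            raise ValueError("window_bp must be > 0")
        n_windows = max(int(np.ceil(length / w)), 1)
        hist = np.bincount(
            np.minimum((positions // w).astype(int), n_windows - 1),
            minlength=n_windows,
        )
        counts.extend(hist.tolist())
    counts = np.asarray(counts)
    if len(counts) < 2:
        raise ValueError("need at least 2 windows for the conformity test")

    mean = counts.mean()
    kmax = int(counts.max())
    observed = np.bincount(counts, minlength=kmax + 2).astype(float)
    expected = poisson.pmf(np.arange(kmax + 1), mean) * len(counts)
    # open upper tail
    expected = np.append(expected, len(counts) - expected.sum())
    observed = observed[: kmax + 2]

    # pool adjacent cells until every expected count reaches the minimum
    obs_cells: list[float] = []
    exp_cells: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_cells.append(acc_o)
            exp_cells.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp_cells:
        obs_cells[-1] += acc_o
        exp_cells[-1] += acc_e
    obs_arr = np.asarray(obs_cells)
    exp_arr = np.asarray(exp_cells)
    if len(obs_arr) < 3:
        # too few distinct count classes: fall back to a dispersion test
        stat = float((len(counts) - 1) * counts.var(ddof=1) / mean) if mean > 0 else 0.0
        df = len(counts) - 1
        p = float(chi2.sf(stat, df))
        return stat, df, p
    stat = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    df = len(obs_arr) - 2
    p = float(chi2.sf(stat, df))
    return stat, df, p
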