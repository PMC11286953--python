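"""Synthetic four-stand genotype datasets with a known neutral background.

The generator emulates the statistical structure of the study system: four
stands (two per mountain slope) of 20–26 diploid trees each, thousands of
short captured coding regions, near-zero genome-wide differentiation, and a
small fraction of missing genotypes.  Genotypes are drawn from the staged
demographic model (module :mod:`demoscan.demography`) at the haplotype level
and paired into diploids; optional divergently selected loci of known effect
can be injected afterwards for power studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import MISSING, SLOPE_OF, STANDS, GenotypeDataset
from .demography import (
    DEFAULT_MU,
    DEFAULT_REC,
    DemographicParameterSet,
    build_event_schedule,
    simulate_fragments,
)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a four-stand dataset.

    Defaults mirror the study layout: per-stand sample counts within 20–26
    whose pairwise sums match the reported pair sizes (N3+S1 = 45,
    N4+S5 = 51), ~9k target regions, and 2.9% missing genotypes.  Region
    lengths are fixed at 1000 bp by default so that synthetic data and the
    simulated neutral reference stay commensurable; the "empirical" length
    model instead draws lengths around the study's 390 bp mean.
    """

    samples_per_stand: Mapping[str, int] = field(
        default_factory=lambda: {"N3": 21, "N4": 25, "S1": 24, "S5": 26}
    )
    n_regions: int = 8791
    region_length_bp: int = 1000
    length_model: str = "fixed"  # "fixed" | "empirical"
    empirical_mean_bp: int = 390
    missing_rate: float = 0.029
    slope_assignment: Mapping[str, str] = field(default_factory=lambda: dict(SLOPE_OF))

    def __post_init__(self) -> None:
        if set(self.samples_per_stand) != set(STANDS):
            raise ValueError(f"design must cover exactly the stands {STANDS}")
        if any(n < 2 for n in self.samples_per_stand.values()):
            raise ValueError("each stand needs at least 2 sampled individuals")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.length_model not in ("fixed", "empirical"):
            raise ValueError("length_model must be 'fixed' or 'empirical'")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for stand in STANDS:
            if stand not in self.slope_assignment:
                raise ValueError(f"stand {stand} has no slope assignment")

    def region_lengths(self, rng: np.random.Generator) -> np.ndarray:
        if self.length_model == "fixed":
            return np.full(self.n_regions, self.region_length_bp, dtype=int)
        # right-skewed lengths with the empirical mean, floored at 100 bp
        draw = rng.gamma(shape=2.0, scale=(self.empirical_mean_bp - 100) / 2.0,
                         size=self.n_regions)
        return (100 + np.round(draw)).astype(int)


@dataclass
class SelectionTruth:
    """Known injected divergence events for power testing.

    One record per locus: the site label (``region:pos``), the stand whose
    allele frequency is displaced, the stand pair it is meant to diverge in,
    and the displacement ``delta_p`` in [0, 1].
    """

    records: pd.DataFrame  # columns: locus, stand, pair, delta_p

    def __post_init__(self) -> None:
        need = {"locus", "stand", "pair", "delta_p"}
        if not need <= set(self.records.columns):
            raise ValueError(f"truth table needs columns {sorted(need)}")
        dp = self.records["delta_p"]
        if ((dp < 0) | (dp > 1)).any():
            raise ValueError("delta_p must lie in [0, 1]")

    def loci(self) -> list[str]:
        return list(self.records["locus"])

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SelectionTruth":
        return cls(pd.read_csv(path, sep="\t"))


def generate_neutral_dataset(
    design: StudyDesign,
    params: DemographicParameterSet,
    seed: int,
    mu: float = DEFAULT_MU,
    rec_per_bp: float = DEFAULT_REC,
) -> GenotypeDataset:
    """Draw a four-stand dataset from the staged coalescent model.

    Regions are independent fragments; missing genotypes are masked i.i.d.
    at the design's rate.  Deterministic given (design, params, seed).
    """
    rng = np.random.default_rng(seed)
    schedule = build_event_schedule(params)
    lengths = design.region_lengths(rng)
    data = simulate_fragments(
        schedule,
        n_fragments=design.n_regions,
        fragment_bp=lengths if design.length_model == "empirical" else int(lengths[0]),
        mu=mu,
        rec_per_bp=rec_per_bp,
        sample_sizes={s: design.samples_per_stand[s] for s in STANDS},
        seed=int(rng.integers(1, 2**31 - 1)),
        region_prefix="region",
    )
    if design.missing_rate > 0 and data.n_sites:
        mask = rng.random(data.genotypes.shape) < design.missing_rate
        data.genotypes[mask] = MISSING
    return data


def mask_missing(data: GenotypeDataset, rate: float, seed: int) -> GenotypeDataset:
    """Return a copy with genotypes masked missing i.i.d. at the given rate.

    Used to process a simulated null with the same missingness as the
    empirical data, so that projection and filtering treat both identically.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = data.copy()
    if rate > 0 and out.n_sites:
        rng = np.random.default_rng(seed)
        out.genotypes[rng.random(out.genotypes.shape) < rate] = MISSING
    return out


def inject_selection(
    data: GenotypeDataset,
    truth: SelectionTruth,
    seed: int,
    resample_unshifted: bool = True,
) -> GenotypeDataset:
    """Return a copy with truth loci displaced in frequency in one stand.

    For each record the named stand's genotypes at the locus are redrawn
    from a binomial whose frequency is the stand's current allele frequency
    shifted by ``delta_p`` (upwards from frequencies <= 0.5, downwards
    otherwise), clamped to [0, 1].  Missing genotypes stay missing; all
    other loci are untouched.  With ``resample_unshifted=False`` records
    with ``delta_p == 0`` are skipped entirely, leaving the locus
    bit-identical.
    """
    labels = data.site_labels()
    index_of = {lab: i for i, lab in enumerate(labels)}
    unknown = [l for l in truth.loci() if l not in index_of]
    if unknown:
        raise ValueError(f"truth loci absent from dataset: {unknown[:3]}")

    out = data.copy()
    rng = np.random.default_rng(seed)
    for rec in truth.records.itertuples(index=False):
        if rec.delta_p == 0 and not resample_unshifted:
            continue
        site = index_of[rec.locus]
        cols = out.stand_columns(rec.stand)
        g = out.genotypes[site, cols]
        called = g >= 0
        n_chrom = 2 * called.sum()
        if n_chrom == 0:
            continue
        p = g[called].sum() / n_chrom
        # shift away from the majority side so the realised displacement
        # min(delta_p, room) is non-decreasing in delta_p
        p_new = p + rec.delta_p if p <= 0.5 else p - rec.delta_p
        p_new = float(np.clip(p_new, 0.0, 1.0))
        new = g.copy()
        new[called] = rng.binomial(2, p_new, size=int(called.sum())).astype(np.int8)
        out.genotypes[site, cols] = new
    return out


def choose_truth_loci(
    data: GenotypeDataset,
    pair: tuple[str, str],
    n_loci: int,
    delta_p: float,
    seed: int,
) -> SelectionTruth:
    """Pick random polymorphic loci of a pair and build a truth table.

    The displaced stand is the second of the pair.  Loci are sampled without
    replacement among sites polymorphic within the pair.
    """
    alt_a, n_a = data.allele_counts(pair[0])
    alt_b, n_b = data.allele_counts(pair[1])
    alt, n = alt_a + alt_b, n_a + n_b
    poly = np.flatnonzero((alt > 0) & (alt < n) & (n_a > 0) & (n_b > 0))
    if len(poly) < n_loci:
        raise ValueError(
            f"only {len(poly)} polymorphic loci available for pair {pair}, "
            f"need {n_loci}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(poly, size=n_loci, replace=False)
    labels = data.site_labels()
    records = pd.DataFrame(
        {
            "locus": [labels[i] for i in chosen],
            "stand": pair[1],
            "pair": f"{pair[0]}-{pair[1]}",
            "delta_p": delta_p,
        }
    )
    return SelectionTruth(records=records)
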