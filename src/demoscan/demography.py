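"""Staged demographic model for four recently diverged tree stands.

The model describes, forward in time: a deep-time expansion of a single
ancestral population (``TIMEE`` to ``TIMED``, rate ``GROWTHRATE2``), a period
of stability (``TIMED`` to ``TIMEC``), a long contraction mirroring
progressive deforestation (``TIMEC`` to ``TIMEB``, rate ``GROWTHRATE1``),
stability at the minimum extent (``TIMEB`` to ``TIMEA``), and finally renewed
expansion during which the population progressively splits into the four
sampled stands (N3, N4, S1, S5) while exchanging migrants (``TIMEA`` to the
present, rate ``GROWTHRATE0``).  Stand mergers (viewed backwards in time)
happen at ``TIME1`` (N3+N4), ``TIME2`` (+S1) and ``TIME3`` (+S5), following
the fixed topology (S5-(S1-(N3-N4))).  All times are in generations before
present; sizes are diploid effective sizes; growth rates are per-generation
exponential rates in forward time.

The translation to a coalescent simulator is exact: msprime's ``growth_rate``
is a forward-time exponential rate, so each epoch's forward rate is passed
through unchanged, anchored at the epoch boundary closest to the present.
When stands merge backwards in time the ancestral deme takes the *sum* of the
merging demes' sizes at the merger time (mass conservation), so with all
growth rates zero the ancestral size equals the minimum-extent size.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import msprime
import numpy as np
import pandas as pd

from .dataset import GenotypeDataset, STANDS, STAND_PAIRS, make_sample_table

#: default per-base per-generation mutation rate (beech estimate)
DEFAULT_MU = 9.5e-10

#: default per-base recombination rate (~2 cM/Mb)
DEFAULT_REC = 2e-8

PARAM_NAMES = (
    "POPSIZE_N3", "POPSIZE_N4", "POPSIZE_S1", "POPSIZE_S5",
    "MIG_N3_N4", "MIG_N3_S1", "MIG_N3_S5",
    "MIG_N4_S1", "MIG_N4_S5", "MIG_S1_S5",
    "TIME1", "TIME2", "TIME3",
    "TIMEA", "TIMEB", "TIMEC", "TIMED", "TIMEE",
    "GROWTHRATE0", "GROWTHRATE1", "GROWTHRATE2",
)

_TIME_ORDER = ("TIME1", "TIME2", "TIME3", "TIMEA", "TIMEB", "TIMEC", "TIMED", "TIMEE")


@dataclass(frozen=True)
class DemographicParameterSet:
    """One realization of the 21 named demographic parameters."""

    POPSIZE_N3: float
    POPSIZE_N4: float
    POPSIZE_S1: float
    POPSIZE_S5: float
    MIG_N3_N4: float
    MIG_N3_S1: float
    MIG_N3_S5: float
    MIG_N4_S1: float
    MIG_N4_S5: float
    MIG_S1_S5: float
    TIME1: float
    TIME2: float
    TIME3: float
    TIMEA: float
    TIMEB: float
    TIMEC: float
    TIMED: float
    TIMEE: float
    GROWTHRATE0: float
    GROWTHRATE1: float
    GROWTHRATE2: float

    def __post_init__(self) -> None:
        for name in ("POPSIZE_N3", "POPSIZE_N4", "POPSIZE_S1", "POPSIZE_S5"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (got {getattr(self, name)})")
        for name in PARAM_NAMES:
            if name.startswith("MIG") and getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (got {getattr(self, name)})")
        times = [getattr(self, n) for n in _TIME_ORDER]
        if any(t < 0 for t in times):
            raise ValueError("all TIME parameters must be >= 0")
        for (na, ta), (nb, tb) in zip(
            zip(_TIME_ORDER, times), zip(_TIME_ORDER[1:], times[1:])
        ):
            if ta > tb:
                raise ValueError(f"time ordering violated: {na}={ta} > {nb}={tb}")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_dict(), index=list(PARAM_NAMES))

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "DemographicParameterSet":
        missing = [n for n in PARAM_NAMES if n not in values]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        return cls(**{n: float(values[n]) for n in PARAM_NAMES})

    def migration_rate(self, a: str, b: str) -> float:
        x, y = sorted((a, b))
        return getattr(self, f"MIG_{x}_{y}")


#: published summary of 100 maximum-likelihood runs (lower CI, median, mode, upper CI)
PUBLISHED_ESTIMATES = pd.DataFrame(
    {
        "lower": [601, 42482, 652, 304,
                  0.0013, 0.0014, 0.0013, 0.0013, 0.0013, 0.0012,
                  1, 1, 1, 2, 2, 90, 101, 176,
                  0.00443, -0.00010, 0.00001],
        "median": [23383, 44528, 23729, 20242,
                   0.0022, 0.0026, 0.0024, 0.0022, 0.0022, 0.0023,
                   1, 1, 1, 2, 4, 98, 159, 937,
                   0.00313, -0.00127, -0.00001],
        "mode": [18521, 46345, 30362, 29609,
                 0.0021, 0.0043, 0.0028, 0.0015, 0.0035, 0.0062,
                 1, 1, 1, 2, 3, 99, 103, 987,
                 0.00366, -0.00125, -0.00004],
        "upper": [37882, 46573, 38128, 33290,
                  0.0057, 0.0070, 0.0067, 0.0056, 0.0058, 0.0061,
                  3, 3, 5, 12, 16, 99, 268, 989,
                  -0.00010, -0.00544, -0.00004],
    },
    index=list(PARAM_NAMES),
)

#: the median parameter set of the published maximum-likelihood runs
PUBLISHED_MEDIANS = DemographicParameterSet.from_mapping(PUBLISHED_ESTIMATES["median"])


@dataclass
class EventSchedule:
    """Backwards-in-time event list compiled to an msprime demography."""

    params: DemographicParameterSet
    demography: msprime.Demography
    events: pd.DataFrame  # columns: time, event, detail
    minimum_extent_size: float

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EventSchedule({len(self.events)} events, "
            f"N_min={self.minimum_extent_size:.1f})"
        )


def build_event_schedule(params: DemographicParameterSet) -> EventSchedule:
    """Translate the 21 parameters into a coalescent event schedule.

    Backwards in time: the four stands (sizes ``POPSIZE_*``, forward growth
    ``GROWTHRATE0``, pairwise symmetric migration ``MIG_*``) merge at
    ``TIME1``/``TIME2``/``TIME3`` under the fixed topology, the merged
    population reaches the minimum-extent size at ``TIMEA``, and the deeper
    epochs follow the staged history described in the module docstring.
    """
    p = params
    g0 = p.GROWTHRATE0
    dem = msprime.Demography()
    for stand in STANDS:
        dem.add_population(
            name=stand,
            initial_size=getattr(p, f"POPSIZE_{stand}"),
            growth_rate=g0,
        )

    def size_at(name: str, t: float) -> float:
        """Size of a leaf/ancestor population at backwards time t (growth g0)."""
        return _initial_sizes[name] * math.exp(-g0 * t)

    _initial_sizes = {s: getattr(p, f"POPSIZE_{s}") for s in STANDS}

    events: list[tuple[float, str, str]] = []

    for a, b in STAND_PAIRS:
        m = p.migration_rate(a, b)
        if m > 0:
            dem.set_symmetric_migration_rate([a, b], m)

    # mergers; ancestral size = sum of children at merger time (mass conservation)
    merge_spec = [
        (p.TIME1, ("N3", "N4"), "ANC1"),
        (p.TIME2, ("ANC1", "S1"), "ANC2"),
        (p.TIME3, ("ANC2", "S5"), "ANC3"),
    ]
    for t, (left, right), anc in merge_spec:
        size_t = size_at(left, t) + size_at(right, t)
        # msprime initial_size refers to time 0; extrapolate along growth g0
        dem.add_population(
            name=anc, initial_size=size_t * math.exp(g0 * t), growth_rate=g0
        )
        _initial_sizes[anc] = size_t * math.exp(g0 * t)
        dem.add_population_split(time=t, derived=[left, right], ancestral=anc)
        events.append((t, "merge", f"{left}+{right} -> {anc} (size {size_t:.1f})"))

    n_min = size_at("ANC3", p.TIMEA)
    epoch_changes = [
        (p.TIMEA, n_min, 0.0, "stability at minimum extent"),
        (p.TIMEB, n_min, p.GROWTHRATE1, "contraction epoch (forward)"),
    ]
    n_c = n_min * math.exp(-p.GROWTHRATE1 * (p.TIMEC - p.TIMEB))
    epoch_changes += [
        (p.TIMEC, n_c, 0.0, "stability before contraction"),
        (p.TIMED, n_c, p.GROWTHRATE2, "deep expansion epoch (forward)"),
    ]
    n_e = n_c * math.exp(-p.GROWTHRATE2 * (p.TIMEE - p.TIMED))
    epoch_changes.append((p.TIMEE, n_e, 0.0, "constant ancestral population"))

    for t, size, rate, label in epoch_changes:
        dem.add_population_parameters_change(
            time=t, population="ANC3", initial_size=size, growth_rate=rate
        )
        events.append((t, "size/growth change", f"ANC3 size {size:.1f}, rate {rate}"))

    dem.sort_events()
    table = pd.DataFrame(events, columns=["time", "event", "detail"]).sort_values(
        "time", kind="stable", ignore_index=True
    )
    return EventSchedule(
        params=p, demography=dem, events=table, minimum_extent_size=n_min
    )


def _fragment_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(1, 2**31 - 1, size=n)


def simulate_fragments(
    schedule: EventSchedule | msprime.Demography,
    n_fragments: int = 750,
    fragment_bp: int | Sequence[int] = 1000,
    mu: float = DEFAULT_MU,
    rec_per_bp: float = DEFAULT_REC,
    sample_sizes: Mapping[str, int] | None = None,
    seed: int = 1,
    region_prefix: str = "frag",
) -> GenotypeDataset:
    """Simulate independent coalescent fragments and diploid genotypes.

    Each fragment is an independent ancestry simulation of ``fragment_bp``
    bases with intra-fragment recombination; biallelic variants are laid down
    under a binary (0/1) mutation model at rate ``mu``.  ``sample_sizes``
    maps population name to diploid sample count.  Deterministic given
    ``seed``.
    """
    dem = schedule.demography if isinstance(schedule, EventSchedule) else schedule
    if sample_sizes is None:
        sample_sizes = {s: 24 for s in STANDS}
    if any(n <= 0 for n in sample_sizes.values()):
        raise ValueError("all sample sizes must be positive")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")

    lengths = (
        [int(fragment_bp)] * n_fragments
        if np.isscalar(fragment_bp)
        else [int(x) for x in fragment_bp]
    )
    if len(lengths) != n_fragments:
        raise ValueError("fragment_bp sequence must have length n_fragments")

    anc_seeds = _fragment_seeds(seed, n_fragments)
    mut_seeds = _fragment_seeds(seed + 1, n_fragments)

    samples = make_sample_table({s: sample_sizes[s] for s in sample_sizes})
    n_ind = len(samples)

    geno_parts: list[np.ndarray] = []
    site_rows: list[tuple[str, int]] = []
    region_rows: list[tuple[str, int]] = []
    width = max(5, len(str(n_fragments)))

    uniform_len = len(set(lengths)) == 1

    def _one(ts, region_id):
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            model=msprime.BinaryMutationModel(),
            random_seed=int(mut_seeds[len(region_rows) - 1]),
        )
        if mts.num_sites:
            hap = mts.genotype_matrix()  # (sites, haploids) in {0,1}
            dip = hap.reshape(hap.shape[0], n_ind, 2).sum(axis=2).astype(np.int8)
            geno_parts.append(dip)
            for site in mts.sites():
                site_rows.append((region_id, int(site.position) + 1))

    common = dict(
        samples={k: v for k, v in sample_sizes.items()},
        demography=dem,
        recombination_rate=rec_per_bp,
        ploidy=2,
    )
    if uniform_len:
        reps = msprime.sim_ancestry(
            sequence_length=lengths[0],
            num_replicates=n_fragments,
            random_seed=int(anc_seeds[0]),
            **common,
        )
        for i, ts in enumerate(reps):
            region_id = f"{region_prefix}{i:0{width}d}"
            region_rows.append((region_id, lengths[i]))
            _one(ts, region_id)
    else:
        for i, L in enumerate(lengths):
            ts = msprime.sim_ancestry(
                sequence_length=L, random_seed=int(anc_seeds[i]), **common
            )
            region_id = f"{region_prefix}{i:0{width}d}"
            region_rows.append((region_id, L))
            _one(ts, region_id)

    if geno_parts:
        genotypes = np.vstack(geno_parts)
    else:
        genotypes = np.zeros((0, n_ind), dtype=np.int8)
    sites = pd.DataFrame(site_rows, columns=["region", "pos"])
    regions = pd.DataFrame(region_rows, columns=["region", "length"]).set_index(
        "region"
    )
    return GenotypeDataset(
        genotypes=genotypes, samples=samples, sites=sites, regions=regions
    )


def expected_joint_branch_sfs(
    demography: msprime.Demography,
    pair_sample_sizes: Mapping[str, int],
    pairs: Sequence[tuple[str, str]],
    n_fragments: int = 200,
    fragment_bp: int = 1000,
    rec_per_bp: float = DEFAULT_REC,
    seed: int = 1,
) -> dict[tuple[str, str], np.ndarray]:
    """Monte-Carlo expected unfolded joint SFS via branch statistics.

    Averages the branch-length allele-frequency spectrum over independent
    fragments; the result is proportional to the expected site spectrum
    (the mutation rate cancels once spectra are normalised to proportions),
    with far less Monte-Carlo noise than counting simulated mutations.
    """
    reps = msprime.sim_ancestry(
        samples=dict(pair_sample_sizes),
        demography=demography,
        sequence_length=fragment_bp,
        recombination_rate=rec_per_bp,
        num_replicates=n_fragments,
        random_seed=int(seed),
        ploidy=2,
    )
    totals: dict[tuple[str, str], np.ndarray] = {}
    pop_id = None
    for ts in reps:
        if pop_id is None:
            pop_id = {ts.population(j).metadata["name"]: j for j in range(ts.num_populations)}
        for pair in pairs:
            sets = [ts.samples(population=pop_id[pair[0]]),
                    ts.samples(population=pop_id[pair[1]])]
            afs = ts.allele_frequency_spectrum(
                sample_sets=sets, mode="branch", polarised=True, span_normalise=False
            )
            if pair in totals:
                totals[pair] += afs
            else:
                totals[pair] = afs
    return totals


def expected_new_mutations(
    genome_bp: float, mu: float, n_gametes: float, n_generations: float
) -> tuple[float, float]:
    """Expected new mutations per gamete and in a population.

    ``per_gamete = genome_bp * mu``; the population total multiplies by the
    number of gametes forming each generation and the number of generations
    elapsed.
    """
    if genome_bp <= 0 or n_gametes <= 0 or n_generations <= 0:
        raise ValueError("genome_bp, n_gametes and n_generations must be > 0")
    if mu < 0:
        raise ValueError("mutation rate must be >= 0")
    per_gamete = genome_bp * mu
    return per_gamete, per_gamete * n_gametes * n_generations
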