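"""Composite-likelihood demographic inference and uncertainty propagation.

Three stages mirror the analysis strategy:

(a) **estimation** — repeated derivative-free maximisation (Nelder–Mead with
    random restarts) of the composite log-likelihood of the observed folded
    joint spectra, where the expected spectra under candidate parameters are
    approximated by coalescent simulation;

(b) **uncertainty resampling** — the run-to-run distribution of estimates is
    summarised by "correlation blocks" of co-varying parameters; a core
    parameter per block is redrawn uniformly over its estimated range and the
    dependent parameters follow fitted linear regressions with residual
    noise, producing parameter sets that respect the estimated covariation;

(c) **neutral reference** — each resampled parameter set is simulated into an
    independent fragment set, and all fragments are compiled into one
    composite dataset that serves as the null for the outlier scans.

Expected spectra use branch-length statistics rather than simulated
mutations: the branch spectrum is proportional to the expected site spectrum,
so normalised proportions are identical in expectation while Monte-Carlo
noise is much lower.  Each optimisation run evaluates all candidates with
the same simulation seed (common random numbers), which makes the noisy
objective a fixed deterministic surface the simplex can descend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import msprime
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import linregress

from .dataset import GenotypeDataset, STAND_PAIRS, concat_datasets
from .demography import (
    DEFAULT_MU,
    DEFAULT_REC,
    PARAM_NAMES,
    DemographicParameterSet,
    build_event_schedule,
    expected_joint_branch_sfs,
    simulate_fragments,
)
from .sfs import Folded2DSFS, composite_loglik, fold_unfolded_counts


# ---------------------------------------------------------------------------
# model abstraction
# ---------------------------------------------------------------------------

class DemographicModel:
    """A named parameter vector mapped to an msprime demography.

    Subclasses define ``param_names``, ``pairs`` (population pairs whose
    joint spectra enter the likelihood), a transform between natural
    parameters and an unconstrained optimisation vector, and the demography
    builder.
    """

    param_names: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]

    def build(self, params: Mapping[str, float]) -> msprime.Demography:
        raise NotImplementedError

    def validate(self, params: Mapping[str, float]) -> bool:
        try:
            self.build(params)
            return True
        except (ValueError, KeyError):
            return False

    # -- optimisation coordinates -------------------------------------
    def to_vector(self, params: Mapping[str, float]) -> np.ndarray:
        raise NotImplementedError

    def from_vector(self, x: np.ndarray) -> dict[str, float]:
        raise NotImplementedError

    def random_start(
        self, ranges: Mapping[str, tuple[float, float]], rng: np.random.Generator
    ) -> dict[str, float]:
        """Log-uniform draw for positive parameters, uniform otherwise."""
        out = {}
        for name in self.param_names:
            lo, hi = ranges[name]
            if lo > 0 and hi > 0:
                out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                out[name] = float(rng.uniform(lo, hi))
        return out


class TwoPopModel(DemographicModel):
    """Reduced two-population split model with symmetric migration.

    Parameters: current sizes ``N1``/``N2``, ancestral size ``NANC``,
    symmetric migration rate ``MIG`` and split time ``TSPLIT`` (generations).
    Used for parameter-recovery studies where the full staged model would be
    under-determined.
    """

    param_names = ("N1", "N2", "NANC", "MIG", "TSPLIT")
    pairs = (("P1", "P2"),)

    def build(self, params: Mapping[str, float]) -> msprime.Demography:
        if min(params["N1"], params["N2"], params["NANC"]) <= 0:
            raise ValueError("population sizes must be > 0")
        if params["MIG"] < 0 or params["TSPLIT"] <= 0:
            raise ValueError("MIG must be >= 0 and TSPLIT > 0")
        dem = msprime.Demography()
        dem.add_population(name="P1", initial_size=params["N1"])
        dem.add_population(name="P2", initial_size=params["N2"])
        dem.add_population(name="ANC", initial_size=params["NANC"])
        if params["MIG"] > 0:
            dem.set_symmetric_migration_rate(["P1", "P2"], params["MIG"])
        dem.add_population_split(
            time=params["TSPLIT"], derived=["P1", "P2"], ancestral="ANC"
        )
        return dem

    def to_vector(self, params: Mapping[str, float]) -> np.ndarray:
        return np.array(
            [
                np.log(params["N1"]),
                np.log(params["N2"]),
                np.log(params["NANC"]),
                np.log(max(params["MIG"], 1e-12)),
                np.log(params["TSPLIT"]),
            ]
        )

    def from_vector(self, x: np.ndarray) -> dict[str, float]:
        n1, n2, nanc, mig, t = np.exp(x)
        return {"N1": n1, "N2": n2, "NANC": nanc, "MIG": mig, "TSPLIT": t}


class FourStandModel(DemographicModel):
    """The full 21-parameter staged model over the four stands.

    Optimisation coordinates keep the hard invariants satisfied by
    construction: sizes, migration rates and the first merger time are
    log-transformed, later event times are parameterised as log-increments
    over the preceding time, and growth rates stay linear.
    """

    param_names = PARAM_NAMES
    pairs = STAND_PAIRS

    _log_names = (
        "POPSIZE_N3", "POPSIZE_N4", "POPSIZE_S1", "POPSIZE_S5",
        "MIG_N3_N4", "MIG_N3_S1", "MIG_N3_S5",
        "MIG_N4_S1", "MIG_N4_S5", "MIG_S1_S5",
    )
    _time_names = ("TIME1", "TIME2", "TIME3", "TIMEA", "TIMEB", "TIMEC", "TIMED", "TIMEE")
    _growth_names = ("GROWTHRATE0", "GROWTHRATE1", "GROWTHRATE2")

    def build(self, params: Mapping[str, float]) -> msprime.Demography:
        pset = DemographicParameterSet.from_mapping(params)
        return build_event_schedule(pset).demography

    def to_vector(self, params: Mapping[str, float]) -> np.ndarray:
        x = [np.log(max(params[n], 1e-12)) for n in self._log_names]
        prev = 0.0
        for n in self._time_names:
            inc = max(params[n] - prev, 1e-9)
            x.append(np.log(inc))
            prev = params[n]
        x.extend(params[n] for n in self._growth_names)
        return np.array(x)

    def from_vector(self, x: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        k = len(self._log_names)
        for n, v in zip(self._log_names, x[:k]):
            out[n] = float(np.exp(v))
        t = 0.0
        for i, n in enumerate(self._time_names):
            t += float(np.exp(x[k + i]))
            out[n] = t
        k += len(self._time_names)
        for i, n in enumerate(self._growth_names):
            out[n] = float(x[k + i])
        return out


# ---------------------------------------------------------------------------
# parameter ensembles
# ---------------------------------------------------------------------------

@dataclass
class ParameterEnsemble:
    """A collection of parameter sets with provenance."""

    table: pd.DataFrame  # one row per set; parameter columns (+ optional loglik)
    provenance: str = "ml_runs"  # or "resampled"

    def __len__(self) -> int:
        return len(self.table)

    def param_columns(self) -> list[str]:
        return [c for c in self.table.columns if c != "loglik"]

    def row(self, i: int) -> dict[str, float]:
        return {c: float(self.table.iloc[i][c]) for c in self.param_columns()}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, provenance: str = "ml_runs") -> "ParameterEnsemble":
        return cls(pd.read_csv(path, sep="\t"), provenance=provenance)


# ---------------------------------------------------------------------------
# step (a): maximum composite likelihood estimation
# ---------------------------------------------------------------------------

def _expected_spectra(
    model: DemographicModel,
    params: Mapping[str, float],
    sample_sizes: Mapping[str, int],
    sims_per_eval: int,
    fragment_bp: int,
    rec_per_bp: float,
    seed: int,
) -> list[Folded2DSFS]:
    dem = model.build(params)
    totals = expected_joint_branch_sfs(
        dem,
        pair_sample_sizes=sample_sizes,
        pairs=model.pairs,
        n_fragments=sims_per_eval,
        fragment_bp=fragment_bp,
        rec_per_bp=rec_per_bp,
        seed=seed,
    )
    return [fold_unfolded_counts(totals[p], p) for p in model.pairs]


def anchored_loglik(
    observed: Sequence[Folded2DSFS],
    expected_branch: Sequence[Folded2DSFS],
    mu: float,
    obs_total_bases: float,
    sim_total_bases: float,
) -> float:
    """Composite log-likelihood including the monomorphic class.

    ``expected_branch`` holds folded spectra of summed branch lengths over
    the simulated fragments; multiplying by ``mu / sim_total_bases`` turns
    each cell into a per-base SNP probability, and the remaining mass is the
    monomorphic probability.  Including the monomorphic class anchors the
    absolute parameter scale (sizes and times), which the shape of the
    polymorphic spectrum alone cannot identify.
    """
    total = 0.0
    for obs, exp in zip(observed, expected_branch):
        if obs.n_proj != exp.n_proj:
            raise ValueError(
                f"projection mismatch for pair {obs.pair}: "
                f"{obs.n_proj} vs {exp.n_proj}"
            )
        poly = exp.mask.copy()
        poly[0, 0] = False
        p = exp.matrix.copy().astype(float)
        p[~poly] = 0.0
        p = mu * p / sim_total_bases
        positive = p[poly][p[poly] > 0]
        if positive.size == 0:
            return -1e12
        p[poly & (p <= 0)] = positive.min() * 1e-3
        p_mono = 1.0 - p[poly].sum()
        if p_mono <= 0:
            return -1e12
        o = obs.matrix.copy().astype(float)
        o[~poly] = 0.0
        n_poly = o[poly]
        n_mono = obs_total_bases - n_poly.sum()
        total += float((n_poly * np.log(p[poly])).sum() + n_mono * np.log(p_mono))
    return total


def estimate_parameters(
    observed: Sequence[Folded2DSFS],
    starting_ranges: Mapping[str, tuple[float, float]],
    model: DemographicModel | None = None,
    n_runs: int = 100,
    sims_per_eval: int = 200,
    seed: int = 1,
    sample_sizes: Mapping[str, int] | None = None,
    fragment_bp: int = 1000,
    rec_per_bp: float = DEFAULT_REC,
    maxfev: int = 200,
    mu: float = DEFAULT_MU,
    obs_total_bases: float | None = None,
) -> ParameterEnsemble:
    """Repeated ML estimation of demographic parameters from joint spectra.

    Each run starts from an independent draw within ``starting_ranges`` and
    maximises the composite log-likelihood with Nelder–Mead in the model's
    unconstrained coordinates; the search may leave the starting ranges but
    never violates the hard parameter invariants.  Returns one parameter
    vector per run together with its log-likelihood.

    With ``obs_total_bases`` given (total sequenced bases behind the observed
    spectra, invariant sites included) the likelihood also scores the
    monomorphic class at mutation rate ``mu``, which anchors the absolute
    parameter scale; otherwise only the polymorphic spectrum shape is used
    and parameters are identified up to a scale factor at best.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if model is None:
        model = FourStandModel()
    missing = [n for n in model.param_names if n not in starting_ranges]
    if missing:
        raise ValueError(f"starting_ranges missing parameters: {missing}")
    if sample_sizes is None:
        n_proj = {}
        for obs in observed:
            a, b = obs.pair
            n_proj[a] = obs.n_proj[0] // 2
            n_proj[b] = obs.n_proj[1] // 2
        sample_sizes = n_proj

    rng = np.random.default_rng(seed)
    rows = []
    for run in range(n_runs):
        eval_seed = int(rng.integers(1, 2**31 - 1))
        start = model.random_start(starting_ranges, rng)
        x0 = model.to_vector(start)

        def negloglik(x: np.ndarray) -> float:
            params = model.from_vector(x)
            try:
                expected = _expected_spectra(
                    model, params, sample_sizes, sims_per_eval,
                    fragment_bp, rec_per_bp, eval_seed,
                )
                if obs_total_bases is not None:
                    return -anchored_loglik(
                        list(observed), expected, mu, obs_total_bases,
                        sims_per_eval * fragment_bp,
                    )
                return -composite_loglik(list(observed), expected)
            except Exception:
                # invalid candidate demography: worst possible objective
                return 1e12

        res = minimize(
            negloglik,
            x0,
            method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-3},
        )
        best = model.from_vector(res.x)
        best["loglik"] = -float(res.fun)
        rows.append(best)
    table = pd.DataFrame(rows, columns=list(model.param_names) + ["loglik"])
    return ParameterEnsemble(table=table, provenance="ml_runs")


# ---------------------------------------------------------------------------
# step (b): correlation blocks and resampling
# ---------------------------------------------------------------------------

@dataclass
class CorrelationBlocks:
    """Connected components of the |r| >= threshold parameter graph."""

    blocks: list[list[str]]
    cores: list[str]
    r_threshold: float
    correlations: pd.DataFrame
    constant: list[str] = field(default_factory=list)

    def block_of(self, name: str) -> int:
        for i, b in enumerate(self.blocks):
            if name in b:
                return i
        raise KeyError(name)


def correlation_blocks(
    ensemble: ParameterEnsemble, r_threshold: float = 0.7
) -> CorrelationBlocks:
    """Group parameters into blocks of mutually correlated ML estimates.

    Edges connect parameters with ``|Pearson r| >= r_threshold``; blocks are
    the connected components.  The core of a block is the member with the
    largest sum of ``|r|`` to the other members (ties broken by column
    order).  Constant columns cannot enter a correlation and become their own
    singleton blocks.
    """
    if len(ensemble) < 3:
        raise ValueError("need at least 3 parameter sets to estimate correlations")
    cols = ensemble.param_columns()
    tab = ensemble.table[cols]
    constant = [c for c in cols if tab[c].nunique() <= 1 or tab[c].std() == 0]
    varying = [c for c in cols if c not in constant]
    corr = tab[varying].corr()

    parent = {c: c for c in varying}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(varying):
        for b in varying[i + 1:]:
            if abs(corr.loc[a, b]) >= r_threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    groups: dict[str, list[str]] = {}
    for c in varying:
        groups.setdefault(find(c), []).append(c)

    blocks: list[list[str]] = []
    cores: list[str] = []
    order = {c: i for i, c in enumerate(cols)}
    for root in sorted(groups, key=lambda r: order[min(groups[r], key=order.get)]):
        members = sorted(groups[root], key=order.get)
        if len(members) == 1:
            core = members[0]
        else:
            strength = {
                m: sum(abs(corr.loc[m, o]) for o in members if o != m)
                for m in members
            }
            best = max(strength.values())
            core = min((m for m in members if strength[m] == best), key=order.get)
        blocks.append(members)
        cores.append(core)
    for c in constant:
        blocks.append([c])
        cores.append(c)
    return CorrelationBlocks(
        blocks=blocks, cores=cores, r_threshold=r_threshold,
        correlations=corr, constant=constant,
    )


def resample_parameter_sets(
    ensemble: ParameterEnsemble,
    blocks: CorrelationBlocks,
    n: int = 100,
    seed: int = 1,
    validator: Callable[[Mapping[str, float]], bool] | None = None,
    max_attempts: int = 1000,
) -> ParameterEnsemble:
    """Draw parameter sets that respect the estimated parameter covariation.

    Per draw, each block's core parameter is sampled uniformly between the
    minimum and maximum of its ML distribution; dependent parameters follow
    their fitted linear regression on the core plus Gaussian residual noise.
    Rates are clamped at zero from below; candidates violating the hard
    invariants (positivity, time ordering) are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    cols = ensemble.param_columns()
    tab = ensemble.table[cols]
    if validator is None:
        if set(PARAM_NAMES) <= set(cols):
            def validator(params):
                try:
                    DemographicParameterSet.from_mapping(params)
                    return True
                except ValueError:
                    return False
        else:
            def validator(params):
                return True

    regressions: dict[str, tuple[str, float, float, float]] = {}
    fallback_uniform: list[str] = []
    for block, core in zip(blocks.blocks, blocks.cores):
        for dep in block:
            if dep == core:
                continue
            xy = tab[[core, dep]].dropna()
            if len(xy) < 3:
                fallback_uniform.append(dep)
                continue
            fit = linregress(xy[core], xy[dep])
            resid = xy[dep] - (fit.intercept + fit.slope * xy[core])
            regressions[dep] = (core, fit.intercept, fit.slope, float(resid.std(ddof=2)))

    lo = tab.min()
    hi = tab.max()

    rows = []
    for _ in range(n):
        for attempt in range(max_attempts):
            cand: dict[str, float] = {}
            for block, core in zip(blocks.blocks, blocks.cores):
                cand[core] = float(rng.uniform(lo[core], hi[core]))
                for dep in block:
                    if dep == core:
                        continue
                    if dep in regressions:
                        c, a, b, sd = regressions[dep]
                        cand[dep] = float(a + b * cand[c] + rng.normal(0.0, sd))
                    else:
                        cand[dep] = float(rng.uniform(lo[dep], hi[dep]))
            # clamp rates to their domain before rejecting on hard invariants
            for name in cand:
                if name.startswith("MIG") and cand[name] < 0:
                    cand[name] = 0.0
            if validator(cand):
                rows.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw a valid parameter set in {max_attempts} attempts"
            )
    table = pd.DataFrame(rows, columns=cols)
    out = ParameterEnsemble(table=table, provenance="resampled")
    out.fallback_uniform = fallback_uniform  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# step (c): the compiled neutral reference
# ---------------------------------------------------------------------------

def build_neutral_reference(
    param_sets: ParameterEnsemble,
    fragments_per_set: int = 750,
    fragment_bp: int = 1000,
    sample_sizes: Mapping[str, int] | None = None,
    mu: float = DEFAULT_MU,
    rec_per_bp: float = DEFAULT_REC,
    seed: int = 1,
    model: DemographicModel | None = None,
) -> GenotypeDataset:
    """Simulate every parameter set and compile one composite null dataset.

    Fragment region ids carry the source set (``setNN_fragMMMMM``) and the
    region table gains a ``source_set`` column, so downstream statistics can
    trace each null locus to the parameter set that generated it.
    """
    if model is None:
        model = FourStandModel()
    rng = np.random.default_rng(seed)
    parts = []
    for i in range(len(param_sets)):
        params = param_sets.row(i)
        dem = model.build(params)
        ds = simulate_fragments(
            dem,
            n_fragments=fragments_per_set,
            fragment_bp=fragment_bp,
            mu=mu,
            rec_per_bp=rec_per_bp,
            sample_sizes=sample_sizes,
            seed=int(rng.integers(1, 2**31 - 1)),
            region_prefix=f"set{i:03d}_frag",
        )
        ds.regions["source_set"] = i
        parts.append(ds)
    return concat_datasets(parts)
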