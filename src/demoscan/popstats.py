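"""Diversity and differentiation statistics with bootstrap support.

Implements per-base nucleotide diversity over whole target regions
(invariant sites included), the Weir & Cockerham (1984) variance-component
F_ST estimator (multi-locus ratio of sums), a hierarchical variance
decomposition over slope / stand-within-slope / individual levels, pairwise
F_ST and Jost's D matrices, locus (region) bootstrap confidence intervals,
and UPGMA clustering of pairwise distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityTable:
    """Per-region and per-stand nucleotide diversity (per base)."""

    per_region: pd.DataFrame  # index region; columns: one per stand
    per_stand: pd.Series  # length-weighted stand means

    def __repr__(self) -> str:  # pragma: no cover
        return f"DiversityTable(stands={dict(self.per_stand.round(6))})"


def nucleotide_diversity(
    data: GenotypeDataset, stands: Sequence[str] | None = None
) -> DiversityTable:
    """Average pairwise diversity per base, invariant sites included.

    Per region and stand: ``pi = sum_sites 2*p*q*n/(n-1) / region_length``
    with ``n`` the called chromosome count at the site.  The stand value is
    the length-weighted mean over regions, i.e. the average over all
    sequenced nucleotides.
    """
    if stands is None:
        stands = data.stands
    lengths = data.regions["length"].astype(float)
    region_index = data.regions.index
    out = {}
    for stand in stands:
        alt, n = data.allele_counts(stand)
        if (n < 2).all() and data.n_sites:
            raise ValueError(f"stand {stand} has fewer than 2 called chromosomes")
        ok = n >= 2
        p = np.zeros(data.n_sites)
        het = np.zeros(data.n_sites)
        p[ok] = alt[ok] / n[ok]
        het[ok] = 2 * p[ok] * (1 - p[ok]) * n[ok] / (n[ok] - 1)
        sums = (
            pd.Series(het, index=data.sites["region"].values)
            .groupby(level=0)
            .sum()
            .reindex(region_index, fill_value=0.0)
        )
        out[stand] = sums / lengths
    per_region = pd.DataFrame(out)
    weights = lengths / lengths.sum()
    per_stand = (per_region.mul(weights, axis=0)).sum()
    return DiversityTable(per_region=per_region, per_stand=per_stand)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(
    data: GenotypeDataset, stands: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) a, b, c variance components."""
    r = len(stands)
    if r < 2:
        raise ValueError("need at least 2 stands")
    n_i = np.zeros((data.n_sites, r))
    p_i = np.zeros((data.n_sites, r))
    h_i = np.zeros((data.n_sites, r))
    for k, stand in enumerate(stands):
        g = data.genotypes[:, data.stand_columns(stand)]
        called = g >= 0
        n_called = called.sum(axis=1)
        n_i[:, k] = n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[:, k] = np.where(
                n_called > 0, np.where(called, g, 0).sum(axis=1) / (2 * n_called), 0.0
            )
            h_i[:, k] = np.where(
                n_called > 0, (g == 1).sum(axis=1) / n_called, 0.0
            )
    nbar = n_i.mean(axis=1)
    ok = (n_i > 0).all(axis=1) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=1) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=1) / (r * nbar)
        s2 = (n_i * (p_i - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=1) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    c = np.where(ok, c, 0.0)
    # degenerate nc (all samples in one pop after missingness) guards
    bad = ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    a[bad] = b[bad] = c[bad] = 0.0
    return a, b, c


def wc_fst(data: GenotypeDataset, stands: Sequence[str] | None = None) -> float:
    """Multi-locus Weir & Cockerham F_ST (ratio of summed components)."""
    if stands is None:
        stands = data.stands
    a, b, c = _wc_components(data, stands)
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


@dataclass
class HierarchicalComponents:
    """Variance components of the slope / stand / individual hierarchy."""

    components: pd.Series  # sigma2 for slope, stand, individual, allele
    f_slope_total: float
    f_stand_total: float  # differentiation of stands relative to the total
    f_stand_slope: float
    flags: list[str]


def _henderson_nested(
    y: np.ndarray, levels: list[np.ndarray]
) -> np.ndarray | None:
    """Henderson method-I variance components for a nested random model.

    ``y`` is the vector of allele indicators; ``levels`` are nested grouping
    vectors ordered outermost first (e.g. slope, stand, individual).  Returns
    the estimated components (outermost first, residual last), or None when
    the design is degenerate.
    """
    n = len(y)
    if n == 0:
        return None
    groupings = levels + [np.arange(n)]  # innermost: one group per observation
    q = len(groupings)  # number of random components excluding residual... see below
    # T statistics: T_l = sum over groups at level l of (group sum)^2 / group size
    # plus T_mu = (grand sum)^2 / n and T_0 = sum y^2 (residual level).
    sums = []
    sizes_list = []
    for g in groupings:
        codes, _ = pd.factorize(g)
        s = np.bincount(codes, weights=y)
        cnt = np.bincount(codes)
        sums.append(s)
        sizes_list.append(cnt)
        # keep codes for coefficient computation
    T = [float((s**2 / c).sum()) for s, c in zip(sums, sizes_list)]
    T_mu = float(y.sum() ** 2 / n)

    # coefficients: E[T_l] = sum_u (1/n_u) [ n_u^2 mu^2 + sum_m sigma_m^2 sum_g c_{u,g}^2 + n_u sigma_e^2 ]
    # where c_{u,g} = overlap count of group u (level l) and group g (level m).
    ncomp = q  # components: one per grouping level (last equals residual obs-level)
    A = np.zeros((ncomp + 1, ncomp + 1))  # unknowns: sigma^2 per level..., mu^2
    rhs = np.zeros(ncomp + 1)
    frames = [pd.factorize(g)[0] for g in groupings]
    for li in range(ncomp):
        gl = frames[li]
        nu = sizes_list[li].astype(float)
        for mi in range(ncomp):
            gm = frames[mi]
            # sum over groups u at level li of (1/n_u) * sum_g c_{u,g}^2
            overlap = pd.crosstab(gl, gm).to_numpy().astype(float)
            A[li, mi] = float(((overlap**2).sum(axis=1) / nu).sum())
        A[li, ncomp] = float((nu**2 / nu).sum())  # = sum n_u
        rhs[li] = T[li]
    # T_mu row
    for mi in range(ncomp):
        gm = frames[mi]
        cnt = sizes_list[mi].astype(float)
        A[ncomp, mi] = float((cnt**2).sum() / n)
    A[ncomp, ncomp] = float(n)
    rhs[ncomp] = T_mu
    # least squares handles confounded levels (e.g. one stand per slope):
    # the minimum-norm solution spreads an unseparable component over the
    # confounded levels, leaving their sum meaningful
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank == 0:
        return None
    return sol[:ncomp]  # outermost ... innermost(residual) variance components


def wc_fst_global(data: GenotypeDataset) -> HierarchicalComponents:
    """Hierarchical variance decomposition: slope / stand / individual.

    Sums Henderson method-I components per locus over loci and derives the
    hierarchical fixation indices as ratios of summed components.  A level
    with a single group is flagged and its component reported as NaN.
    """
    flags: list[str] = []
    slopes = data.samples["slope"].to_numpy()
    stands = data.samples["stand"].to_numpy()
    if len(np.unique(stands)) < 2:
        raise ValueError("need at least 2 stands")
    single_slope = len(np.unique(slopes)) < 2
    if single_slope:
        flags.append("slope level has a single group; component undefined")

    totals = np.zeros(4)  # slope, stand, individual, allele(residual)
    n_used = 0
    for s in range(data.n_sites):
        g = data.genotypes[s]
        called = g >= 0
        if called.sum() < 2:
            continue
        # expand diploids into allele indicator observations
        idx = np.flatnonzero(called)
        y = np.concatenate([[min(g[i], 1), 1 if g[i] == 2 else 0] for i in idx])
        ind = np.repeat(idx, 2)
        lv = [slopes[ind], stands[ind], ind] if not single_slope else [stands[ind], ind]
        comps = _henderson_nested(y.astype(float), lv)
        if comps is None:
            continue
        if single_slope:
            comps = np.concatenate([[0.0], comps])
        totals += comps
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable loci for hierarchical decomposition")
    total_var = totals.sum()
    comp = pd.Series(totals, index=["slope", "stand", "individual", "allele"])
    if total_var == 0:
        f_slope = f_stand_total = f_stand_slope = float("nan")
        flags.append("zero total variance")
    else:
        f_slope = totals[0] / total_var
        f_stand_total = (totals[0] + totals[1]) / total_var
        denom = total_var - totals[0]
        f_stand_slope = totals[1] / denom if denom != 0 else float("nan")
    if single_slope:
        comp["slope"] = float("nan")
        f_slope = float("nan")
    return HierarchicalComponents(
        components=comp,
        f_slope_total=float(f_slope),
        f_stand_total=float(f_stand_total),
        f_stand_slope=float(f_stand_slope),
        flags=flags,
    )


def pairwise_fst(data: GenotypeDataset) -> pd.DataFrame:
    """Weir & Cockerham F_ST for every stand pair (raw, may be negative)."""
    stands = data.stands
    out = pd.DataFrame(np.nan, index=stands, columns=stands, dtype=float)
    for a, b in combinations(stands, 2):
        value = wc_fst(data, [a, b])
        out.loc[a, b] = out.loc[b, a] = value
    return out


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def josts_d_pair(data: GenotypeDataset, stand_a: str, stand_b: str) -> float:
    """Two-population Jost's D, multi-locus ratio-of-averages form.

    Per locus: ``H_S`` is the mean within-stand expected heterozygosity and
    ``H_T`` the expected heterozygosity of mean allele frequencies;
    ``D = 2 * (H_T - H_S) / (1 - H_S)`` aggregated as
    ``2 * sum(H_T - H_S) / sum(1 - H_S)`` over loci.
    """
    hs_list = []
    ht_list = []
    for stand in (stand_a, stand_b):
        alt, n = data.allele_counts(stand)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / n, np.nan)
        hs_list.append(2 * p * (1 - p))
        ht_list.append(p)
    hs = np.nanmean(np.stack(hs_list), axis=0)
    pbar = np.nanmean(np.stack(ht_list), axis=0)
    ht = 2 * pbar * (1 - pbar)
    ok = np.isfinite(hs) & np.isfinite(ht)
    if not ok.any():
        return float("nan")
    denom = (1 - hs[ok]).sum()
    if denom == 0:
        return float("nan")
    return float(2 * (ht[ok] - hs[ok]).sum() / denom)


def josts_d(data: GenotypeDataset) -> pd.DataFrame:
    stands = data.stands
    out = pd.DataFrame(np.nan, index=stands, columns=stands, dtype=float)
    for a, b in combinations(stands, 2):
        out.loc[a, b] = out.loc[b, a] = josts_d_pair(data, a, b)
    return out


# ---------------------------------------------------------------------------
# bootstrap over loci (regions)
# ---------------------------------------------------------------------------

def bootstrap_ci(
    statistic: Callable[[GenotypeDataset], float],
    data: GenotypeDataset,
    B: int = 1000,
    levels: Sequence[float] = (0.95, 0.99),
    seed: int = 1,
) -> dict:
    """Percentile bootstrap over target regions.

    Regions are resampled with replacement ``B`` times and the statistic is
    recomputed on each pseudo-dataset.  Returns the point estimate, the
    bootstrap replicates, and the percentile confidence interval per level;
    a differentiation statistic is "significant" when its CI excludes 0.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    region_ids = list(data.regions.index)
    if len(region_ids) < 2:
        raise ValueError("need at least 2 regions to bootstrap")
    site_regions = data.sites["region"].to_numpy()
    rows_of = {r: np.flatnonzero(site_regions == r) for r in region_ids}
    rng = np.random.default_rng(seed)
    point = float(statistic(data))
    reps = np.empty(B)
    for b in range(B):
        chosen = rng.choice(region_ids, size=len(region_ids), replace=True)
        rows = np.concatenate([rows_of[r] for r in chosen]) if region_ids else []
        sites = data.sites.iloc[rows].copy()
        # relabel duplicated regions so region-level statistics see distinct loci
        offsets = []
        counter: dict[str, int] = {}
        for r in chosen:
            counter[r] = counter.get(r, 0) + 1
            offsets.append(f"{r}~{counter[r]}")
        new_region_col = np.concatenate(
            [np.repeat(lbl, len(rows_of[r])) for r, lbl in zip(chosen, offsets)]
        ) if len(rows) else np.array([], dtype=object)
        sites["region"] = new_region_col
        regions = pd.DataFrame(
            {"length": [data.regions.loc[r, "length"] for r in chosen]},
            index=pd.Index(offsets, name="region"),
        )
        pseudo = GenotypeDataset(
            genotypes=data.genotypes[rows] if len(rows) else
            np.zeros((0, data.n_samples), np.int8),
            samples=data.samples.copy(),
            sites=sites,
            regions=regions,
        )
        reps[b] = statistic(pseudo)
    out = {"point": point, "replicates": reps, "ci": {}}
    for level in levels:
        alpha = (1 - level) / 2
        lo, hi = np.nanquantile(reps, [alpha, 1 - alpha])
        out["ci"][level] = (float(lo), float(hi))
        out.setdefault("significant", {})[level] = not (lo <= 0 <= hi)
    return out


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma_tree(dist: pd.DataFrame) -> str:
    """UPGMA agglomeration of a symmetric distance matrix; newick output.

    Negative entries are truncated to 0 first; ties are broken by
    lexicographic order of cluster labels.  Branch lengths are ultrametric
    (leaf-to-root distances all equal).
    """
    if not np.allclose(dist.values, dist.values.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    labels = list(dist.index)
    d = {
        frozenset((a, b)): max(float(dist.loc[a, b]), 0.0)
        for a, b in combinations(labels, 2)
    }
    clusters: dict[str, dict] = {
        lab: {"newick": lab, "size": 1, "height": 0.0, "label": lab} for lab in labels
    }
    while len(clusters) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted(c for c in kv[0]))),
        )
        (pair, dmin) = best
        a, b = sorted(pair)
        ca, cb = clusters.pop(a), clusters.pop(b)
        height = dmin / 2.0
        new_label = min(a, b)
        newick = (
            f"({ca['newick']}:{height - ca['height']:g},"
            f"{cb['newick']}:{height - cb['height']:g})"
        )
        merged = {
            "newick": newick,
            "size": ca["size"] + cb["size"],
            "height": height,
            "label": new_label,
        }
        # update distances: size-weighted average over member leaves (UPGMA)
        new_d = {}
        for key, value in d.items():
            if a in key or b in key:
                continue
            new_d[key] = value
        for other in clusters:
            da = d[frozenset((a, other))]
            db = d[frozenset((b, other))]
            new_d[frozenset((new_label, other))] = (
                ca["size"] * da + cb["size"] * db
            ) / (ca["size"] + cb["size"])
        clusters[new_label] = merged
        d = new_d
    (root,) = clusters.values()
    return root["newick"] + ";"
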