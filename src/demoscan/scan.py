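"""Divergence-outlier scans against a demography-aware simulated null.

Three divergence statistics are supported:

* **G2D** — the multinomial composite-likelihood-ratio (G-test) statistic
  comparing a target region's folded joint-SFS cell frequencies with the
  genome-wide cell frequencies; region level, needs >= 2 SNPs.
* **AFD** — absolute allele-frequency difference between the two stands;
  SNP level.
* **PHI_ST** — the mode of the locus-specific posterior of an AMOVA-style
  fixation index under a hierarchical Balding–Nichols model, sampled by
  Metropolis-within-Gibbs, with a deterministic moment (AMOVA) estimator as
  fallback and cross-check; SNP level.

Each empirical statistic is ranked within the corresponding statistic
computed on the compiled simulated null ("empirical-null p-value",
``p = max(r, 1)/N`` in the upper tail), p-values are converted to Storey
q-values, and outliers are flagged at a false-discovery rate of 0.01.  The
shift between empirical and simulated statistic distributions classifies
each test as liberal, unbiased, or conservative (two-sided rank-sum test).
A Savage–Dickey Bayes-factor search on the same posterior machinery gives
the non-demography-controlled ("standard") scan for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.stats import gaussian_kde, mannwhitneyu

from .dataset import STAND_PAIRS, GenotypeDataset, pair_label
from .filtering import subset_pair
from .sfs import default_projection, fold_mask, site_cell_weights

METHODS = ("G2D", "AFD", "PHI_ST")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def g2d(region_cell_counts: np.ndarray, genomewide_proportions: np.ndarray) -> float:
    """Multinomial G statistic of region vs genome-wide cell frequencies.

    ``G2D = 2 * sum_c n_c * ln((n_c/n) / p_c)`` over occupied cells; the
    region must carry at least 2 SNPs (``sum n_c >= 2``).
    """
    counts = np.asarray(region_cell_counts, dtype=float)
    props = np.asarray(genomewide_proportions, dtype=float)
    if counts.shape != props.shape:
        raise ValueError("cell counts and proportions differ in shape")
    n = counts.sum()
    if n < 2:
        raise ValueError("G2D requires a region with at least 2 SNPs")
    occ = counts > 0
    if (props[occ] <= 0).any():
        raise ValueError("genome-wide proportions must be positive on occupied cells")
    return float(2.0 * (counts[occ] * np.log((counts[occ] / n) / props[occ])).sum())


def afd(freq_a: float | np.ndarray, freq_b: float | np.ndarray) -> float | np.ndarray:
    """Absolute allele-frequency difference."""
    fa = np.asarray(freq_a, dtype=float)
    fb = np.asarray(freq_b, dtype=float)
    if ((fa < 0) | (fa > 1) | (fb < 0) | (fb > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    out = np.abs(fa - fb)
    return float(out) if out.ndim == 0 else out


def moment_phi_st(
    alt_a: np.ndarray, chrom_a: np.ndarray, alt_b: np.ndarray, chrom_b: np.ndarray
) -> np.ndarray:
    """Moment (AMOVA) estimator of the two-stand fixation index per locus.

    One-way analysis of molecular variance on allele indicators:
    ``phi = sigma2_among / (sigma2_among + sigma2_within)``.
    """
    alt_a = np.asarray(alt_a, float)
    alt_b = np.asarray(alt_b, float)
    na = np.asarray(chrom_a, float)
    nb = np.asarray(chrom_b, float)
    n = na + nb
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = alt_a / na
        pb = alt_b / nb
        pw = (alt_a + alt_b) / n
        ssd_within = na * pa * (1 - pa) + nb * pb * (1 - pb)
        ssd_among = na * (pa - pw) ** 2 + nb * (pb - pw) ** 2
        ms_within = ssd_within / (n - 2)
        n0 = (n - (na**2 + nb**2) / n)  # / (r - 1) with r = 2
        sigma_a = (ssd_among - ms_within) / n0
        phi = sigma_a / (sigma_a + ms_within)
    return np.where(np.isfinite(phi), phi, 0.0)


# -- hierarchical Bayesian Phi_ST -------------------------------------------

@dataclass
class PhiPosterior:
    """Posterior summaries of the locus-specific fixation index."""

    modes: np.ndarray
    samples: np.ndarray  # (n_loci, n_kept) post burn-in, chains concatenated
    rhat: np.ndarray
    converged: np.ndarray
    moment: np.ndarray


def _betabinom_logpmf(k: np.ndarray, n: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Beta-binomial log-likelihood up to the k-constant (fixed per locus)."""
    from scipy.special import betaln

    return betaln(k + a, n - k + b) - betaln(a, b)


def phi_st_posterior(
    alt_a: np.ndarray,
    chrom_a: np.ndarray,
    alt_b: np.ndarray,
    chrom_b: np.ndarray,
    n_iter: int = 3000,
    burn_in: int = 1000,
    n_chains: int = 2,
    seed: int = 1,
    rhat_threshold: float = 1.2,
    step: float = 0.15,
) -> PhiPosterior:
    """Metropolis-within-Gibbs sampling of locus-specific fixation indices.

    Hierarchical model per locus: a pair-wide frequency ``pi ~ U(0,1)`` and a
    locus-specific index ``phi ~ U(0,1)`` parameterise a Balding–Nichols
    distribution ``p_s ~ Beta(pi (1-phi)/phi, (1-pi)(1-phi)/phi)`` for each
    stand's allele frequency; the stand frequencies are integrated out
    analytically, leaving a beta-binomial likelihood for the observed allele
    counts.  All loci are updated in parallel (vectorised random-walk
    proposals with reflection at the boundaries).  Non-converged loci
    (split-chain diagnostic above ``rhat_threshold``) are flagged and their
    moment estimate substituted for the mode.
    """
    alt_a = np.asarray(alt_a, float)
    alt_b = np.asarray(alt_b, float)
    na = np.asarray(chrom_a, float)
    nb = np.asarray(chrom_b, float)
    if ((na < 2) | (nb < 2)).any():
        raise ValueError("each stand needs >= 2 called chromosomes per locus")
    L = len(alt_a)
    rng = np.random.default_rng(seed)

    def reflect(x):
        x = np.mod(x, 2.0)
        return np.where(x > 1.0, 2.0 - x, x)

    def logpost(pi, phi):
        conc = (1.0 - phi) / np.clip(phi, 1e-9, None)
        a = np.clip(pi * conc, 1e-9, None)
        b = np.clip((1.0 - pi) * conc, 1e-9, None)
        return (
            _betabinom_logpmf(alt_a, na, a, b)
            + _betabinom_logpmf(alt_b, nb, a, b)
        )

    kept = n_iter - burn_in
    all_samples = np.empty((n_chains, L, kept))
    for chain in range(n_chains):
        pi = rng.uniform(0.2, 0.8, size=L)
        phi = rng.uniform(0.05, 0.95, size=L)
        lp = logpost(pi, phi)
        for it in range(n_iter):
            for which in range(2):
                # random walk, with occasional independence draws so the
                # chain can cross flat plateaus near the boundaries
                noise = rng.normal(0.0, step, size=L)
                jump = rng.random(L) < 0.1
                fresh = rng.random(L)
                if which == 0:
                    prop = np.where(jump, fresh, reflect(pi + noise))
                    prop_pi, prop_phi = prop, phi
                else:
                    prop = np.where(jump, fresh, reflect(phi + noise))
                    prop_pi, prop_phi = pi, prop
                lp_new = logpost(prop_pi, prop_phi)
                accept = np.log(rng.random(L)) < (lp_new - lp)
                pi = np.where(accept, prop_pi, pi)
                phi = np.where(accept, prop_phi, phi)
                lp = np.where(accept, lp_new, lp)
            if it >= burn_in:
                all_samples[chain, :, it - burn_in] = phi

    # split-chain convergence diagnostic (each chain halved along time)
    half_len = kept // 2
    halves = (
        all_samples[:, :, : 2 * half_len]
        .reshape(n_chains, L, 2, half_len)
        .transpose(0, 2, 1, 3)
        .reshape(n_chains * 2, L, half_len)
    )
    m = halves.mean(axis=2)
    v = halves.var(axis=2, ddof=1)
    W = v.mean(axis=0)
    B = (kept // 2) * m.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_hat = (kept // 2 - 1) / (kept // 2) * W + B / (kept // 2)
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(np.isfinite(rhat), rhat, 1.0)
    converged = rhat <= rhat_threshold

    samples = all_samples.transpose(1, 0, 2).reshape(L, n_chains * kept)
    moment = moment_phi_st(alt_a, na, alt_b, nb)
    modes = np.array([_kde_mode(samples[l]) for l in range(L)])
    modes = np.where(converged, modes, moment)
    return PhiPosterior(
        modes=modes, samples=samples, rhat=rhat, converged=converged, moment=moment
    )


def _kde_mode(x: np.ndarray, grid_size: int = 256) -> float:
    """Mode of a [0,1]-supported sample via boundary-reflected KDE."""
    if np.ptp(x) < 1e-9:
        return float(x[0])
    aug = np.concatenate([x, -x, 2.0 - x])  # reflect at both boundaries
    kde = gaussian_kde(aug)
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


# ---------------------------------------------------------------------------
# empirical-null p-values and q-values
# ---------------------------------------------------------------------------

def empirical_pvalue(observed: float | np.ndarray, null: np.ndarray) -> np.ndarray:
    """Upper-tail normalised-rank p-value against a simulated null.

    ``r`` counts null values >= the observation (ties count); the p-value is
    ``max(r, 1)/N`` so that p lies in ``[1/N, 1]``.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    sorted_null = np.sort(null)
    r = null.size - np.searchsorted(sorted_null, obs, side="left")
    p = np.maximum(r, 1) / null.size
    return p if np.ndim(observed) else float(p[0])


def estimate_pi0(p: np.ndarray) -> tuple[float, str]:
    """Storey's null-proportion estimate with the smoother method.

    Evaluates ``pi0(lambda)`` on a grid, fits a cubic smoothing spline and
    reads off the value at the largest lambda; falls back to the fixed
    ``lambda = 0.5`` estimate when the smoother is ill-conditioned (too few
    distinct p-values, or an estimate outside (0, 1]).
    """
    p = np.asarray(p, dtype=float)
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
    method = "smoother"
    pi0 = np.nan
    if np.unique(p).size >= 10:
        try:
            spline = UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(spline(lam[-1]))
        except Exception:
            pi0 = np.nan
    if not np.isfinite(pi0) or pi0 <= 0 or pi0 > 1.0:
        pi0 = float((p > 0.5).mean() / 0.5)
        method = "fixed-lambda-0.5"
        pi0 = min(max(pi0, 1.0 / p.size), 1.0)
    return pi0, method


def qvalues(
    p: np.ndarray, fdr: float = 0.01, pi0: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Storey q-values and outlier flags at the given FDR.

    With ``pi0`` forced to 1 the q-values reduce to Benjamini–Hochberg
    adjusted p-values.  Returns ``(q, flags, pi0)``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0, _ = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, q < fdr, float(pi0)


# ---------------------------------------------------------------------------
# bias classification
# ---------------------------------------------------------------------------

@dataclass
class BiasEntry:
    method: str
    pair: str
    wilcoxon_p: float
    shift: str  # left | right | none
    classification: str  # liberal | unbiased | conservative
    note: str = ""


def classify_bias(
    empirical: np.ndarray,
    simulated: np.ndarray,
    alpha: float = 0.05,
    method: str = "",
    pair: str = "",
) -> BiasEntry:
    """Classify a test from the shift of its simulated-null distribution.

    Two-sided rank-sum test between the empirical and simulated statistic
    distributions.  Non-significant: unbiased.  Significant with the
    simulated distribution shifted left (lower median): liberal (false
    positives); shifted right: conservative (false negatives).
    """
    empirical = np.asarray(empirical, float)
    simulated = np.asarray(simulated, float)
    if empirical.size < 2 or simulated.size < 2:
        raise ValueError("need >= 2 values in both samples")
    if np.ptp(empirical) == 0 and np.ptp(simulated) == 0 and (
        empirical[0] == simulated[0]
    ):
        return BiasEntry(method, pair, 1.0, "none", "unbiased", note="all values tied")
    stat_p = mannwhitneyu(simulated, empirical, alternative="two-sided").pvalue
    med_sim = float(np.median(simulated))
    med_emp = float(np.median(empirical))
    if stat_p >= alpha:
        return BiasEntry(method, pair, float(stat_p), "none", "unbiased")
    if med_sim < med_emp:
        return BiasEntry(method, pair, float(stat_p), "left", "liberal")
    return BiasEntry(method, pair, float(stat_p), "right", "conservative")


# ---------------------------------------------------------------------------
# standard (island-model) Bayes-factor scan
# ---------------------------------------------------------------------------

def standard_bf_scan(
    posterior_samples: np.ndarray,
    prior_samples: np.ndarray | None = None,
    prior_density_at_null: float | None = None,
    null_value: float = 0.0,
    threshold: float = 3.0,
    cap: float = 1e6,
) -> pd.DataFrame:
    """Savage–Dickey density-ratio Bayes factors at the null point.

    ``BF10 = prior(null) / posterior(null)`` from boundary-reflected kernel
    density estimates; loci exceed when ``BF10 > threshold``.  Degenerate
    posteriors with (near) zero density at the null are capped and flagged.
    """
    post = np.atleast_2d(np.asarray(posterior_samples, float))
    if prior_density_at_null is None:
        if prior_samples is None:
            prior_density_at_null = 1.0  # Uniform(0, 1) prior
        else:
            prior_density_at_null = _reflected_density(
                np.asarray(prior_samples, float), null_value
            )
    rows = []
    for l in range(post.shape[0]):
        dens = _reflected_density(post[l], null_value)
        capped = False
        if dens <= prior_density_at_null / cap:
            bf = cap
            capped = True
        else:
            bf = prior_density_at_null / dens
        rows.append(
            {"locus_index": l, "bf": float(bf), "outlier": bool(bf > threshold),
             "capped": capped}
        )
    return pd.DataFrame(rows)


def _reflected_density(x: np.ndarray, point: float) -> float:
    if np.ptp(x) < 1e-9:
        return np.inf if abs(float(x[0]) - point) < 1e-6 else 0.0
    aug = np.concatenate([x, -x, 2.0 - x])
    kde = gaussian_kde(aug)
    # reflection triples the sample; rescale so the [0,1] density integrates to 1
    return float(3.0 * kde(np.array([point]))[0])


# ---------------------------------------------------------------------------
# the scan driver
# ---------------------------------------------------------------------------

@dataclass
class OutlierScanResult:
    """Consolidated per-locus scan output plus bias report."""

    table: pd.DataFrame  # locus, region, pos, pair, method, stat, p, q, flag
    bias: pd.DataFrame
    overlap: pd.DataFrame
    pi0: dict[tuple[str, str], float] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _afd_stats(data: GenotypeDataset) -> tuple[pd.DataFrame, list[str]]:
    log: list[str] = []
    stands = data.stands
    a, b = stands[0], stands[1]
    alt_a, na = data.allele_counts(a)
    alt_b, nb = data.allele_counts(b)
    ok = (na > 0) & (nb > 0)
    skipped = int((~ok).sum())
    if skipped:
        log.append(f"AFD: skipped {skipped} sites with an all-missing stand")
    with np.errstate(invalid="ignore"):
        stat = np.abs(alt_a / np.maximum(na, 1) - alt_b / np.maximum(nb, 1))
    frame = pd.DataFrame(
        {
            "locus": data.site_labels(),
            "region": data.sites["region"],
            "pos": data.sites["pos"],
            "stat": stat,
        }
    )[ok]
    return frame, log


def _g2d_stats(
    data: GenotypeDataset, projection: tuple[int, int]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-region G2D values against the dataset's own genome-wide spectrum."""
    log: list[str] = []
    stands = data.stands
    pair = (stands[0], stands[1])
    weights, usable = site_cell_weights(data, pair, projection)
    if (~usable).sum():
        log.append(
            f"G2D: dropped {int((~usable).sum())} sites below projection {projection}"
        )
    n_a, n_b = projection
    keep = fold_mask(n_a, n_b).ravel()
    keep_poly = keep.copy()
    keep_poly[0] = False  # (0, 0) cell
    folded = weights + weights[:, ::-1]
    # self-complementary cell must not double
    if n_a % 2 == 0 and n_b % 2 == 0:
        centre = (n_a // 2) * (n_b + 1) + n_b // 2
        folded[:, centre] = weights[:, centre]
    cells = folded[:, keep_poly]
    genome = cells.sum(axis=0)
    if genome.sum() <= 0:
        raise ValueError("no polymorphic mass in the genome-wide spectrum")
    props = genome / genome.sum()
    floor = 1.0 / (10.0 * max(genome.sum(), 1.0))
    props = np.where(props <= 0, floor, props)
    props /= props.sum()

    regions = data.sites["region"].to_numpy()
    rows = []
    for region in pd.unique(regions):
        mask = (regions == region) & usable
        counts = cells[mask].sum(axis=0)
        if counts.sum() < 2:
            log.append(f"G2D: region {region} has <2 usable SNPs; skipped")
            continue
        rows.append(
            {"locus": region, "region": region, "pos": 0,
             "stat": g2d(counts, props)}
        )
    return pd.DataFrame(rows), log


def run_scan(
    empirical: GenotypeDataset,
    null_reference: GenotypeDataset,
    methods: Sequence[str] = ("G2D", "AFD"),
    pairs: Sequence[tuple[str, str]] | None = None,
    fdr: float = 0.01,
    seed: int = 1,
    projection: tuple[int, int] | None = None,
    phi_iter: int = 2000,
    phi_burn: int = 500,
    bias_alpha: float = 0.05,
) -> OutlierScanResult:
    """Scan every stand pair with the requested methods against the null.

    For each pair both datasets are subset to the pair (repolarising the
    monomorphic filter), the statistic is computed on every empirical and
    null locus, empirical-null p-values and Storey q-values are derived, and
    the test's bias is classified from the two statistic distributions.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    if pairs is None:
        stands = [s for s in empirical.stands]
        pairs = [p for p in STAND_PAIRS if p[0] in stands and p[1] in stands]
        if not pairs:
            from itertools import combinations

            pairs = list(combinations(stands, 2))

    tables = []
    bias_rows = []
    pi0_map: dict[tuple[str, str], float] = {}
    log: list[str] = []
    rng = np.random.default_rng(seed)
    for pair in pairs:
        emp = subset_pair(empirical, *pair)
        null = subset_pair(null_reference, *pair)
        label = pair_label(*pair)
        if projection is None:
            proj = default_projection(emp, pair)
            proj = (
                min(proj[0], default_projection(null, pair)[0]),
                min(proj[1], default_projection(null, pair)[1]),
            )
        else:
            proj = projection
        for method in methods:
            if method == "AFD":
                emp_stats, l1 = _afd_stats(emp)
                null_stats, l2 = _afd_stats(null)
            elif method == "G2D":
                emp_stats, l1 = _g2d_stats(emp, proj)
                null_stats, l2 = _g2d_stats(null, proj)
            else:  # PHI_ST
                emp_stats, l1 = _phi_stats(
                    emp, phi_iter, phi_burn, int(rng.integers(1, 2**31 - 1))
                )
                null_stats, l2 = _phi_stats(
                    null, phi_iter, phi_burn, int(rng.integers(1, 2**31 - 1))
                )
            log += [f"{label}/{m}" for m in l1 + l2]
            if len(emp_stats) == 0 or len(null_stats) == 0:
                log.append(f"{label}/{method}: no usable loci; skipped")
                continue
            p = empirical_pvalue(emp_stats["stat"].to_numpy(),
                                 null_stats["stat"].to_numpy())
            q, flags, pi0 = qvalues(p, fdr=fdr)
            pi0_map[(method, label)] = pi0
            frame = emp_stats.copy()
            frame["pair"] = label
            frame["method"] = method
            frame["p"] = p
            frame["q"] = q
            frame["flag"] = flags
            tables.append(frame)
            bias_rows.append(
                classify_bias(
                    emp_stats["stat"].to_numpy(),
                    null_stats["stat"].to_numpy(),
                    alpha=bias_alpha,
                    method=method,
                    pair=label,
                ).__dict__
            )
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=["locus", "region", "pos", "stat", "pair", "method", "p", "q", "flag"]
        )
    )
    bias = pd.DataFrame(bias_rows)
    overlap = _overlap_summary(table)
    return OutlierScanResult(table=table, bias=bias, overlap=overlap, pi0=pi0_map, log=log)


def _phi_stats(
    data: GenotypeDataset, n_iter: int, burn_in: int, seed: int
) -> tuple[pd.DataFrame, list[str]]:
    stands = data.stands
    alt_a, na = data.allele_counts(stands[0])
    alt_b, nb = data.allele_counts(stands[1])
    ok = (na >= 2) & (nb >= 2)
    log = []
    if (~ok).sum():
        log.append(f"PHI_ST: skipped {int((~ok).sum())} sites with <2 chromosomes")
    post = phi_st_posterior(
        alt_a[ok], na[ok], alt_b[ok], nb[ok],
        n_iter=n_iter, burn_in=burn_in, seed=seed,
    )
    n_bad = int((~post.converged).sum())
    if n_bad:
        log.append(f"PHI_ST: {n_bad} loci non-converged; moment estimate substituted")
    frame = pd.DataFrame(
        {
            "locus": data.site_labels()[ok].to_numpy(),
            "region": data.sites["region"][ok].to_numpy(),
            "pos": data.sites["pos"][ok].to_numpy(),
            "stat": post.modes,
        }
    )
    return frame, log


def _overlap_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Regions flagged by >= 2 methods or >= 2 pairs."""
    if table.empty or not table["flag"].any():
        return pd.DataFrame(columns=["region", "n_methods", "n_pairs"])
    hits = table[table["flag"]]
    grouped = hits.groupby("region").agg(
        n_methods=("method", "nunique"), n_pairs=("pair", "nunique")
    )
    return grouped[(grouped["n_methods"] >= 2) | (grouped["n_pairs"] >= 2)].reset_index()
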