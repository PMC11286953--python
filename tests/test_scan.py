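"""Divergence statistics, empirical-null p/q machinery, bias classes, BF scan."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import demoscan as d
from demoscan.scan import (
    BiasEntry,
    classify_bias,
    empirical_pvalue,
    estimate_pi0,
    g2d,
    moment_phi_st,
    phi_st_posterior,
    qvalues,
    standard_bf_scan,
)


# ---------------------------------------------------------------------------
# G2D
# ---------------------------------------------------------------------------

def brute_force_g2d(counts, props):
    """Twice the difference of multinomial log-likelihoods, term by term."""
    counts = np.asarray(counts, float)
    props = np.asarray(props, float)
    n = counts.sum()
    ll_region = sum(c * math.log(c / n) for c in counts if c > 0)
    ll_genome = sum(c * math.log(p) for c, p in zip(counts, props) if c > 0)
    return 2 * (ll_region - ll_genome)


def test_g2d_zero_when_region_matches_genome():
    props = np.array([0.5, 0.3, 0.2])
    counts = 10 * props
    assert g2d(counts, props) == pytest.approx(0.0, abs=1e-12)


def test_g2d_hand_computed_two_snp_example():
    """Two SNPs in one of two equiprobable cells: G = 2 * 2 ln 2 = 2.7726."""
    assert g2d([2, 0], [0.5, 0.5]) == pytest.approx(2.772589, abs=1e-5)


def test_g2d_matches_brute_force_on_small_regions():
    rng = np.random.default_rng(15)
    for _ in range(50):
        k = rng.integers(2, 5)  # occupied cells
        counts = rng.integers(0, 6, size=k)
        if counts.sum() < 2:
            continue
        props = rng.dirichlet(np.ones(k))
        assert g2d(counts, props) == pytest.approx(
            brute_force_g2d(counts, props), abs=1e-10
        )


def test_g2d_rejects_single_snp_regions():
    with pytest.raises(ValueError, match="at least 2"):
        g2d([1, 0], [0.5, 0.5])


# ---------------------------------------------------------------------------
# AFD
# ---------------------------------------------------------------------------

def test_afd_basic_values_and_symmetry():
    assert d.afd(0.2, 0.2) == 0.0
    assert d.afd(0.0, 1.0) == 1.0
    rng = np.random.default_rng(16)
    a, b = rng.uniform(size=20), rng.uniform(size=20)
    assert np.allclose(d.afd(a, b), d.afd(b, a))
    with pytest.raises(ValueError):
        d.afd(-0.1, 0.5)


# ---------------------------------------------------------------------------
# Phi_ST: moment oracle and posterior
# ---------------------------------------------------------------------------

def amova_oracle(alt_a, na, alt_b, nb):
    """AMOVA components from explicit pairwise allele mismatches."""
    pops = [
        np.array([1] * alt_a + [0] * (na - alt_a)),
        np.array([1] * alt_b + [0] * (nb - alt_b)),
    ]
    allv = np.concatenate(pops)
    N = len(allv)
    r = 2

    def ssd(v):
        return sum(
            (v[i] != v[j]) for i, j in itertools.combinations(range(len(v)), 2)
        ) / len(v)

    ssd_total = ssd(allv)
    ssd_within = sum(ssd(v) for v in pops)
    ssd_among = ssd_total - ssd_within
    ms_within = ssd_within / (N - r)
    n0 = (N - (na**2 + nb**2) / N) / (r - 1)
    sigma_a = (ssd_among / (r - 1) - ms_within) / n0
    denom = sigma_a + ms_within
    return sigma_a / denom if denom else 0.0


def test_moment_phi_matches_amova_oracle_exhaustively():
    """All 2-stand single-locus instances with <= 6 diploids per stand."""
    for n_dip_a in range(2, 7):
        for n_dip_b in range(2, 7):
            na, nb = 2 * n_dip_a, 2 * n_dip_b
            for ka in range(na + 1):
                for kb in range(nb + 1):
                    if ka + kb == 0 or ka + kb == na + nb:
                        continue  # monomorphic: undefined, skip
                    got = moment_phi_st([ka], [na], [kb], [nb])[0]
                    want = amova_oracle(ka, na, kb, nb)
                    assert got == pytest.approx(want, abs=1e-10), (ka, na, kb, nb)


def test_moment_phi_fixed_difference_is_one():
    assert moment_phi_st([0], [40], [40], [40])[0] == pytest.approx(1.0)


def test_phi_posterior_identical_counts_mode_near_zero():
    post = phi_st_posterior([8], [40], [8], [40], seed=2)
    assert post.modes[0] <= 0.1
    assert post.moment[0] <= 0.0


def test_phi_posterior_fixed_difference_mode_near_one():
    post = phi_st_posterior([0], [40], [40], [40], seed=3)
    assert post.modes[0] > 0.9
    assert post.moment[0] == pytest.approx(1.0)


def test_phi_posterior_is_seeded():
    a = phi_st_posterior([3, 9], [20, 30], [7, 9], [20, 30], seed=4, n_iter=800, burn_in=200)
    b = phi_st_posterior([3, 9], [20, 30], [7, 9], [20, 30], seed=4, n_iter=800, burn_in=200)
    assert np.array_equal(a.samples, b.samples)


# ---------------------------------------------------------------------------
# empirical p-values
# ---------------------------------------------------------------------------

def test_empirical_pvalue_floor_and_ties():
    null = np.arange(100, dtype=float)
    assert empirical_pvalue(1e9, null) == 0.01  # larger than all: floor 1/N
    assert empirical_pvalue(0.0, null) == 1.0
    # ties count towards the rank (conservative)
    null = np.array([1.0, 2.0, 2.0, 3.0])
    assert empirical_pvalue(2.0, null) == pytest.approx(3 / 4)


def test_empirical_pvalues_are_subuniform_under_the_null():
    rng = np.random.default_rng(17)
    N = 200
    ps = []
    for _ in range(1000):
        null = rng.normal(size=N)
        obs = rng.normal()
        ps.append(empirical_pvalue(obs, null))
    ps = np.asarray(ps)
    for alpha in (0.01, 0.05, 0.1, 0.5):
        assert (ps <= alpha).mean() <= alpha + 1 / N + 3 * math.sqrt(alpha / 1000)


def test_empirical_pvalue_rejects_empty_null():
    with pytest.raises(ValueError):
        empirical_pvalue(1.0, np.array([]))


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def test_qvalues_all_ones_yield_no_flags():
    q, flags, pi0 = qvalues(np.ones(50))
    assert np.allclose(q, 1.0)
    assert not flags.any()


def test_qvalues_with_pi0_one_reduce_to_benjamini_hochberg():
    rng = np.random.default_rng(18)
    p = rng.uniform(size=100)
    q, _, _ = qvalues(p, pi0=1.0)
    order = np.argsort(p)
    bh = np.minimum.accumulate(
        (p[order] * len(p) / np.arange(1, len(p) + 1))[::-1]
    )[::-1]
    assert np.allclose(q[order], np.minimum(bh, 1.0))


def test_qvalues_are_monotone_in_p():
    rng = np.random.default_rng(19)
    p = np.concatenate([rng.uniform(size=200), rng.uniform(0, 1e-3, size=10)])
    q, _, _ = qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q <= 1.0).all()


def test_qvalue_fdr_is_controlled_on_a_null_signal_mixture():
    """95% uniform nulls + 5% strong signals: realised FDR stays near target."""
    rng = np.random.default_rng(20)
    fdrs = []
    for _ in range(40):
        null_p = rng.uniform(size=950)
        signal_p = rng.uniform(0, 1e-5, size=50)
        p = np.concatenate([null_p, signal_p])
        is_null = np.arange(1000) < 950
        q, flags, _ = qvalues(p, fdr=0.01)
        if flags.any():
            fdrs.append((flags & is_null).sum() / flags.sum())
    assert np.mean(fdrs) <= 0.02


def test_qvalues_reject_invalid_input():
    with pytest.raises(ValueError):
        qvalues(np.array([]))
    with pytest.raises(ValueError):
        qvalues(np.array([0.0, 0.5]))


# ---------------------------------------------------------------------------
# bias classification
# ---------------------------------------------------------------------------

def test_identical_samples_classify_unbiased():
    rng = np.random.default_rng(21)
    x = rng.normal(size=200)
    entry = classify_bias(x, x.copy())
    assert entry.classification == "unbiased"


def test_right_shifted_null_classifies_conservative():
    rng = np.random.default_rng(22)
    emp = rng.normal(size=200)
    entry = classify_bias(emp, emp + 10)
    assert entry.classification == "conservative"
    assert entry.shift == "right"


def test_left_shifted_null_classifies_liberal():
    rng = np.random.default_rng(23)
    emp = rng.normal(size=200)
    entry = classify_bias(emp, emp - 10)
    assert entry.classification == "liberal"
    assert entry.shift == "left"


def test_all_tied_samples_are_unbiased_with_note():
    entry = classify_bias(np.ones(10), np.ones(10))
    assert entry.classification == "unbiased"
    assert entry.note


# ---------------------------------------------------------------------------
# standard Bayes-factor scan
# ---------------------------------------------------------------------------

def test_bf_is_one_when_posterior_equals_prior():
    rng = np.random.default_rng(24)
    x = rng.uniform(size=500)
    out = standard_bf_scan(x[None, :], prior_samples=x)
    assert out["bf"].iloc[0] == pytest.approx(1.0)


def test_bf_large_when_posterior_mass_far_from_null():
    rng = np.random.default_rng(25)
    post = rng.beta(50, 5, size=500)
    out = standard_bf_scan(post[None, :])
    assert out["bf"].iloc[0] > 100
    assert out["outlier"].iloc[0]


def test_standard_scan_flags_more_than_demography_controlled_scan():
    """Strong drift (departure from the island model) inflates the standard
    scan's outlier count while the demography-controlled scan stays quiet."""
    from demoscan.filtering import subset_pair
    from demoscan.inference import ParameterEnsemble, build_neutral_reference

    p = d.PUBLISHED_MEDIANS.as_dict()
    for k in p:
        if k.startswith("MIG"):
            p[k] = 0.0
    p.update(
        POPSIZE_N3=1500, POPSIZE_N4=1500, POPSIZE_S1=1500, POPSIZE_S5=1500,
        TIME1=300, TIME2=320, TIME3=340, TIMEA=360, TIMEB=400,
        TIMEC=500, TIMED=600, TIMEE=1000,
    )
    drift = d.DemographicParameterSet.from_mapping(p)
    design = d.StudyDesign(n_regions=800, missing_rate=0.0)
    counts = {"standard": [], "controlled": []}
    for seed in (66, 67):
        emp = d.generate_neutral_dataset(design, drift, seed=seed, mu=1e-8)
        sub = subset_pair(emp, "N3", "S5")
        alt_a, na = sub.allele_counts("N3")
        alt_b, nb = sub.allele_counts("S5")
        post = phi_st_posterior(alt_a, na, alt_b, nb, n_iter=1200, burn_in=400, seed=9)
        bf = standard_bf_scan(post.samples)
        ens = ParameterEnsemble(pd.DataFrame([p] * 5), provenance="resampled")
        null = build_neutral_reference(
            ens, fragments_per_set=300,
            sample_sizes=design.samples_per_stand, seed=77 + seed, mu=1e-8,
        )
        scan = d.run_scan(emp, null, methods=("AFD",), pairs=[("N3", "S5")], seed=3)
        counts["standard"].append(int(bf["outlier"].sum()))
        counts["controlled"].append(int(scan.table["flag"].sum()))
    assert all(
        s > c for s, c in zip(counts["standard"], counts["controlled"])
    ), counts


# ---------------------------------------------------------------------------
# scan driver
# ---------------------------------------------------------------------------

def test_run_scan_produces_consistent_p_and_q(neutral_small, null_small):
    result = d.run_scan(
        neutral_small, null_small, methods=("G2D", "AFD"),
        pairs=[("N3", "N4"), ("S1", "S5")], seed=5,
    )
    t = result.table
    assert set(t["method"]) <= {"G2D", "AFD"}
    assert ((t["p"] > 0) & (t["p"] <= 1)).all()
    assert ((t["q"] >= 0) & (t["q"] <= 1)).all()
    # within each method x pair, sorting by p sorts q
    for (_, _), grp in t.groupby(["method", "pair"]):
        srt = grp.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()
    assert set(result.bias["classification"]) <= {
        "liberal", "unbiased", "conservative"
    }


def test_run_scan_skips_single_snp_regions_for_g2d(neutral_small, null_small):
    result = d.run_scan(
        neutral_small, null_small, methods=("G2D",), pairs=[("N3", "N4")], seed=6
    )
    region_snps = neutral_small.sites.groupby("region").size()
    single = set(region_snps.index[region_snps == 1])
    assert not set(result.table["region"]) & single


def test_run_scan_with_phi_method_runs_at_small_scale(null_small):
    design = d.StudyDesign(n_regions=60)
    emp = d.generate_neutral_dataset(design, d.PUBLISHED_MEDIANS, seed=404)
    small_null = null_small.take_sites(np.arange(min(300, null_small.n_sites)))
    result = d.run_scan(
        emp, small_null, methods=("PHI_ST",), pairs=[("N3", "S5")],
        seed=7, phi_iter=600, phi_burn=200,
    )
    assert len(result.table) > 0
    assert ((result.table["stat"] >= -1) & (result.table["stat"] <= 1)).all()
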