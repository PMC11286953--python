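"""Diversity and differentiation statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import demoscan as d


def _dataset(genotypes, stands, region="r", length=100):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(genotypes.shape[1])],
            "stand": list(stands),
            "slope": [s[0] for s in stands],
        }
    )
    sites = pd.DataFrame(
        {"region": [region] * genotypes.shape[0],
         "pos": np.arange(1, genotypes.shape[0] + 1)}
    )
    regions = pd.DataFrame(
        {"length": [length]}, index=pd.Index([region], name="region")
    )
    return d.GenotypeDataset(genotypes, samples, sites, regions)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def brute_force_pi(genotypes, length):
    """Average pairwise differences among chromosomes, per base."""
    haps = []
    for col in range(genotypes.shape[1]):
        g = genotypes[:, col]
        haps.append(np.where(g >= 1, 1, 0))
        haps.append(np.where(g == 2, 1, 0))
    haps = np.array(haps)
    n = len(haps)
    diffs = sum(
        (haps[i] != haps[j]).sum() for i, j in itertools.combinations(range(n), 2)
    )
    return diffs / (n * (n - 1) / 2) / length


def test_pi_zero_for_identical_homozygotes():
    data = _dataset([[0, 0, 0, 0], [2, 2, 2, 2]], ["N3"] * 4)
    div = d.nucleotide_diversity(data, stands=["N3"])
    assert div.per_stand["N3"] == 0.0


def test_pi_matches_brute_force_pairwise_differences():
    """2 diploids, allele counts 2/2 at one SNP of a 100-bp region."""
    g = np.array([[1, 1]], dtype=np.int8)  # two hets: 2 alt of 4 chromosomes
    data = _dataset(g, ["N3", "N3"])
    div = d.nucleotide_diversity(data, stands=["N3"])
    expected = brute_force_pi(g, 100)
    assert div.per_stand["N3"] == pytest.approx(expected)
    assert div.per_stand["N3"] == pytest.approx(2 / 3 / 100)  # 0.00667


def test_pi_brute_force_on_random_instances():
    rng = np.random.default_rng(12)
    for _ in range(20):
        g = rng.integers(0, 3, size=(rng.integers(1, 6), 4)).astype(np.int8)
        data = _dataset(g, ["N3"] * 4, length=50)
        div = d.nucleotide_diversity(data, stands=["N3"])
        assert div.per_stand["N3"] == pytest.approx(brute_force_pi(g, 50))


def test_pi_errors_when_stand_has_no_called_chromosomes():
    data = _dataset([[-1], [-1]], ["N3"])
    with pytest.raises(ValueError):
        d.nucleotide_diversity(data, stands=["N3"])


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST vs brute-force ANOVA oracle
# ---------------------------------------------------------------------------

def wc_oracle(counts):
    """Scalar Weir & Cockerham (1984) components from per-pop summaries.

    ``counts`` is a list of loci; each locus a list of (n_ind, p_hat, h_obs)
    per population.  Independent transcription of the published estimator.
    """
    A = B = C = 0.0
    for locus in counts:
        r = len(locus)
        ns = [x[0] for x in locus]
        ps = [x[1] for x in locus]
        hs = [x[2] for x in locus]
        nbar = sum(ns) / r
        if nbar <= 1 or min(ns) == 0:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        A, B, C = A + a, B + b, C + c
    return A / (A + B + C) if (A + B + C) else float("nan")


def _summaries(data, stands):
    out = []
    for locus in range(data.n_sites):
        row = []
        for stand in stands:
            g = data.genotypes[locus, data.stand_columns(stand)]
            called = g[g >= 0]
            n = len(called)
            p = called.sum() / (2 * n) if n else 0.0
            h = (called == 1).mean() if n else 0.0
            row.append((n, p, h))
        out.append(row)
    return out


def test_wc_fst_toy_case_against_oracle():
    """2 stands x 10 diploids, one locus with allele counts 10/10 vs 0/20."""
    g = np.zeros((1, 20), dtype=np.int8)
    g[0, :5] = 2  # 5 hom-alt in stand 1 -> 10 alt of 20
    data = _dataset(g, ["N3"] * 10 + ["S5"] * 10)
    got = d.wc_fst(data)
    expected = wc_oracle(_summaries(data, ["N3", "S5"]))
    assert got == pytest.approx(expected)
    assert got > 0.2


def test_wc_fst_identical_stands_is_nonpositive():
    g = np.array([[0, 1, 2, 0, 1, 2]], dtype=np.int8)
    data = _dataset(g, ["N3"] * 3 + ["S5"] * 3)
    assert d.wc_fst(data) <= 0


def test_wc_fst_exhaustive_small_instances_match_oracle():
    """Randomised sweep over <=3 stands, <=5 loci, <=6 diploids with missing."""
    rng = np.random.default_rng(77)
    for _ in range(60):
        n_stands = rng.integers(2, 4)
        n_per = rng.integers(2, 7)
        n_loci = rng.integers(1, 6)
        g = rng.integers(0, 3, size=(n_loci, n_stands * n_per)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = -1
        stands = ["N3", "S5", "S1"][:n_stands]
        data = _dataset(g, sum([[s] * n_per for s in stands], []))
        got = d.wc_fst(data, stands)
        expected = wc_oracle(_summaries(data, stands))
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def test_hierarchical_components_track_population_structure():
    """Slope+stand variance fraction agrees with plain W&C F_ST in size."""
    rng = np.random.default_rng(5)
    # four stands on two slopes with a genuine slope-level frequency contrast
    g = np.concatenate(
        [
            rng.binomial(2, 0.2, size=(12, 12)),  # N3+N4 (slope N)
            rng.binomial(2, 0.7, size=(12, 12)),  # S1+S5 (slope S)
        ],
        axis=1,
    ).astype(np.int8)
    stands = ["N3"] * 6 + ["N4"] * 6 + ["S1"] * 6 + ["S5"] * 6
    data = _dataset(g, stands)
    hier = d.wc_fst_global(data)
    flat = d.wc_fst(data)
    assert hier.f_stand_total == pytest.approx(flat, abs=0.1)
    # the slope level carries (almost) all the differentiation here
    assert hier.components["slope"] > hier.components["stand"]


def test_pairwise_fst_matrix_symmetry(neutral_small):
    from demoscan.filtering import mono_remove

    pw = d.pairwise_fst(mono_remove(neutral_small))
    assert np.allclose(pw.values, pw.values.T, equal_nan=True)
    assert np.isnan(np.diag(pw.values)).all()


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def test_josts_d_identical_stands_is_zero():
    g = np.array([[0, 1, 2, 0, 1, 2], [1, 1, 0, 1, 1, 0]], dtype=np.int8)
    data = _dataset(g, ["N3"] * 3 + ["S5"] * 3)
    assert d.josts_d_pair(data, "N3", "S5") == pytest.approx(0.0, abs=1e-12)


def test_josts_d_fixed_differences_give_one():
    g = np.array([[0, 0, 2, 2], [2, 2, 0, 0]], dtype=np.int8)
    data = _dataset(g, ["N3", "N3", "S5", "S5"])
    assert d.josts_d_pair(data, "N3", "S5") == pytest.approx(1.0)


def test_josts_d_insensitive_to_within_stand_diversity():
    """Frequency pairs with equal D but unequal H_S: D agrees, F_ST does not.

    (0.1, 0.3) and (0.325, 0.5) sit on (almost) the same Jost's-D contour
    while their heterozygosity levels differ, so the Nei-style F_ST halves
    between the two cases.
    """

    def make(alt_count_a, alt_count_b, n_dip=20):
        def col(alt):
            out = [2] * (alt // 2) + [1] * (alt % 2)
            return out + [0] * (n_dip - len(out))

        g = np.array([col(alt_count_a) + col(alt_count_b)], dtype=np.int8)
        return _dataset(g, ["N3"] * n_dip + ["S5"] * n_dip)

    low_hs = make(4, 12)    # frequencies 0.1 vs 0.3
    high_hs = make(13, 20)  # frequencies 0.325 vs 0.5
    d_low = d.josts_d_pair(low_hs, "N3", "S5")
    d_high = d.josts_d_pair(high_hs, "N3", "S5")
    fst_low = d.wc_fst(low_hs)
    fst_high = d.wc_fst(high_hs)
    assert d_low == pytest.approx(d_high, abs=0.002)
    assert abs(fst_low - fst_high) > 0.01


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_constant_statistic_has_zero_width(toy_dataset):
    ci = d.bootstrap_ci(lambda ds: 0.42, toy_dataset, B=50, seed=3)
    assert ci["ci"][0.95] == (0.42, 0.42)
    assert ci["point"] == 0.42


def test_bootstrap_is_seeded_and_reproducible(neutral_small):
    from demoscan.filtering import mono_remove

    data = mono_remove(neutral_small).take_sites(np.arange(100))
    a = d.bootstrap_ci(d.wc_fst, data, B=30, seed=9)
    b = d.bootstrap_ci(d.wc_fst, data, B=30, seed=9)
    assert np.array_equal(a["replicates"], b["replicates"])
    c = d.bootstrap_ci(d.wc_fst, data, B=30, seed=10)
    assert not np.array_equal(a["replicates"], c["replicates"])


def test_bootstrap_rejects_degenerate_inputs(toy_dataset):
    with pytest.raises(ValueError):
        d.bootstrap_ci(d.wc_fst, toy_dataset, B=1)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def test_upgma_three_taxa_hand_example():
    dist = pd.DataFrame(
        [[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]],
        index=["A", "B", "C"],
        columns=["A", "B", "C"],
    )
    assert d.upgma_tree(dist) == "((A:0.5,B:0.5):1.5,C:2);"


def test_upgma_two_taxa_cherry():
    dist = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["X", "Y"], columns=["X", "Y"])
    assert d.upgma_tree(dist) == "(X:1.5,Y:1.5);"


def test_upgma_output_is_ultrametric_and_parses():
    import io

    from Bio import Phylo

    rng = np.random.default_rng(3)
    n = 5
    m = rng.uniform(1, 10, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    labels = list("ABCDE")
    dist = pd.DataFrame(m, index=labels, columns=labels)
    tree = Phylo.read(io.StringIO(d.upgma_tree(dist)), "newick")
    depths = tree.depths()
    leaf_depths = [v for k, v in depths.items() if k.is_terminal()]
    assert np.allclose(leaf_depths, leaf_depths[0])


def test_upgma_rejects_asymmetric_input():
    dist = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["A", "B"], columns=["A", "B"])
    with pytest.raises(ValueError, match="symmetric"):
        d.upgma_tree(dist)
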