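"""Staged demographic model, joint SFS machinery, and worked mutation counts."""

import math

import numpy as np
import pandas as pd
import pytest

import demoscan as d
from demoscan.sfs import (
    Folded2DSFS,
    composite_loglik,
    fold_matrix,
    fold_unfolded_counts,
    folded_joint_sfs,
)


# ---------------------------------------------------------------------------
# parameter set invariants
# ---------------------------------------------------------------------------

def test_parameter_set_has_21_named_parameters():
    assert len(d.PARAM_NAMES) == 21
    s = d.PUBLISHED_MEDIANS.as_series()
    assert list(s.index) == list(d.PARAM_NAMES)


def test_parameter_set_rejects_invalid_values():
    base = d.PUBLISHED_MEDIANS.as_dict()
    bad = dict(base, POPSIZE_N3=0)
    with pytest.raises(ValueError, match="POPSIZE_N3"):
        d.DemographicParameterSet.from_mapping(bad)
    bad = dict(base, MIG_N3_N4=-0.1)
    with pytest.raises(ValueError, match="MIG_N3_N4"):
        d.DemographicParameterSet.from_mapping(bad)
    bad = dict(base, TIMEB=1000)  # TIMEB > TIMEC
    with pytest.raises(ValueError, match="TIMEB"):
        d.DemographicParameterSet.from_mapping(bad)


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------

def test_schedule_with_zero_growth_is_piecewise_constant():
    p = d.PUBLISHED_MEDIANS.as_dict()
    p.update(GROWTHRATE0=0.0, GROWTHRATE1=0.0, GROWTHRATE2=0.0,
             TIME1=1, TIME2=2, TIME3=3, TIMEA=4, TIMEB=5, TIMEC=6, TIMED=7, TIMEE=8)
    sched = d.build_event_schedule(d.DemographicParameterSet.from_mapping(p))
    total = sum(p[f"POPSIZE_{s}"] for s in ("N3", "N4", "S1", "S5"))
    # with zero growth, the ancestral (minimum-extent) size is the summed size
    assert sched.minimum_extent_size == pytest.approx(total)
    # and the deep-time sizes all collapse onto it
    dbg = sched.demography.debug()
    eps = sched.demography.events
    sizes = [e.initial_size for e in eps if hasattr(e, "initial_size")
             and e.initial_size is not None]
    assert all(s == pytest.approx(total) for s in sizes)


def test_schedule_mergers_at_generation_one():
    sched = d.build_event_schedule(d.PUBLISHED_MEDIANS)
    merges = sched.events[sched.events["event"] == "merge"]
    assert list(merges["time"]) == [1, 1, 1]


def test_instant_merger_without_migration_is_panmictic():
    """All mergers at t~0 with no migration: F_ST indistinguishable from 0."""
    p = d.PUBLISHED_MEDIANS.as_dict()
    for k in p:
        if k.startswith("MIG"):
            p[k] = 0.0
    p.update(TIME1=0.01, TIME2=0.01, TIME3=0.01, TIMEA=0.02,
             GROWTHRATE0=0.0, GROWTHRATE1=0.0, GROWTHRATE2=0.0)
    params = d.DemographicParameterSet.from_mapping(p)
    fsts = []
    for seed in range(1, 9):
        ds = d.simulate_fragments(
            d.build_event_schedule(params), n_fragments=150, mu=1e-8,
            sample_sizes={s: 10 for s in d.STANDS}, seed=seed,
        )
        fsts.append(d.wc_fst(ds))
    assert abs(np.mean(fsts)) < 0.005


def test_simulate_fragments_is_seed_reproducible():
    sched = d.build_event_schedule(d.PUBLISHED_MEDIANS)
    a = d.simulate_fragments(sched, n_fragments=20, sample_sizes={s: 5 for s in d.STANDS}, seed=5)
    b = d.simulate_fragments(sched, n_fragments=20, sample_sizes={s: 5 for s in d.STANDS}, seed=5)
    assert a.equals(b)


def test_simulate_fragments_rejects_bad_inputs():
    sched = d.build_event_schedule(d.PUBLISHED_MEDIANS)
    with pytest.raises(ValueError):
        d.simulate_fragments(sched, n_fragments=0)
    with pytest.raises(ValueError):
        d.simulate_fragments(sched, n_fragments=2, sample_sizes={"N3": 0, "N4": 2, "S1": 2, "S5": 2})


# ---------------------------------------------------------------------------
# folded joint SFS
# ---------------------------------------------------------------------------

def _pair_dataset(genos):
    genos = np.asarray(genos, dtype=np.int8)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(genos.shape[1])],
            "stand": ["N3", "N3", "S5", "S5"],
            "slope": ["N", "N", "S", "S"],
        }
    )
    sites = pd.DataFrame(
        {"region": ["r"] * genos.shape[0], "pos": np.arange(1, genos.shape[0] + 1)}
    )
    regions = pd.DataFrame({"length": [1000]}, index=pd.Index(["r"], name="region"))
    return d.GenotypeDataset(genos, samples, sites, regions)


def test_folded_sfs_single_snp_lands_in_expected_cell():
    # counts (1 of 4, 0 of 4)
    data = _pair_dataset([[1, 0, 0, 0]])
    sfs = folded_joint_sfs(data, ("N3", "S5"), projection=(4, 4))
    assert sfs.matrix[1, 0] == pytest.approx(1.0)
    assert sfs.total == pytest.approx(1.0)


def test_folded_sfs_folds_major_alleles():
    # counts (3 of 4, 4 of 4) must fold to cell (1, 0)
    data = _pair_dataset([[2, 1, 2, 2]])
    sfs = folded_joint_sfs(data, ("N3", "S5"), projection=(4, 4))
    assert sfs.matrix[1, 0] == pytest.approx(1.0)
    assert not sfs.mask[3, 4]


def test_folded_sfs_total_is_conserved(neutral_small):
    from demoscan.filtering import subset_pair

    sub = subset_pair(neutral_small, "N3", "N4")
    sfs = folded_joint_sfs(sub, ("N3", "N4"))
    assert sfs.total == pytest.approx(sfs.n_sites_used, rel=1e-6)
    assert sfs.n_sites_used + sfs.n_sites_dropped == sub.n_sites


def test_fold_matrix_partition_is_involution_consistent():
    rng = np.random.default_rng(1)
    for na, nb in [(4, 4), (5, 4), (5, 5), (6, 3)]:
        m = rng.integers(0, 10, size=(na + 1, nb + 1)).astype(float)
        folded, keep = fold_matrix(m)
        # every cell pair contributes exactly once
        assert folded[keep].sum() == pytest.approx(m.sum())
        # no masked cell is the fold-partner of another masked cell
        for i in range(na + 1):
            for j in range(nb + 1):
                partner = (na - i, nb - j)
                if (i, j) == partner:
                    continue
                assert keep[i, j] != keep[partner]


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------

def _sfs_from(matrix, pair=("N3", "N4")):
    return fold_unfolded_counts(np.asarray(matrix, float), pair)


def test_composite_loglik_is_maximal_at_observed_proportions():
    obs = _sfs_from([[0, 5, 3], [2, 1, 0], [0, 0, 0]])
    best = composite_loglik([obs], [obs])
    rng = np.random.default_rng(8)
    for _ in range(20):
        noise = rng.uniform(0.5, 2.0, size=obs.matrix.shape)
        other = Folded2DSFS(
            pair=obs.pair, n_proj=obs.n_proj,
            matrix=obs.matrix * noise, mask=obs.mask,
        )
        assert composite_loglik([obs], [other]) <= best + 1e-9


def test_composite_loglik_uniform_expectation_closed_form():
    obs = _sfs_from([[0, 4], [3, 3]])  # folded counts in k cells
    poly = obs.mask.copy()
    poly[0, 0] = False
    k = int(poly.sum())
    n = obs.matrix[poly].sum()
    uniform = Folded2DSFS(
        pair=obs.pair, n_proj=obs.n_proj,
        matrix=np.where(poly, 1.0, 0.0), mask=obs.mask,
    )
    assert composite_loglik([obs], [uniform]) == pytest.approx(n * math.log(1 / k))


def test_composite_loglik_scales_linearly_with_counts():
    obs = _sfs_from([[0, 5, 3], [2, 1, 0], [1, 0, 0]])
    exp = _sfs_from([[0, 4, 4], [3, 2, 1], [1, 1, 0]])
    base = composite_loglik([obs], [exp])
    tripled = Folded2DSFS(
        pair=obs.pair, n_proj=obs.n_proj, matrix=3 * obs.matrix, mask=obs.mask
    )
    assert composite_loglik([tripled], [exp]) == pytest.approx(3 * base)


def test_composite_loglik_rejects_shape_mismatch():
    a = _sfs_from(np.zeros((3, 3)) + 1)
    b = _sfs_from(np.zeros((4, 4)) + 1)
    with pytest.raises(ValueError, match="projection mismatch"):
        composite_loglik([a], [b])


# ---------------------------------------------------------------------------
# expected new mutations (worked examples)
# ---------------------------------------------------------------------------

def test_expected_new_mutations_per_gamete_and_total():
    per_gamete, total = d.expected_new_mutations(542e6, 9.5e-10, 5000, 2)
    assert per_gamete == pytest.approx(0.515, abs=0.001)
    assert round(per_gamete, 1) == 0.5
    # with the rounded per-gamete rate the population total is 5000
    assert 0.5 * 5000 * 2 == 5000
    assert total == pytest.approx(5149, abs=1)


def test_expected_new_mutations_edge_cases():
    assert d.expected_new_mutations(1e6, 0.0, 10, 1) == (0.0, 0.0)
    with pytest.raises(ValueError):
        d.expected_new_mutations(0, 1e-9, 10, 1)
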