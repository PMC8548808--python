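"""Dosage calling, Hind/He, thresholds and coverage filters."""

import numpy as np
import pytest
from scipy.stats import binom

from paraploid.genotyping import (
    ThresholdPair,
    call_genotypes,
    coverage_filter,
    estimate_allele_freqs_em,
    hind_he,
    partition_loci_by_ploidy,
    simulate_hind_he_threshold,
    simulate_threshold_pair,
)
from paraploid.simdata import ScenarioSpec, simulate_dataset
from tests.conftest import make_dataset


def posterior_oracle(ref, alt, k, q, e):
    """Brute-force enumeration of the Binomial-product posterior."""
    out = np.empty(k + 1)
    for g in range(k + 1):
        f = (g / k) * (1 - e) + (1 - g / k) * e
        out[g] = binom.pmf(alt, ref + alt, f) * binom.pmf(g, k, q)
    return out / out.sum()


def test_em_frequency_trivial_cases():
    ds = make_dataset(ref=[[30], [30]], alt=[[0], [0]])
    q = estimate_allele_freqs_em(ds, 4, error_rate=0.001)
    assert q[0] < 0.01
    ds2 = make_dataset(ref=[[20], [20]], alt=[[20], [20]])
    q2 = estimate_allele_freqs_em(ds2, 4, error_rate=0.001)
    assert abs(q2[0] - 0.5) < 0.01


def test_em_frequency_simulate_and_recover():
    rng = np.random.default_rng(0)
    k, q_true, n = 4, 0.3, 16
    g = rng.binomial(k, q_true, n)
    depth = rng.poisson(30, n)
    alt = rng.binomial(depth, g / k * 0.999 + (1 - g / k) * 0.001)
    ds = make_dataset(ref=(depth - alt)[:, None], alt=alt[:, None])
    q = estimate_allele_freqs_em(ds, k, error_rate=0.001)
    assert abs(q[0] - q_true) <= 0.08


def test_all_missing_locus_flagged():
    ds = make_dataset(ref=[[0]], alt=[[0]])
    q = estimate_allele_freqs_em(ds, 4)
    assert np.isnan(q[0])


def test_map_call_overwhelming_evidence_and_missing():
    ds = make_dataset(ref=[[0, 0]], alt=[[30, 0]])
    gm = call_genotypes(ds, 4, np.array([0.5, 0.5]), error_rate=0.001)
    assert gm.dosage[0, 0] == 4
    assert gm.dosage[0, 1] == -1 and gm.missing[0, 1]


def test_posterior_matches_brute_force_enumeration():
    """Criterion oracle: posterior equals the normalized product formula to 1e-10."""
    cases = [(12, 8, 4, 0.5, 0.01), (5, 25, 4, 0.2, 0.001), (10, 10, 2, 0.7, 0.01)]
    for ref, alt, k, q, e in cases:
        ds = make_dataset(ref=[[ref]], alt=[[alt]], ploidy=k)
        gm = call_genotypes(ds, k, np.array([q]), error_rate=e)
        np.testing.assert_allclose(
            gm.posterior[0, 0, : k + 1], posterior_oracle(ref, alt, k, q, e), atol=1e-10
        )
        assert abs(gm.posterior[0, 0].sum() - 1.0) < 1e-9
        assert gm.dosage[0, 0] == gm.posterior[0, 0].argmax()


def test_map_accuracy_on_deep_tetraploids():
    spec = ScenarioSpec(
        scenario="standing_variation",
        prop_selected=0.0,
        n_loci=600,
        n_per_pop=6,
        depth_mean=200.0,
        error_rate=0.001,
        seed=21,
    )
    ft, ds = simulate_dataset(spec)
    gm = call_genotypes(ds, 4, ft.freqs.mean(axis=1).to_numpy(), error_rate=0.001)
    called = gm.dosage >= 0
    acc = (gm.dosage[called] == ds.true_dosage[called]).mean()
    assert acc >= 0.99


def test_hind_he_closed_form_and_exclusions():
    # one individual AD=(5,5): Hind = 2*25/(10*9); a 1-read individual is excluded
    ds = make_dataset(ref=[[5], [1], [4]], alt=[[5], [0], [0]])
    hh = hind_he(ds)
    np.testing.assert_allclose(hh.hind_individual[0, 0], 50 / 90)
    assert np.isnan(hh.hind_individual[1, 0])
    assert hh.table["n_ind"].iloc[0] == 2


def test_hind_he_monomorphic_undefined():
    ds = make_dataset(ref=[[10], [12]], alt=[[0], [0]])
    hh = hind_he(ds)
    assert hh.undefined[0]


def test_hind_he_matches_mendelian_expectation():
    """Diploid HWE at q=0.5, deep coverage: locus Hind/He near (k-1)/k = 0.5."""
    rng = np.random.default_rng(3)
    n, L = 200, 300
    g = rng.binomial(2, 0.5, (n, L))
    depth = np.full((n, L), 100)
    alt = rng.binomial(depth, g / 2)
    ds = make_dataset(ref=depth - alt, alt=alt, ploidy=2)
    hh = hind_he(ds)
    assert abs(np.nanmean(hh.values) - 0.5) < 0.03


def test_threshold_monotone_in_quantile_and_deterministic():
    t90 = simulate_hind_he_threshold(20, 2, (30.0, 5.0), quantile=0.90, seed=5)
    t99 = simulate_hind_he_threshold(20, 2, (30.0, 5.0), quantile=0.99, seed=5)
    assert t99 > t90
    assert t90 == simulate_hind_he_threshold(20, 2, (30.0, 5.0), quantile=0.90, seed=5)
    # diploid threshold exceeds the 0.5 HWE expectation for any depth model
    assert t90 > 0.5


def test_threshold_pair_ordering_enforced():
    pair = simulate_threshold_pair(20, (30.0, 5.0), seed=6)
    assert 0 < pair.t_diploid < pair.t_tetraploid < 1
    with pytest.raises(ValueError):
        ThresholdPair(t_diploid=0.7, t_tetraploid=0.6)


def test_partition_with_printed_thresholds():
    t = ThresholdPair(t_diploid=0.52, t_tetraploid=0.65)
    sets = partition_loci_by_ploidy(np.array([0.40, 0.60, 0.80, np.nan]), t)
    assert list(sets["diploid_set"]) == [0]
    assert list(sets["tetraploid_set"]) == [1]
    assert list(sets["discarded"]) == [2, 3]
    total = sum(len(v) for v in sets.values())
    assert total == 4  # disjoint and exhaustive


def test_coverage_filter_boundaries():
    # locus 0: 2/5 genotyped (40%) -> dropped; locus 1: depth 19.9 -> dropped;
    # locus 2: depth 20.1 in >50% -> kept
    ref = np.array(
        [[30, 19, 21], [30, 20, 20], [0, 20, 20], [0, 20, 20], [0, 20, 21]]
    )
    alt = np.zeros_like(ref)
    ref[2:, 1:] = ref[2:, 1:]  # loci 1,2 genotyped in all 5
    ds = make_dataset(ref=ref, alt=alt)
    keep, report = coverage_filter(ds, min_prop_genotyped=0.5, min_mean_depth=20.0)
    assert 0 not in keep  # 40% genotyped
    assert 1 not in keep  # mean depth 19.8 < 20
    assert 2 in keep
    assert report.n_kept + report.n_discarded == report.n_input == 3


def test_coverage_filter_empty_dataset():
    ds = make_dataset(ref=np.empty((1, 0), dtype=int), alt=np.empty((1, 0), dtype=int))
    keep, report = coverage_filter(ds)
    assert keep.size == 0 and report.n_input == 0
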