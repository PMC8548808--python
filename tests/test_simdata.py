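"""Generator correctness: drift-pulse moments, scenario structure, I/O round-trips."""

import numpy as np
import pandas as pd
import pytest

from paraploid.popstats import dxy, fst
from paraploid.simdata import (
    ReadDataset,
    ScenarioSpec,
    read_dataset,
    simulate_dataset,
    simulate_frequencies,
    simulate_reads,
    write_dataset,
)
from paraploid.simdata import _bn_pulse


@pytest.mark.parametrize(
    "kwargs",
    [
        {"ploidy": 3},  # odd ploidy
        {"prop_selected": 1.2},
        {"m": -0.1},
        {"F_eco": 0.0},
        {"F_drainage": 1.0},
        {"n_loci": 0},
        {"scenario": "panmixia"},
    ],
)
def test_spec_rejects_invalid_parameters(kwargs):
    with pytest.raises(ValueError):
        ScenarioSpec(**kwargs)


def test_balding_nichols_pulse_variance():
    """Monte-Carlo oracle: child-frequency variance equals F*p*(1-p)."""
    rng = np.random.default_rng(123)
    p, F = 0.3, 0.1
    draws = _bn_pulse(rng, np.full(100_000, p), F)
    expected = F * p * (1 - p)  # 0.021
    assert abs(draws.var() - expected) / expected < 0.05
    assert abs(draws.mean() - p) < 0.01


def test_full_admixture_homogenizes_within_drainage_pairs():
    spec = ScenarioSpec(scenario="secondary_contact", prop_selected=0.0, m=1.0, seed=3)
    ft = simulate_frequencies(spec)
    for dr in spec.drainages:
        ph = ft.freqs[f"highland_{dr}"].to_numpy()
        pl = ft.freqs[f"lowland_{dr}"].to_numpy()
        np.testing.assert_allclose(ph, pl, atol=1e-12)
        pair_fst = fst(np.stack([ph, pl], axis=1))
        assert np.nanmax(np.abs(pair_fst)) < 1e-12


def test_no_drift_limit_keeps_ancestral_frequency():
    spec = ScenarioSpec(
        scenario="standing_variation",
        prop_selected=0.0,
        F_eco=1e-4,
        F_drainage=1e-4,
        F_terminal=1e-4,
        n_loci=500,
        seed=4,
    )
    ft = simulate_frequencies(spec)
    focal = [p for p in spec.populations if p != "outgroup"]
    spread = ft.freqs[focal].max(axis=1) - ft.freqs[focal].min(axis=1)
    assert spread.max() < 0.1


def test_de_novo_selected_sets_disjoint_by_construction():
    spec = ScenarioSpec(scenario="de_novo_mutation", n_loci=2000, seed=5)
    ft = simulate_frequencies(spec)
    d1 = set(np.flatnonzero(ft.causal_drainage == "D1"))
    d2 = set(np.flatnonzero(ft.causal_drainage == "D2"))
    assert d1 and d2 and not (d1 & d2)
    assert len(d1) + len(d2) == round(spec.prop_selected * spec.n_loci)


def test_secondary_contact_selected_loci_resist_homogenization():
    spec = ScenarioSpec(scenario="secondary_contact", n_loci=2000, seed=6)
    ft = simulate_frequencies(spec)
    for dr in spec.drainages:
        d = dxy(ft.freqs[f"highland_{dr}"].to_numpy(), ft.freqs[f"lowland_{dr}"].to_numpy())
        assert d[~ft.selected].mean() < d[ft.selected].mean()


def test_selected_count_matches_proportion():
    spec = ScenarioSpec(scenario="standing_variation", n_loci=1234, prop_selected=0.07, seed=1)
    ft = simulate_frequencies(spec)
    assert ft.selected.sum() == round(0.07 * 1234)


def test_fixed_seed_reproduces_frequencies_and_reads():
    spec = ScenarioSpec(scenario="adaptive_introgression", n_loci=300, n_per_pop=3, seed=42)
    ft1, ds1 = simulate_dataset(spec)
    ft2, ds2 = simulate_dataset(spec)
    pd.testing.assert_frame_equal(ft1.freqs, ft2.freqs)
    np.testing.assert_array_equal(ds1.ref_depth, ds2.ref_depth)
    np.testing.assert_array_equal(ds1.alt_depth, ds2.alt_depth)
    np.testing.assert_array_equal(ds1.true_dosage, ds2.true_dosage)


def test_read_model_error_free_extremes():
    """With e=0, dosage 0 yields no alt reads and dosage k no ref reads."""
    spec = ScenarioSpec(
        scenario="standing_variation",
        prop_selected=0.0,
        n_loci=400,
        n_per_pop=4,
        error_rate=0.0,
        seed=9,
    )
    ft = simulate_frequencies(spec)
    ds = simulate_reads(ft, spec)
    hom_ref = ds.true_dosage == 0
    hom_alt = ds.true_dosage == ds.sample_meta["ploidy"].to_numpy()[:, None]
    assert (ds.alt_depth[hom_ref] == 0).all()
    assert (ds.ref_depth[hom_alt] == 0).all()


def test_read_depth_mean_matches_negative_binomial_oracle():
    spec = ScenarioSpec(
        scenario="standing_variation", n_loci=2500, n_per_pop=8, depth_mean=20.0, seed=10
    )
    _, ds = simulate_dataset(spec)
    depths = ds.total_depth.ravel()  # 10 pops x 8 ind x 2500 loci >= 1e5 cells
    assert depths.size >= 100_000
    assert abs(depths.mean() - 20.0) / 20.0 < 0.01


def test_vcf_round_trip_and_gt_formatting(tmp_path, contact_dataset):
    _, _, ds = contact_dataset
    vcf, pm = tmp_path / "sim.vcf", tmp_path / "popmap.tsv"
    write_dataset(ds, vcf, pm)
    back = read_dataset(vcf, pm)
    np.testing.assert_array_equal(back.ref_depth, ds.ref_depth)
    np.testing.assert_array_equal(back.alt_depth, ds.alt_depth)
    pd.testing.assert_frame_equal(back.sample_meta, ds.sample_meta)
    assert back.locus_ids == ds.locus_ids


def test_gt_strings_follow_dosage_and_ploidy(tmp_path):
    from tests.conftest import make_dataset

    ds = make_dataset(
        ref=[[10, 30], [5, 0]],
        alt=[[20, 0], [5, 25]],
        ploidy=[4, 2],
        dosage=[[1, 0], [1, 2]],
    )
    vcf = tmp_path / "mix.vcf"
    write_dataset(ds, vcf, tmp_path / "pm.tsv")
    lines = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
    rec1 = lines[0].split("\t")
    assert rec1[9].startswith("0/0/0/1:")  # tetraploid dosage 1
    assert rec1[10].startswith("0/1:")  # diploid dosage 1
    rec2 = lines[1].split("\t")
    assert rec2[9].startswith("0/0/0/0:")
    assert rec2[10].startswith("1/1:")


def test_read_dataset_rejects_incomplete_popmap(tmp_path, contact_dataset):
    _, _, ds = contact_dataset
    vcf, pm = tmp_path / "sim.vcf", tmp_path / "popmap.tsv"
    write_dataset(ds, vcf, pm)
    meta = pd.read_csv(pm, sep="\t")
    meta.iloc[1:].to_csv(pm, sep="\t", index=False)
    with pytest.raises(ValueError, match=ds.samples[0]):
        read_dataset(vcf, pm)
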