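"""Simulation batteries that measure the pipeline's operating characteristics.

Each function simulates data with known ground truth, runs the relevant part
of the pipeline end to end, and returns the measured quantity: ploidy-call
recovery, Hind/He calibration, genotype accuracy, D-statistic type-I rate,
f4-ratio admixture recovery, and scenario-classification accuracy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dstats import QuartetSpec, f4_ratio, patterson_d
from .genotyping import call_genotypes, population_dosage_frequencies
from .partition import PopulationLayout, classify_scenario, gather_evidence
from .ploidy import AlleleBalanceSet, select_ploidy
from .simdata import ScenarioSpec, simulate_dataset, simulate_frequencies, simulate_het_reads

__all__ = [
    "ploidy_recovery",
    "hindhe_mean",
    "map_accuracy",
    "d_type_i_rate",
    "f4_admixture_estimate",
    "classify_dataset",
    "classifier_battery",
    "species_grouped_by_bin",
]


def _seed_stream(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def ploidy_recovery(
    ks=(2, 3, 4),
    n_individuals: int = 20,
    n_replicates: int = 100,
    n_sites: int = 2000,
    depth_mean: float = 30.0,
    seed: int = 0,
) -> float:
    """Fraction of simulated individuals whose ploidy is correctly selected."""
    seeds = iter(_seed_stream(seed, n_replicates * n_individuals * len(ks)))
    correct = total = 0
    for _ in range(n_replicates):
        for k in ks:
            for _ in range(n_individuals):
                ref, alt = simulate_het_reads(
                    k, n_sites, depth_mean=depth_mean, seed=next(seeds)
                )
                n = ref + alt
                keep = (n >= 10) & (ref >= 3) & (alt >= 3)
                ab = AlleleBalanceSet("b", alt[keep] / n[keep], n_sites, int(keep.sum()))
                correct += select_ploidy(ab).selected == k
                total += 1
    return correct / total


def hindhe_mean(
    ploidy: int,
    n_ind: int = 100,
    depth_mean: float = 50.0,
    n_loci: int = 2000,
    seed: int = 0,
    error_rate: float = 0.001,
) -> float:
    """Mean per-locus Hind/He on Mendelian Hardy-Weinberg loci."""
    from .genotyping import _simulate_hh_values

    rng = np.random.default_rng(seed)
    vals = _simulate_hh_values(rng, n_ind, ploidy, (depth_mean, 5.0), n_loci, error_rate)
    return float(vals.mean())


def map_accuracy(
    depth_mean: float = 200.0,
    error_rate: float = 0.001,
    n_loci: int = 1500,
    seed: int = 0,
) -> float:
    """MAP dosage accuracy on simulated tetraploids at deep coverage."""
    spec = ScenarioSpec(
        scenario="standing_variation",
        prop_selected=0.0,
        n_loci=n_loci,
        n_per_pop=6,
        depth_mean=depth_mean,
        error_rate=error_rate,
        seed=seed,
    )
    ft, ds = simulate_dataset(spec)
    _, freqs = population_dosage_frequencies(ds, 4, error_rate=error_rate)
    # accuracy pooled over populations, each genotyped under its own prior
    acc_n = acc_d = 0
    for pop in spec.populations:
        idx = ds.population_members(pop)
        called = np.zeros_like(ds.true_dosage[idx], dtype=bool)
        sub_gm = call_genotypes(
            type(ds)(
                ref_depth=ds.ref_depth[idx],
                alt_depth=ds.alt_depth[idx],
                sample_meta=ds.sample_meta.iloc[idx].reset_index(drop=True),
                locus_ids=list(ds.locus_ids),
            ),
            4,
            freqs[pop].to_numpy(),
            error_rate=error_rate,
        )
        called = sub_gm.dosage >= 0
        acc_n += int((sub_gm.dosage[called] == ds.true_dosage[idx][called]).sum())
        acc_d += int(called.sum())
    return acc_n / acc_d


def d_type_i_rate(
    n_replicates: int = 100,
    n_loci: int = 2000,
    seed: int = 0,
    z_crit: float = 1.96,
) -> float:
    """|Z| > z_crit rate of Patterson's D on tree-consistent, admixture-free data."""
    seeds = _seed_stream(seed, n_replicates)
    q = QuartetSpec("lowland_D1", "highland_D1", "highland_D2", "outgroup")
    hits = 0
    for s in seeds:
        spec = ScenarioSpec(
            scenario="de_novo_mutation", prop_selected=0.0, m=0.0, n_loci=n_loci, seed=s
        )
        res = patterson_d(simulate_frequencies(spec).freqs, q)
        hits += abs(res.z) > z_crit
    return hits / n_replicates


def f4_admixture_estimate(
    m: float = 0.3,
    n_loci: int = 10000,
    prop_selected: float = 0.05,
    seed: int = 0,
) -> float:
    """f4-ratio estimate of the introgression fraction on the introgressed subset."""
    spec = ScenarioSpec(
        scenario="adaptive_introgression",
        m=m,
        n_loci=n_loci,
        prop_selected=prop_selected,
        seed=seed,
    )
    ft = simulate_frequencies(spec)
    sub = ft.freqs[ft.selected]
    res = f4_ratio(
        sub,
        ("highland_D1", "lowland_D1", "highland_D2", "lowland_D2"),
        ("highland_D1", "lowland_D1", "highland_D1", "lowland_D2"),
    )
    return float(res.d)


def classify_dataset(spec: ScenarioSpec):
    """Simulate -> genotype (known ploidy) -> classify one replicate.

    Returns (ScenarioCall, evidence dict).
    """
    ft, ds = simulate_dataset(spec)
    kvec = ds.sample_meta["ploidy"].to_numpy(dtype=int)
    _, freqs = population_dosage_frequencies(ds, kvec, error_rate=spec.error_rate)
    layout = PopulationLayout.from_sample_meta(ds.sample_meta)
    ev = gather_evidence(freqs.dropna(), layout)
    call = classify_scenario(ev)
    return call, ev


def classifier_battery(
    scenario: str,
    n_replicates: int = 50,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[list[str], list[dict]]:
    """Scenario labels (and evidence) over seeded end-to-end replicates."""
    labels, evidences = [], []
    for s in _seed_stream(seed, n_replicates):
        spec = ScenarioSpec(scenario=scenario, seed=s, **spec_kwargs)
        call, ev = classify_dataset(spec)
        labels.append(call.label)
        evidences.append(ev)
    return labels, evidences


def species_grouped_by_bin(evidences: list[dict]) -> list[float]:
    """Per F_ST bin: fraction of populated (replicate, drainage) partitions whose
    tree is species-grouped.  Bins that were never populated come back NaN."""
    out = []
    for b in range(1, 5):
        hits = total = 0
        for ev in evidences:
            for dr in ev.get("drainages", []):
                call = ev["topology"].get(f"{dr}_bin{b}")
                if call is None:
                    continue
                total += 1
                hits += call.call == "species_grouped"
        out.append(hits / total if total else float("nan"))
    return out
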