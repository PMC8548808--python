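"""Orchestrate simulate -> ploidy -> genotype -> stats -> dstat -> partition -> classify.

Every intermediate artifact is a plain file (VCF / TSV / JSON / newick) in the
output directory, so each stage can be inspected, re-run or replaced.  The
same configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dstats, genotyping, partition, ploidy, popstats, simdata

log = logging.getLogger("paraploid")

__all__ = ["PipelineConfig", "ConfigError", "StageError", "validate", "run"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 in the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name (exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Either a scenario to simulate or input paths, plus stage parameters."""

    out_dir: str = "paraploid_out"
    seed: int = 0
    scenario: dict | None = None  # ScenarioSpec fields
    vcf: str | None = None
    popmap: str | None = None
    run_ploidy: bool = True
    ploidy_table: str | None = None  # user-supplied calls; skips the ploidy stage
    min_depth: int = 10
    min_minor_reads: int = 3
    error_rate: float = 0.001
    min_prop_genotyped: float = 0.5
    min_mean_depth: float = 20.0
    maf: float = 0.05
    hindhe_sim_loci: int = 2000
    hindhe_quantile: float = 0.95
    min_loci: int = 25
    z_crit: float = 3.0
    n_blocks: int = 50
    quartets: list[list[str]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate(config: PipelineConfig) -> list[str]:
    """Schema and cross-reference checks without running anything."""
    errors: list[str] = []
    has_paths = config.vcf is not None or config.popmap is not None
    if config.scenario is not None and has_paths:
        errors.append("give either a scenario block or input paths, not both")
    if config.scenario is None and not (config.vcf and config.popmap):
        errors.append("need a scenario block, or both vcf and popmap paths")
    if config.scenario is not None:
        try:
            simdata.ScenarioSpec(**{**config.scenario, "seed": config.seed})
        except (TypeError, ValueError) as exc:
            errors.append(f"invalid scenario: {exc}")
    for path_attr in ("vcf", "popmap", "ploidy_table"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            errors.append(f"{path_attr} path does not exist: {p}")
    if not 0 <= config.maf < 0.5:
        errors.append("maf must be in [0, 0.5)")
    if config.min_depth < 1 or config.min_minor_reads < 0:
        errors.append("min_depth must be >= 1 and min_minor_reads >= 0")
    return errors


def _stage(name, report, func, *args, **kwargs):
    t0 = time.time()
    log.info("stage %s: start", name)
    try:
        result = func(*args, **kwargs)
    except Exception as exc:  # halt with the failing stage named
        raise StageError(name, exc) from exc
    report["stages"][name] = {"seconds": round(time.time() - t0, 3)}
    return result


def run(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run report (also written to disk)."""
    errors = validate(config)
    if errors:
        raise ConfigError("; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": {k: v for k, v in asdict(config).items()}}

    # --- acquire data -----------------------------------------------------
    if config.scenario is not None:
        spec = simdata.ScenarioSpec(**{**config.scenario, "seed": config.seed})

        def _simulate():
            ft, ds = simdata.simulate_dataset(spec)
            simdata.write_dataset(ds, out / "sim.vcf", out / "popmap.tsv")
            ft.freqs.to_csv(out / "true_frequencies.tsv", sep="\t")
            return ft, ds

        _, ds = _stage("simulate", report, _simulate)
    else:
        ds = _stage("load", report, simdata.read_dataset, config.vcf, config.popmap)
    report["n_samples"], report["n_loci"] = ds.n_samples, ds.n_loci

    # --- ploidy -----------------------------------------------------------
    if config.ploidy_table is not None:
        tab = pd.read_csv(config.ploidy_table, sep="\t").set_index("sample")
        ploidy_vec = tab.loc[ds.samples, "selected_k"].to_numpy(dtype=int)
        report["stages"]["ploidy"] = {"source": "user table"}
    elif config.run_ploidy:

        def _ploidy():
            rows = []
            for s in ds.samples:
                ab = ploidy.extract_allele_balance(
                    ds, s, min_depth=config.min_depth, min_minor_reads=config.min_minor_reads
                )
                call = ploidy.select_ploidy(ab)
                rows.append(
                    {
                        "sample": s,
                        "n_sites": call.n_sites,
                        "stat_k2": call.ratio[2],
                        "stat_k3": call.ratio[3],
                        "stat_k4": call.ratio[4],
                        "selected_k": call.selected,
                        "confidence": "high" if call.confident else "low",
                    }
                )
            tab = pd.DataFrame(rows)
            tab.to_csv(out / "ploidy.tsv", sep="\t", index=False)
            return tab["selected_k"].to_numpy(dtype=int)

        ploidy_vec = _stage("ploidy", report, _ploidy)
    else:
        ploidy_vec = ds.sample_meta["ploidy"].to_numpy(dtype=int)
        report["stages"]["ploidy"] = {"source": "popmap"}

    # --- genotype + filters -----------------------------------------------
    def _genotype():
        keep, cov_report = genotyping.coverage_filter(
            ds, config.min_prop_genotyped, config.min_mean_depth
        )
        hh = genotyping.hind_he(ds)
        thresholds = genotyping.simulate_threshold_pair(
            ds.n_samples,
            depth_model=ds.total_depth,
            n_sim_loci=config.hindhe_sim_loci,
            quantile=config.hindhe_quantile,
            seed=config.seed,
            error_rate=config.error_rate,
        )
        sets = genotyping.partition_loci_by_ploidy(hh, thresholds)
        gm, freqs = genotyping.population_dosage_frequencies(
            ds, ploidy_vec, error_rate=config.error_rate
        )
        global_p = np.nanmean(freqs.to_numpy(), axis=1)
        maf_keep = popstats.maf_filter(global_p, config.maf)
        retained = np.intersect1d(keep, maf_keep)
        filters = {
            "coverage": asdict(cov_report),
            "thresholds": {
                "t_diploid": thresholds.t_diploid,
                "t_tetraploid": thresholds.t_tetraploid,
                **thresholds.meta,
            },
            "ploidy_consistency": {k: int(v.size) for k, v in sets.items()},
            "maf": {"threshold": config.maf, "n_kept": int(maf_keep.size)},
            "retained": int(retained.size),
        }
        with open(out / "filters.json", "w") as fh:
            json.dump(filters, fh, indent=2, default=str)
        hh.table.to_csv(out / "hind_he.tsv", sep="\t")
        return gm, freqs, retained

    gm, freqs, retained = _stage("genotype", report, _genotype)
    report["n_retained_loci"] = int(retained.size)
    freqs_ret = freqs.iloc[retained]

    # --- stats ------------------------------------------------------------
    layout = partition.PopulationLayout.from_sample_meta(ds.sample_meta)
    pairs = [(layout.highland(d), layout.lowland(d)) for d in layout.drainages]

    def _stats():
        table = popstats.locus_stats_table(freqs_ret.dropna(), pairs=pairs)
        table.to_csv(out / "locus_stats.tsv", sep="\t")
        return table

    _stage("stats", report, _stats)

    # --- dstats -----------------------------------------------------------
    def _dstat():
        quartets = [tuple(q) for q in config.quartets]
        if not quartets and layout.outgroup and len(layout.drainages) >= 2:
            dX, dY = layout.drainages[:2]
            quartets = [
                (layout.lowland(dX), layout.highland(dX), layout.highland(dY), layout.outgroup),
                (layout.lowland(dX), layout.highland(dX), layout.lowland(dY), layout.outgroup),
            ]
        rows = []
        for q in quartets:
            res = dstats.patterson_d(
                freqs_ret.dropna(), dstats.QuartetSpec(*q), n_blocks=config.n_blocks
            )
            rows.append(
                {
                    "p1": q[0], "p2": q[1], "p3": q[2], "outgroup": q[3],
                    "d": res.d, "se": res.se, "z": res.z,
                    "f4": res.f4, "n_loci": res.n_loci,
                }
            )
        tab = pd.DataFrame(rows)
        tab.to_csv(out / "dstats.tsv", sep="\t", index=False)
        return tab

    _stage("dstat", report, _dstat)

    # --- partition + classify ----------------------------------------------
    def _partition():
        pdir = out / "partition"
        pdir.mkdir(exist_ok=True)
        ratio_tab = partition.dxy_ratio_table(freqs_ret.dropna(), layout)
        ratio_tab.to_csv(pdir / "dxy_ratio.tsv", sep="\t")
        ev = partition.gather_evidence(
            freqs_ret.dropna(), layout, min_loci=config.min_loci, n_blocks=config.n_blocks
        )
        bins = pd.DataFrame(
            {f"bin_{d}": ev["bins"][d] for d in layout.drainages},
            index=freqs_ret.dropna().index,
        )
        bins.to_csv(pdir / "fst_bins.tsv", sep="\t")
        for key, call in ev["topology"].items():
            if call is None:
                continue
            idx = np.flatnonzero(ev["bins"][key.rsplit("_bin", 1)[0]] == int(key[-1]))
            sub = freqs_ret.dropna()[layout.focal_populations].iloc[idx]
            tree = partition.nj_tree(partition.pop_distance_matrix(sub), key, len(sub))
            with open(pdir / f"tree_{key}.nwk", "w") as fh:
                fh.write(str(tree.tree))
        call = partition.classify_scenario(ev, z_crit=config.z_crit)
        summary = call.evidence.get("summary", {})
        payload = {
            "label": call.label,
            "reason": call.reason,
            "z_max": summary.get("z_max"),
            "outlier_jaccard": summary.get("outlier_jaccard"),
            "shared_ancestry_drainages": summary.get("shared_ancestry_drainages"),
            "topology": {
                k: (v.call if v else None) for k, v in call.evidence["topology"].items()
            },
        }
        with open(out / "scenario_call.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
        return call

    call = _stage("partition", report, _partition)
    report["scenario_call"] = call.label

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
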