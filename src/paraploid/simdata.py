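"""Synthetic mixed-ploidy SNP read datasets under four ecotype-origin scenarios.

Every downstream stage of the pipeline (ploidy inference, dosage genotyping,
differentiation statistics, partitioned tree analysis) is exercised against data
generated here, where the ground truth — true allele frequencies, true dosages,
which loci are under divergent selection, and which evolutionary scenario
produced them — is known exactly.

The demographic model is a population tree of drainage basins crossed with
elevational ecotypes (highland / lowland).  Drift along each branch is realised
as a Balding–Nichols pulse: a child population's allele frequency is drawn from
a Beta distribution with mean equal to the parent frequency ``p`` and variance
``F * p * (1 - p)``, where ``F`` in (0, 1) is the drift intensity of that
branch.  Loci are unlinked; there is no haplotype structure.

Four scenarios are supported, differing in branch order and in how the selected
loci behave:

``standing_variation``
    Drainages split first, ecotypes within drainages after.  One shared set of
    selected loci; the same (ancestrally rare) allele is driven to ``sel_shift``
    in the highland population of every drainage.
``de_novo_mutation``
    Same branch order; each drainage has its own disjoint set of selected loci,
    driven only in that drainage's highland population.
``secondary_contact``
    Ecotypes split first (divergence in isolation), drainages within ecotypes
    after.  At selected loci the highland ecotype ancestor is driven to
    ``sel_shift`` before the drainage split.  On contact, each highland
    population receives a fraction ``m`` of its allele frequencies from the
    lowland population of the same drainage — at neutral loci only, because
    selection constrains introgression at the adaptive loci.
``adaptive_introgression``
    Drainage-first branch order; selected loci are driven in the donor
    drainage's highland population, and the recipient drainage's highland
    population receives them with weight ``m``
    (``p' = (1-m) * p_self + m * p_donor``).

Read data are layered on top of the frequencies: dosages are Binomial(k, p)
(autopolyploid Hardy-Weinberg), total depths are negative-binomial, and
alternate read counts are Binomial with a symmetric per-read miscall rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "FreqTable",
    "ReadDataset",
    "simulate_frequencies",
    "simulate_reads",
    "simulate_dataset",
    "simulate_het_reads",
    "write_dataset",
    "read_dataset",
]

SCENARIOS = (
    "standing_variation",
    "de_novo_mutation",
    "secondary_contact",
    "adaptive_introgression",
)

# Frequencies are clamped into this interval before every Beta pulse and before
# binomial sampling, so loci stay informative at small n.
_FREQ_CLAMP = (0.001, 0.999)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic dataset.

    ``F_eco``, ``F_drainage`` and ``F_terminal`` are the Balding–Nichols drift
    intensities of, respectively, the ecotype-split branches, the
    drainage-split branches and the terminal (population-specific) branches.
    ``m`` is the admixture fraction applied at secondary contact (and the copy
    weight for adaptive introgression).  ``sel_shift`` is the frequency the
    favoured allele is driven to in highland populations at selected loci.
    """

    scenario: str = "secondary_contact"
    n_drainages: int = 2
    ecotypes: tuple[str, str] = ("highland", "lowland")
    include_outgroup: bool = True
    n_loci: int = 5000
    prop_selected: float = 0.05
    F_eco: float = 0.1
    F_drainage: float = 0.1
    F_terminal: float = 0.05
    m: float = 0.5
    sel_shift: float = 0.95
    n_per_pop: int = 8
    ploidy: int | dict[str, int] = 4
    depth_mean: float = 25.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n_drainages < 1:
            raise ValueError("n_drainages must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        for name in ("prop_selected", "m", "sel_shift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("F_eco", "F_drainage", "F_terminal"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for pop, k in self.ploidy_map.items():
            if k < 2 or k % 2 != 0:
                raise ValueError(f"ploidy must be an even integer >= 2, got {k} for {pop!r}")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    @property
    def drainages(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_drainages)]

    @property
    def populations(self) -> list[str]:
        pops = [f"{eco}_{dr}" for dr in self.drainages for eco in self.ecotypes]
        if self.include_outgroup:
            pops.append("outgroup")
        return pops

    @property
    def ploidy_map(self) -> dict[str, int]:
        if isinstance(self.ploidy, dict):
            missing = set(self.populations) - set(self.ploidy)
            if missing:
                raise ValueError(f"ploidy dict missing populations: {sorted(missing)}")
            return {p: int(self.ploidy[p]) for p in self.populations}
        return {p: int(self.ploidy) for p in self.populations}


@dataclass
class FreqTable:
    """Per-locus, per-population alternate-allele frequencies with truth flags."""

    freqs: pd.DataFrame  # loci x populations
    selected: np.ndarray  # bool, per locus
    causal_drainage: np.ndarray  # object array: drainage id, "shared", or ""
    spec: ScenarioSpec

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[0]

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)


@dataclass
class ReadDataset:
    """Per-individual, per-locus ref/alt read depths plus sample metadata.

    The common currency of all pipeline stages.  ``sample_meta`` has one row
    per sample with columns sample, population, drainage, ecotype, ploidy.
    """

    ref_depth: np.ndarray  # (n_samples, n_loci) int
    alt_depth: np.ndarray  # (n_samples, n_loci) int
    sample_meta: pd.DataFrame
    locus_ids: list[str] = field(default_factory=list)
    true_dosage: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ref_depth.shape != self.alt_depth.shape:
            raise ValueError("ref_depth and alt_depth shapes differ")
        if len(self.sample_meta) != self.ref_depth.shape[0]:
            raise ValueError("sample_meta does not cover every sample")
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("read depths must be non-negative")
        if not self.locus_ids:
            self.locus_ids = [f"L{i:06d}" for i in range(self.ref_depth.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.ref_depth.shape[0]

    @property
    def n_loci(self) -> int:
        return self.ref_depth.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.sample_meta["sample"])

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def sample_index(self, sample: str) -> int:
        idx = self.sample_meta.index[self.sample_meta["sample"] == sample]
        if len(idx) == 0:
            raise KeyError(f"unknown sample {sample!r}")
        return int(idx[0])

    def population_members(self, population: str) -> np.ndarray:
        mask = (self.sample_meta["population"] == population).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return np.flatnonzero(mask)


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, *_FREQ_CLAMP)


def _bn_pulse(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding–Nichols drift pulse: Beta draw with mean p, variance F*p*(1-p)."""
    p = _clamp(np.asarray(p, dtype=float))
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return _clamp(rng.beta(a, b))


def simulate_frequencies(spec: ScenarioSpec) -> FreqTable:
    """Realise hierarchical drift and selection for one scenario.

    Branch order is drainage-first for standing_variation, de_novo_mutation and
    adaptive_introgression, ecotype-first for secondary_contact; see the module
    docstring for how selected loci behave in each scenario.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    L = spec.n_loci
    n_sel = round(spec.prop_selected * L)

    selected = np.zeros(L, dtype=bool)
    sel_idx = rng.choice(L, size=n_sel, replace=False) if n_sel else np.empty(0, int)
    selected[sel_idx] = True
    causal = np.full(L, "", dtype=object)

    # Ancestral frequencies: neutral loci broadly polymorphic, the adaptive
    # allele rare before selection.
    p0 = rng.uniform(0.05, 0.95, size=L)
    p0[selected] = rng.uniform(0.05, 0.15, size=n_sel)

    high, low = spec.ecotypes
    freqs: dict[str, np.ndarray] = {}

    if spec.include_outgroup:
        freqs["outgroup"] = _bn_pulse(rng, p0, 2.0 * spec.F_eco)

    if spec.scenario == "secondary_contact":
        # Divergence first: ecotypes split in isolation, then spread across
        # drainages, then come into contact within each drainage.
        p_eco = {eco: _bn_pulse(rng, p0, spec.F_eco) for eco in spec.ecotypes}
        p_eco[high] = p_eco[high].copy()
        p_eco[high][selected] = spec.sel_shift  # pre-contact divergent selection
        for dr in spec.drainages:
            for eco in spec.ecotypes:
                p = _bn_pulse(rng, p_eco[eco], spec.F_drainage)
                freqs[f"{eco}_{dr}"] = _bn_pulse(rng, p, spec.F_terminal)
        # Contact: highland receives lowland migrants at neutral loci only.
        for dr in spec.drainages:
            ph = freqs[f"{high}_{dr}"]
            pl = freqs[f"{low}_{dr}"]
            mixed = (1.0 - spec.m) * ph + spec.m * pl
            freqs[f"{high}_{dr}"] = np.where(selected, ph, mixed)
        causal[selected] = "shared"
    else:
        # Drainage-first branch order.
        for dr in spec.drainages:
            p_dr = _bn_pulse(rng, p0, spec.F_drainage)
            for eco in spec.ecotypes:
                p = _bn_pulse(rng, p_dr, spec.F_eco)
                freqs[f"{eco}_{dr}"] = _bn_pulse(rng, p, spec.F_terminal)

        if spec.scenario == "standing_variation":
            for dr in spec.drainages:
                freqs[f"{high}_{dr}"][selected] = spec.sel_shift
            causal[selected] = "shared"
        elif spec.scenario == "de_novo_mutation":
            # Disjoint selected-locus sets, one per drainage.
            parts = np.array_split(sel_idx, spec.n_drainages)
            for dr, part in zip(spec.drainages, parts):
                freqs[f"{high}_{dr}"][part] = spec.sel_shift
                causal[part] = dr
        elif spec.scenario == "adaptive_introgression":
            donor, *recipients = spec.drainages
            freqs[f"{high}_{donor}"][selected] = spec.sel_shift
            for dr in recipients:
                ph = freqs[f"{high}_{dr}"]
                ph[selected] = (1.0 - spec.m) * ph[selected] + spec.m * freqs[
                    f"{high}_{donor}"
                ][selected]
            causal[selected] = donor

    table = pd.DataFrame({pop: _clamp(freqs[pop]) for pop in spec.populations})
    table.index = [f"L{i:06d}" for i in range(L)]
    return FreqTable(freqs=table, selected=selected, causal_drainage=causal, spec=spec)


def _nb_depths(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    # NegBin with mean `mean` and shape `dispersion` (variance mean + mean^2/dispersion).
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_reads(freq_table: FreqTable, spec: ScenarioSpec | None = None) -> ReadDataset:
    """Layer autopolyploid genotypes and sequencing reads onto frequencies.

    Per individual and locus: dosage ~ Binomial(k, p); total depth ~ negative
    binomial; alternate reads ~ Binomial(depth, f(1-e) + (1-f)e) with
    f = dosage/k and e the per-read miscall rate.
    """
    spec = spec or freq_table.spec
    if list(freq_table.populations) != spec.populations:
        raise ValueError("FreqTable populations do not match the ScenarioSpec layout")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    ploidy_map = spec.ploidy_map
    L = freq_table.n_loci

    rows = []
    dosages, refs, alts = [], [], []
    for pop in spec.populations:
        k = ploidy_map[pop]
        p = _clamp(freq_table.freqs[pop].to_numpy())
        drain, eco = ("", "")
        if pop != "outgroup":
            eco, drain = pop.split("_", 1)
        for i in range(spec.n_per_pop):
            name = f"{pop}_{i:02d}"
            rows.append((name, pop, drain, eco, k))
            g = rng.binomial(k, p)
            depth = _nb_depths(rng, spec.depth_mean, spec.depth_dispersion, L)
            f = g / k
            p_alt_read = f * (1.0 - spec.error_rate) + (1.0 - f) * spec.error_rate
            a = rng.binomial(depth, p_alt_read)
            dosages.append(g)
            refs.append(depth - a)
            alts.append(a)

    meta = pd.DataFrame(rows, columns=["sample", "population", "drainage", "ecotype", "ploidy"])
    return ReadDataset(
        ref_depth=np.asarray(refs),
        alt_depth=np.asarray(alts),
        sample_meta=meta,
        locus_ids=list(freq_table.freqs.index),
        true_dosage=np.asarray(dosages),
    )


def simulate_dataset(spec: ScenarioSpec) -> tuple[FreqTable, ReadDataset]:
    """Convenience: frequencies plus reads for one ScenarioSpec."""
    ft = simulate_frequencies(spec)
    return ft, simulate_reads(ft, spec)


def simulate_het_reads(
    k: int,
    n_sites: int,
    depth_mean: float = 30.0,
    depth_dispersion: float = 5.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(ref, alt) depths at heterozygous sites of a single ploidy-k individual.

    Site allele frequencies are Uniform(0.1, 0.9); dosages are Binomial(k, q)
    conditioned on heterozygosity.  Used to exercise ploidy model selection on
    data with a known answer.
    """
    rng = np.random.default_rng(seed)
    q = rng.uniform(0.1, 0.9, size=n_sites)
    g = rng.binomial(k, q)
    het = (g > 0) & (g < k)
    while not het.all():  # resample homozygous draws until all sites are het
        n_bad = int((~het).sum())
        g[~het] = rng.binomial(k, rng.uniform(0.1, 0.9, size=n_bad))
        het = (g > 0) & (g < k)
    depth = _nb_depths(rng, depth_mean, depth_dispersion, n_sites)
    f = g / k
    alt = rng.binomial(depth, f * (1 - error_rate) + (1 - f) * error_rate)
    return depth - alt, alt


# ---------------------------------------------------------------------------
# VCF / popmap I/O


def write_dataset(ds: ReadDataset, vcf_path, popmap_path) -> None:
    """Write a ReadDataset as VCF v4.2 (FORMAT GT:AD) plus a popmap TSV.

    GT carries one allele per chromosome copy under the sample's ploidy, e.g. a
    tetraploid with alternate dosage 1 is written ``0/0/0/1``; samples with no
    reads (or no known dosage) get ``./.``-style missing genotypes.  AD is
    "ref,alt".  Reading the files back round-trips depths and metadata exactly.
    """
    meta = ds.sample_meta
    ploidies = meta["ploidy"].to_numpy()
    gt_cache: dict[tuple[int, int], str] = {}

    def gt_string(k: int, d: int) -> str:
        key = (k, d)
        if key not in gt_cache:
            gt_cache[key] = "/".join(["0"] * (k - d) + ["1"] * d)
        return gt_cache[key]

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n'
        )
        fh.write("##contig=<ID=sim>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples)
            + "\n"
        )
        for j, locus in enumerate(ds.locus_ids):
            fields = [f"sim\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT:AD"]
            for i in range(ds.n_samples):
                r, a = int(ds.ref_depth[i, j]), int(ds.alt_depth[i, j])
                k = int(ploidies[i])
                if ds.true_dosage is not None and r + a > 0:
                    gt = gt_string(k, int(ds.true_dosage[i, j]))
                elif r + a > 0:
                    gt = "/".join(["."] * k)
                else:
                    gt = "/".join(["."] * k)
                fields.append(f"{gt}:{r},{a}")
            fh.write("\t".join(fields) + "\n")

    meta.to_csv(popmap_path, sep="\t", index=False)


def read_dataset(vcf_path, popmap_path) -> ReadDataset:
    """Read a VCF with FORMAT/AD and a popmap TSV back into a ReadDataset."""
    from cyvcf2 import VCF

    meta = pd.read_csv(popmap_path, sep="\t", keep_default_na=False)
    required = {"sample", "population", "drainage", "ecotype", "ploidy"}
    if not required.issubset(meta.columns):
        raise ValueError(f"popmap must have columns {sorted(required)}")

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing = set(samples) - set(meta["sample"])
    if missing:
        raise ValueError(f"popmap missing samples present in VCF: {sorted(missing)}")
    meta = meta.set_index("sample").loc[samples].reset_index()

    refs, alts, loci = [], [], []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"record {var.ID or var.POS} lacks FORMAT/AD")
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
        loci.append(var.ID or f"{var.CHROM}:{var.POS}")
    vcf.close()

    return ReadDataset(
        ref_depth=np.asarray(refs, dtype=int).T,
        alt_depth=np.asarray(alts, dtype=int).T,
        sample_meta=meta,
        locus_ids=loci,
    )
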