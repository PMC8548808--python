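"""Ploidy-aware dosage genotyping, the Hind/He statistic, and locus filters.

Genotypes are alternate-allele dosages ``g in 0..k`` for an individual of
ploidy ``k``.  Calling is Bayesian with a population-informed prior: the
population allele frequency ``q`` (itself estimated by EM over the read data)
defines a Binomial(k, q) dosage prior under autopolyploid Hardy-Weinberg, and
the read likelihood is Binomial(alt | depth, f_g) with
``f_g = (g/k)(1-e) + (1-g/k)e`` for per-read miscall rate ``e``.

Hind/He is the probability that two reads sampled (without replacement) from
one individual at a locus carry different alleles, divided by the population
gene diversity at that locus.  Under Mendelian segregation its expectation is
``(k-1)/k`` — 0.5 for diploids, 0.75 for tetraploids — so per-locus values,
compared against thresholds obtained by simulating well-behaved loci under the
observed depth distribution, separate loci consistent with diploid inheritance
from tetraploid-consistent ones and from paralog-collapse artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "GenotypeMatrix",
    "HindHeTable",
    "ThresholdPair",
    "FilterReport",
    "estimate_allele_freqs_em",
    "call_genotypes",
    "population_dosage_frequencies",
    "hind_he",
    "simulate_hind_he_threshold",
    "simulate_threshold_pair",
    "partition_loci_by_ploidy",
    "coverage_filter",
]


@dataclass
class GenotypeMatrix:
    """MAP dosage calls with full posteriors.

    ``dosage`` is -1 where missing (zero depth); ``posterior`` has shape
    (n_samples, n_loci, max_ploidy + 1), rows for an individual of ploidy k
    use entries 0..k and are zero beyond.
    """

    dosage: np.ndarray
    posterior: np.ndarray
    ploidy: np.ndarray  # per individual
    locus_ids: list[str] = field(default_factory=list)

    @property
    def missing(self) -> np.ndarray:
        return self.dosage < 0


@dataclass
class HindHeTable:
    """Per-locus mean Hind/He plus its ingredients."""

    table: pd.DataFrame  # columns: hind_he, he, n_ind; index: locus ids
    hind_individual: np.ndarray  # (n_samples, n_loci), NaN where not contributing

    @property
    def values(self) -> np.ndarray:
        return self.table["hind_he"].to_numpy()

    @property
    def undefined(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class ThresholdPair:
    """Simulated 95%-quantile Hind/He upper bounds for the two ploidy models."""

    t_diploid: float
    t_tetraploid: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.t_diploid < self.t_tetraploid < 1.0):
            raise ValueError(
                f"require 0 < t_diploid < t_tetraploid < 1, got "
                f"({self.t_diploid}, {self.t_tetraploid})"
            )


@dataclass
class FilterReport:
    rule: str
    n_input: int
    n_kept: int
    n_discarded: int
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_kept + self.n_discarded != self.n_input:
            raise ValueError("kept + discarded must equal input loci")


def _dosage_loglik(ref: np.ndarray, alt: np.ndarray, k: int, error_rate: float) -> np.ndarray:
    """Read log-likelihood per dosage, shape (k+1, ...) matching ref/alt.

    The binomial coefficient is constant across dosages and omitted; it cancels
    on normalisation.
    """
    g = np.arange(k + 1, dtype=float)
    f = g / k
    p_alt = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    shape = (k + 1,) + (1,) * ref.ndim
    p_alt = p_alt.reshape(shape)
    return alt[None] * np.log(p_alt) + ref[None] * np.log1p(-p_alt)


def estimate_allele_freqs_em(
    ds,
    ploidy: int | np.ndarray,
    error_rate: float = 0.001,
    max_iter: int = 50,
    tol: float = 1e-6,
    sample_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Per-locus allele frequency by EM over dosage posteriors.

    Iterates frequency -> Binomial(k, q) prior -> per-individual posteriors ->
    frequency = mean posterior dosage / ploidy, until the largest frequency
    change is below ``tol``.  Loci with no covered individual come back NaN.
    ``sample_idx`` restricts the estimate to a subset (e.g. one population).
    """
    idx = np.arange(ds.n_samples) if sample_idx is None else np.asarray(sample_idx)
    ref = ds.ref_depth[idx].astype(float)
    alt = ds.alt_depth[idx].astype(float)
    kvec = np.broadcast_to(np.asarray(ploidy), (len(idx),))
    if len(set(kvec.tolist())) != 1:
        # Mixed ploidies: accumulate expected dosages per ploidy group.
        return _em_mixed(ref, alt, kvec, error_rate, max_iter, tol)
    k = int(kvec[0])

    depth = ref + alt
    covered = depth > 0
    any_cov = covered.any(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = alt.sum(axis=0) / np.maximum(depth.sum(axis=0), 1e-12)
    q = np.clip(q, 1e-4, 1 - 1e-4)

    loglik = _dosage_loglik(ref, alt, k, error_rate)  # (k+1, n, L)
    g = np.arange(k + 1, dtype=float).reshape(-1, 1, 1)
    from scipy.stats import binom

    for _ in range(max_iter):
        logprior = binom.logpmf(np.arange(k + 1), k, q[:, None]).T[:, None, :]  # (k+1,1,L)
        logpost = loglik + logprior
        logpost -= logsumexp(logpost, axis=0, keepdims=True)
        post = np.exp(logpost)
        eg = (post * g).sum(axis=0)  # (n, L) expected dosage
        eg = np.where(covered, eg, np.nan)
        with np.errstate(invalid="ignore"):
            q_new = np.nansum(eg, axis=0) / (k * np.maximum(covered.sum(axis=0), 1))
        q_new = np.clip(q_new, 1e-6, 1 - 1e-6)
        delta = np.nanmax(np.abs(np.where(any_cov, q_new - q, 0.0)))
        q = q_new
        if delta < tol:
            break
    return np.where(any_cov, q, np.nan)


def _em_mixed(ref, alt, kvec, error_rate, max_iter, tol):
    from scipy.stats import binom

    depth = ref + alt
    covered = depth > 0
    any_cov = covered.any(axis=0)
    q = np.clip(alt.sum(axis=0) / np.maximum(depth.sum(axis=0), 1e-12), 1e-4, 1 - 1e-4)
    groups = {int(k): np.flatnonzero(kvec == k) for k in np.unique(kvec)}
    logliks = {
        k: _dosage_loglik(ref[gi].astype(float), alt[gi].astype(float), k, error_rate)
        for k, gi in groups.items()
    }
    for _ in range(max_iter):
        num = np.zeros(ref.shape[1])
        den = np.zeros(ref.shape[1])
        for k, gi in groups.items():
            logprior = binom.logpmf(np.arange(k + 1), k, q[:, None]).T[:, None, :]
            logpost = logliks[k] + logprior
            logpost -= logsumexp(logpost, axis=0, keepdims=True)
            eg = (np.exp(logpost) * np.arange(k + 1).reshape(-1, 1, 1)).sum(axis=0)
            cov_k = covered[gi]
            num += np.where(cov_k, eg, 0.0).sum(axis=0)
            den += k * cov_k.sum(axis=0)
        q_new = np.clip(num / np.maximum(den, 1), 1e-6, 1 - 1e-6)
        delta = np.max(np.abs(np.where(any_cov, q_new - q, 0.0)))
        q = q_new
        if delta < tol:
            break
    return np.where(any_cov, q, np.nan)


def call_genotypes(
    ds,
    ploidy: int | np.ndarray,
    freqs: np.ndarray,
    error_rate: float = 0.001,
) -> GenotypeMatrix:
    """MAP dosages with full posteriors, P(g | reads) ∝ Binom(alt | n, f_g) Binom(g | k, q)."""
    from scipy.stats import binom

    kvec = np.broadcast_to(np.asarray(ploidy), (ds.n_samples,)).astype(int)
    kmax = int(kvec.max())
    n, L = ds.n_samples, ds.n_loci
    posterior = np.zeros((n, L, kmax + 1))
    dosage = np.full((n, L), -1, dtype=int)
    depth = ds.total_depth
    q = np.where(np.isfinite(freqs), np.clip(freqs, 1e-6, 1 - 1e-6), 0.5)

    for k in np.unique(kvec):
        gi = np.flatnonzero(kvec == k)
        loglik = _dosage_loglik(
            ds.ref_depth[gi].astype(float), ds.alt_depth[gi].astype(float), int(k), error_rate
        )
        logprior = binom.logpmf(np.arange(k + 1), int(k), q[:, None]).T[:, None, :]
        logpost = loglik + logprior
        logpost -= logsumexp(logpost, axis=0, keepdims=True)
        post = np.moveaxis(np.exp(logpost), 0, -1)  # (len(gi), L, k+1)
        posterior[gi, :, : k + 1] = post
        dosage[gi] = post.argmax(axis=-1)

    dosage[depth == 0] = -1
    posterior[depth == 0] = 0.0
    return GenotypeMatrix(
        dosage=dosage, posterior=posterior, ploidy=kvec, locus_ids=list(ds.locus_ids)
    )


def population_dosage_frequencies(
    ds,
    ploidy: int | np.ndarray,
    error_rate: float = 0.001,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotype every population with its own EM frequency prior and return the
    combined GenotypeMatrix plus per-population allele frequencies from the
    MAP dosages (sum of dosages over sum of ploidies of genotyped samples)."""
    meta = ds.sample_meta
    kvec = np.broadcast_to(np.asarray(ploidy), (ds.n_samples,)).astype(int)
    kmax = int(kvec.max())
    dosage = np.full((ds.n_samples, ds.n_loci), -1, dtype=int)
    posterior = np.zeros((ds.n_samples, ds.n_loci, kmax + 1))
    freq_cols: dict[str, np.ndarray] = {}
    for pop in dict.fromkeys(meta["population"]):
        idx = ds.population_members(pop)
        q = estimate_allele_freqs_em(ds, kvec[idx], error_rate=error_rate, sample_idx=idx)
        sub = type(ds)(
            ref_depth=ds.ref_depth[idx],
            alt_depth=ds.alt_depth[idx],
            sample_meta=meta.iloc[idx].reset_index(drop=True),
            locus_ids=list(ds.locus_ids),
        )
        gm = call_genotypes(sub, kvec[idx], q, error_rate=error_rate)
        dosage[idx] = gm.dosage
        posterior[idx, :, : gm.posterior.shape[2]] = gm.posterior
        ok = gm.dosage >= 0
        n_chrom = (ok * kvec[idx][:, None]).sum(axis=0)
        p = np.where(ok, gm.dosage, 0).sum(axis=0) / np.maximum(n_chrom, 1)
        freq_cols[pop] = np.where(n_chrom > 0, p, np.nan)
    combined = GenotypeMatrix(
        dosage=dosage, posterior=posterior, ploidy=kvec, locus_ids=list(ds.locus_ids)
    )
    return combined, pd.DataFrame(freq_cols, index=list(ds.locus_ids))


def hind_he(ds, sample_idx: np.ndarray | None = None) -> HindHeTable:
    """Per-locus mean Hind/He across individuals.

    Per individual, Hind = 2*r*a / (n*(n-1)) with r, a the ref/alt read counts
    and n = r + a >= 2; He = 2*p(1-p) with p the pooled read proportion across
    individuals.  Monomorphic loci (He = 0) are flagged undefined (NaN).
    """
    idx = np.arange(ds.n_samples) if sample_idx is None else np.asarray(sample_idx)
    r = ds.ref_depth[idx].astype(float)
    a = ds.alt_depth[idx].astype(float)
    n = r + a
    contributing = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        hind = np.where(contributing, 2.0 * r * a / (n * (n - 1.0)), np.nan)
        p_pool = a.sum(axis=0) / np.maximum(n.sum(axis=0), 1e-12)
    he = 2.0 * p_pool * (1.0 - p_pool)
    n_contrib = contributing.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_hind = np.nanmean(np.where(contributing, hind, np.nan), axis=0)
        ratio = np.where((he > 0) & (n_contrib > 0), mean_hind / he, np.nan)
    table = pd.DataFrame(
        {"hind_he": ratio, "he": he, "n_ind": n_contrib}, index=list(ds.locus_ids)
    )
    return HindHeTable(table=table, hind_individual=hind)


def _simulate_hh_values(
    rng: np.random.Generator,
    n_ind: int,
    ploidy: int,
    depth_model,
    n_sim_loci: int,
    error_rate: float,
) -> np.ndarray:
    q = rng.uniform(0.05, 0.95, size=n_sim_loci)
    g = rng.binomial(ploidy, q[None, :] * np.ones((n_ind, 1)))
    if isinstance(depth_model, tuple):
        mean, dispersion = depth_model
        depth = rng.negative_binomial(
            dispersion, dispersion / (dispersion + mean), size=(n_ind, n_sim_loci)
        )
    else:  # empirical depths: resample observed per-cell totals
        pool = np.asarray(depth_model).ravel()
        pool = pool[pool > 0]
        if pool.size == 0:
            raise ValueError("degenerate depth model: no positive depths")
        depth = rng.choice(pool, size=(n_ind, n_sim_loci), replace=True)
    f = g / ploidy
    alt = rng.binomial(depth, f * (1 - error_rate) + (1 - f) * error_rate)
    ref = depth - alt
    n = depth.astype(float)
    contributing = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        hind = np.where(contributing, 2.0 * ref * alt / (n * (n - 1.0)), np.nan)
        p_pool = alt.sum(axis=0) / np.maximum(depth.sum(axis=0), 1e-12)
    he = 2.0 * p_pool * (1.0 - p_pool)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.nanmean(hind, axis=0) / he
    return vals[np.isfinite(vals)]


def simulate_hind_he_threshold(
    n_ind: int,
    ploidy: int,
    depth_model,
    n_sim_loci: int = 2000,
    quantile: float = 0.95,
    seed: int = 0,
    error_rate: float = 0.001,
) -> float:
    """Upper-bound Hind/He threshold for one ploidy model.

    Simulates well-behaved Mendelian loci (frequency Uniform(0.05, 0.95),
    dosages Binomial(k, q), reads under the given depth model) and returns the
    requested quantile of the per-locus Hind/He distribution.
    """
    rng = np.random.default_rng(seed)
    vals = _simulate_hh_values(rng, n_ind, ploidy, depth_model, n_sim_loci, error_rate)
    if vals.size == 0:
        raise ValueError("simulation produced no defined Hind/He values")
    return float(np.quantile(vals, quantile))


def simulate_threshold_pair(
    n_ind: int,
    depth_model,
    n_sim_loci: int = 2000,
    quantile: float = 0.95,
    seed: int = 0,
    error_rate: float = 0.001,
) -> ThresholdPair:
    """Diploid and tetraploid Hind/He thresholds from matched simulations."""
    t2 = simulate_hind_he_threshold(
        n_ind, 2, depth_model, n_sim_loci, quantile, seed, error_rate
    )
    t4 = simulate_hind_he_threshold(
        n_ind, 4, depth_model, n_sim_loci, quantile, seed + 1, error_rate
    )
    return ThresholdPair(
        t_diploid=t2,
        t_tetraploid=t4,
        meta={
            "n_ind": n_ind,
            "depth_model": depth_model if isinstance(depth_model, tuple) else "empirical",
            "n_sim_loci": n_sim_loci,
            "quantile": quantile,
            "seed": seed,
        },
    )


def partition_loci_by_ploidy(
    hh: HindHeTable | np.ndarray, thresholds: ThresholdPair
) -> dict[str, np.ndarray]:
    """Split loci into diploid-consistent / tetraploid-consistent / discarded.

    Thresholds are inclusive upper bounds: value <= t_diploid goes to the
    diploid set, else <= t_tetraploid to the tetraploid set, else discarded.
    Undefined (NaN) Hind/He is discarded.  The three sets are disjoint and
    exhaustive.
    """
    values = hh.values if isinstance(hh, HindHeTable) else np.asarray(hh, dtype=float)
    defined = np.isfinite(values)
    diploid = defined & (values <= thresholds.t_diploid)
    tetraploid = defined & ~diploid & (values <= thresholds.t_tetraploid)
    discarded = ~(diploid | tetraploid)
    return {
        "diploid_set": np.flatnonzero(diploid),
        "tetraploid_set": np.flatnonzero(tetraploid),
        "discarded": np.flatnonzero(discarded),
    }


def coverage_filter(
    ds,
    min_prop_genotyped: float = 0.5,
    min_mean_depth: float = 20.0,
) -> tuple[np.ndarray, FilterReport]:
    """Keep loci genotyped in more than ``min_prop_genotyped`` of individuals
    at a mean per-genotyped-individual depth of at least ``min_mean_depth``."""
    depth = ds.total_depth
    n = ds.n_samples
    if n == 0 or ds.n_loci == 0:
        return np.empty(0, dtype=int), FilterReport("coverage", ds.n_loci, 0, ds.n_loci)
    genotyped = depth > 0
    prop = genotyped.sum(axis=0) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_depth = np.where(
            genotyped.any(axis=0),
            depth.sum(axis=0) / np.maximum(genotyped.sum(axis=0), 1),
            0.0,
        )
    keep = (prop > min_prop_genotyped) & (mean_depth >= min_mean_depth)
    report = FilterReport(
        rule="coverage",
        n_input=ds.n_loci,
        n_kept=int(keep.sum()),
        n_discarded=int((~keep).sum()),
        detail={
            "fail_prop": int((prop <= min_prop_genotyped).sum()),
            "fail_depth": int((mean_depth < min_mean_depth).sum()),
            "min_prop_genotyped": min_prop_genotyped,
            "min_mean_depth": min_mean_depth,
        },
    )
    return np.flatnonzero(keep), report
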