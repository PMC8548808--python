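"""Ploidy-aware per-locus and genome-wide differentiation statistics.

All measures here are functions of population allele frequencies only, which
is what makes them valid across ploidies: frequencies from a tetraploid sample
need no heterozygosity correction.  Gene diversity is Hs = 1 - sum(p_i^2);
differentiation is Nei's G_ST form F_ST = (Ht - mean Hs) / Ht with Ht the gene
diversity of the pooled (mean) frequency; Jost's D rescales the same
quantities by (1 - mean Hs) and the number of populations; absolute divergence
D_XY = p1(1-p2) + (1-p1)p2 is the probability that two alleles, one drawn from
each population, differ, averaged arithmetically across loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FreqEstimate",
    "population_frequencies",
    "gene_diversity",
    "fst",
    "jost_d",
    "dxy",
    "dxy_matrix",
    "gst_genomewide",
    "maf_filter",
    "drift_from_gst",
    "locus_stats_table",
]


@dataclass
class FreqEstimate:
    """Per-locus, per-population alternate-allele frequencies from dosage calls."""

    freqs: pd.DataFrame  # loci x populations
    n_chromosomes: pd.DataFrame  # loci x populations: sum of ploidies of genotyped samples

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)


def population_frequencies(gm, sample_meta: pd.DataFrame, locus_ids=None) -> FreqEstimate:
    """Allele frequencies as sum of MAP dosages over sum of ploidies, per population.

    Missing genotypes are excluded from both sums; a population with no
    genotyped individual at a locus gets NaN.
    """
    pops = list(dict.fromkeys(sample_meta["population"]))
    dosage = gm.dosage
    ploidy = np.asarray(gm.ploidy)
    freq_cols, chrom_cols = {}, {}
    for pop in pops:
        idx = np.flatnonzero((sample_meta["population"] == pop).to_numpy())
        d = dosage[idx]
        k = ploidy[idx][:, None]
        ok = d >= 0
        n_chrom = (ok * k).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, d, 0).sum(axis=0) / np.maximum(n_chrom, 1)
        freq_cols[pop] = np.where(n_chrom > 0, p, np.nan)
        chrom_cols[pop] = n_chrom
    index = list(locus_ids if locus_ids is not None else getattr(gm, "locus_ids", []))
    if not index:
        index = list(range(dosage.shape[1]))
    return FreqEstimate(
        freqs=pd.DataFrame(freq_cols, index=index),
        n_chromosomes=pd.DataFrame(chrom_cols, index=index),
    )


def gene_diversity(p) -> float | np.ndarray:
    """Hs = 1 - sum(p_i^2) for a frequency vector summing to 1.

    For convenience a scalar (or array) in [0, 1] is treated as the alternate
    frequency of a bi-allelic locus, giving 2p(1-p).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim >= 1 and p.shape[-1] > 1 and np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
        return 1.0 - (p**2).sum(axis=-1)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    return 1.0 - p**2 - (1.0 - p) ** 2


def _ht_hs(p: np.ndarray):
    """Ht (diversity of the mean frequency) and mean Hs along the population axis."""
    p = np.asarray(p, dtype=float)
    if p.ndim == 0 or p.shape[-1] < 2:
        raise ValueError("need frequencies from at least two populations")
    if not np.isfinite(p).all() or ((p < 0) | (p > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    pbar = p.mean(axis=-1)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * p * (1.0 - p)).mean(axis=-1)
    return ht, hs


def fst(p) -> float | np.ndarray:
    """Nei G_ST: (Ht - mean Hs) / Ht; NaN where Ht = 0 (monomorphic overall).

    ``p`` holds bi-allelic alternate frequencies with populations on the last
    axis; works element-wise across loci on the leading axes.
    """
    ht, hs = _ht_hs(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
    return float(out) if np.ndim(out) == 0 else out


def jost_d(p) -> float | np.ndarray:
    """Jost's D = [(Ht - mean Hs) / (1 - mean Hs)] * [n / (n - 1)]."""
    p = np.asarray(p, dtype=float)
    n = p.shape[-1]
    ht, hs = _ht_hs(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (ht - hs) / (1.0 - hs) * (n / (n - 1.0))
    return float(out) if np.ndim(out) == 0 else out


def dxy(p1, p2, genome_mean: bool = False):
    """Per-SNP absolute divergence p1(1-p2) + (1-p1)p2.

    With ``genome_mean=True`` returns the arithmetic mean across loci, skipping
    loci where either frequency is missing (NaN).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p1 * (1.0 - p2) + (1.0 - p1) * p2
    if genome_mean:
        return float(np.nanmean(d))
    return d


def dxy_matrix(freqs: pd.DataFrame, locus_subset=None) -> pd.DataFrame:
    """Symmetric matrix of mean per-SNP D_XY between all population pairs."""
    sub = freqs if locus_subset is None else freqs.iloc[locus_subset]
    if len(sub) == 0:
        raise ValueError("empty locus subset")
    pops = list(sub.columns)
    mat = np.zeros((len(pops), len(pops)))
    for i, a in enumerate(pops):
        for j in range(i + 1, len(pops)):
            mat[i, j] = mat[j, i] = dxy(
                sub[a].to_numpy(), sub[pops[j]].to_numpy(), genome_mean=True
            )
    return pd.DataFrame(mat, index=pops, columns=pops)


def gst_genomewide(p: np.ndarray) -> float:
    """Multi-locus G_ST as a ratio of means: (mean Ht - mean Hs) / mean Ht.

    The ratio-of-means form (sums over loci) is the standard multi-locus
    estimator; averaging per-locus ratios instead is downward-biased.
    """
    ht, hs = _ht_hs(np.asarray(p, dtype=float))
    ht_m = float(np.nanmean(ht))
    if ht_m == 0:
        raise ValueError("all loci monomorphic; G_ST undefined")
    return (ht_m - float(np.nanmean(hs))) / ht_m


def maf_filter(global_freqs: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Indices of loci whose global minor allele frequency strictly exceeds the threshold."""
    p = np.asarray(global_freqs, dtype=float)
    maf = np.minimum(p, 1.0 - p)
    return np.flatnonzero(np.isfinite(maf) & (maf > threshold))


def drift_from_gst(gst: float, n_pops: int = 2) -> float:
    """Invert the n-deme drift expectation E[G_ST] = F(1 - 1/n) / (1 - F/n).

    For populations drifted independently from a common ancestor with
    Balding-Nichols intensity F, G_ST underestimates F at small deme numbers
    (for two demes E[G_ST] = F / (2 - F)); this closed form recovers F.
    """
    return float(n_pops * gst / (n_pops - 1.0 + gst))


def locus_stats_table(
    freqs: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """One row per locus: per-population Hs, mean Hs, Ht, F_ST, Jost's D, MAF,
    and D_XY for each requested population pair."""
    p = freqs.to_numpy()
    pops = list(freqs.columns)
    out = {f"hs_{pop}": gene_diversity(freqs[pop].to_numpy()) for pop in pops}
    ht, hs = _ht_hs(p)
    out["hs_mean"] = hs
    out["ht"] = ht
    out["fst"] = fst(p)
    out["jost_d"] = jost_d(p)
    pbar = p.mean(axis=-1)
    out["maf"] = np.minimum(pbar, 1.0 - pbar)
    for a, b in pairs or []:
        out[f"dxy_{a}__{b}"] = dxy(freqs[a].to_numpy(), freqs[b].to_numpy())
        out[f"fst_{a}__{b}"] = fst(freqs[[a, b]].to_numpy())
    return pd.DataFrame(out, index=freqs.index)
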