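"""Four-taxon Patterson's D and f4-ratio admixture statistics.

Both statistics are computed from population allele frequencies (the natural
currency of dosage-called mixed-ploidy data).  For a quartet with assumed
topology (((P1, P2), P3), Outgroup) and per-population alternate frequencies
p1..p4,

    ABBA = (1 - p1) p2 p3 (1 - p4)
    BABA = p1 (1 - p2) p3 (1 - p4)
    D    = sum(ABBA - BABA) / sum(ABBA + BABA)

D is zero in expectation when the quartet is tree-consistent and drift is the
only force; an excess of shared-derived patterns between P2 and P3 (gene flow,
or shared ancestry the assumed topology omits) drives D positive, P1-P3
sharing drives it negative.  f4(A, B; C, D) is the across-locus mean of
(pA - pB)(pC - pD); ratios of two f4 statistics estimate admixture fractions.
Uncertainty comes from a delete-one block jackknife over contiguous locus
blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QuartetSpec", "DResult", "patterson_d", "f4", "f4_ratio", "block_jackknife"]


@dataclass(frozen=True)
class QuartetSpec:
    """Populations P1, P2, P3, Outgroup under assumed topology (((P1,P2),P3),P4)."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        if len({self.p1, self.p2, self.p3, self.outgroup}) != 4:
            raise ValueError("quartet populations must be distinct")

    @property
    def names(self) -> tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.outgroup)


@dataclass
class DResult:
    d: float
    se: float
    z: float
    n_loci: int
    n_blocks: int
    quartet: QuartetSpec | None = None
    f4: float | None = None


def block_jackknife(
    num: np.ndarray, den: np.ndarray | None = None, n_blocks: int = 50
) -> tuple[float, float, float]:
    """Delete-one-block jackknife for a ratio statistic sum(num)/sum(den).

    With ``den=None`` the statistic is the mean of ``num``.  Returns
    (estimate, SE, Z).  Blocks are contiguous index ranges; identical terms
    give SE = 0 (Z is inf for a nonzero estimate, 0 otherwise).
    """
    num = np.asarray(num, dtype=float)
    if den is None:
        den = np.ones_like(num)
    den = np.asarray(den, dtype=float)
    n = num.size
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if n < n_blocks:
        raise ValueError(f"need at least n_blocks={n_blocks} loci, got {n}")

    tot_num, tot_den = num.sum(), den.sum()
    if tot_den == 0:
        raise ValueError("denominator sums to zero over all loci")
    theta = tot_num / tot_den

    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    theta_j = np.empty(n_blocks)
    for j in range(n_blocks):
        s = slice(edges[j], edges[j + 1])
        dden = tot_den - den[s].sum()
        theta_j[j] = (tot_num - num[s].sum()) / dden if dden != 0 else theta
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((theta_j - theta_j.mean()) ** 2).sum()))
    if se == 0:
        z = 0.0 if theta == 0 else float(np.sign(theta) * np.inf)
    else:
        z = float(theta / se)
    return float(theta), se, z


def _freq_array(freqs: pd.DataFrame, names) -> np.ndarray:
    missing = [p for p in names if p not in freqs.columns]
    if missing:
        raise KeyError(f"populations not in frequency table: {missing}")
    arr = freqs[list(names)].to_numpy(dtype=float)
    return arr[np.isfinite(arr).all(axis=1)]


def patterson_d(
    freqs: pd.DataFrame, quartet: QuartetSpec, n_blocks: int = 50
) -> DResult:
    """Patterson's D with block-jackknife SE and Z for one quartet."""
    arr = _freq_array(freqs, quartet.names)
    if arr.shape[0] == 0:
        raise ValueError("no loci with defined frequencies in all four populations")
    p1, p2, p3, p4 = arr.T
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    num, den = abba - baba, abba + baba
    if den.sum() == 0:
        raise ValueError("ABBA+BABA is zero over all loci; D undefined")
    d, se, z = block_jackknife(num, den, n_blocks=n_blocks)
    f4_val = float(np.mean((p2 - p1) * (p3 - p4)))
    return DResult(
        d=d, se=se, z=z, n_loci=arr.shape[0], n_blocks=n_blocks, quartet=quartet, f4=f4_val
    )


def f4(freqs: pd.DataFrame, quartet: tuple[str, str, str, str]) -> np.ndarray:
    """Per-locus f4 terms (pA - pB)(pC - pD); mean across loci is the f4 statistic."""
    arr = _freq_array(freqs, quartet)
    pa, pb, pc, pd_ = arr.T
    return (pa - pb) * (pc - pd_)


def f4_ratio(
    freqs: pd.DataFrame,
    numerator: tuple[str, str, str, str],
    denominator: tuple[str, str, str, str],
    n_blocks: int = 50,
) -> DResult:
    """Ratio of two f4 statistics (an admixture-fraction estimate) with jackknife SE."""
    num = f4(freqs, numerator)
    den = f4(freqs, denominator)
    if num.size != den.size:
        raise ValueError("numerator and denominator quartets cover different loci")
    if den.sum() == 0:
        raise ValueError("denominator f4 is zero; ratio undefined")
    ratio, se, z = block_jackknife(num, den, n_blocks=min(n_blocks, max(2, num.size // 2)))
    return DResult(d=ratio, se=se, z=z, n_loci=num.size, n_blocks=min(n_blocks, num.size))
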