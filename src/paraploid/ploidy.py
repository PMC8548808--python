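"""Per-individual ploidy model selection from bi-allelic allele-balance spectra.

At a heterozygous site the fraction of reads carrying the alternate allele
clusters around dosage/ploidy: ~0.5 for a diploid AB genotype, ~1/3 and ~2/3
for triploids, ~0.25 / 0.5 / 0.75 for tetraploids.  For each candidate ploidy
``k`` we fit a Gaussian mixture whose component means are fixed at
``i/k, i = 1..k-1`` (shared variance, plus one uniform "noise" component that
absorbs mis-mapped or paralogous sites), and compare its log-likelihood against
a reference mixture whose component means are free.  The candidate whose fixed
model comes closest to the free fit — after a BIC-style penalty for the number
of fitted parameters, which prevents the nested tetraploid model (whose mean
set contains 0.5) from absorbing diploid data — is the selected ploidy.

Both the log-likelihood difference ``logL_fixed - logL_free`` and the ratio
``logL_fixed / logL_free`` (the conventional printed form) are reported for
every candidate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlleleBalanceSet",
    "MixtureFit",
    "PloidyCall",
    "extract_allele_balance",
    "fit_fixed_mixture",
    "fit_free_mixture",
    "select_ploidy",
]

VARIANCE_FLOOR = 1e-4
MAX_ITER = 500
TOL = 1e-6
MIN_SITES = 50  # below this the call is flagged low-confidence
CONFIDENCE_MARGIN = 2.0  # logL units separating the top two models
MAX_NOISE_WEIGHT = 0.3  # above this the fit is mostly noise, not a dosage mixture


@dataclass
class AlleleBalanceSet:
    """Alt-read fractions at putatively heterozygous sites of one individual."""

    individual: str
    values: np.ndarray
    n_sites_total: int
    n_sites_retained: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not ((self.values > 0) & (self.values < 1)).all():
            raise ValueError("allele balances must lie strictly in (0, 1)")
        if self.n_sites_retained > self.n_sites_total:
            raise ValueError("retained sites exceed total sites")

    @property
    def empty(self) -> bool:
        return self.values.size == 0


@dataclass
class MixtureFit:
    model: str  # e.g. "fixed_k4" or "free_3"
    means: np.ndarray
    weights: np.ndarray
    variance: float
    noise_weight: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)


@dataclass
class PloidyCall:
    individual: str
    selected: int
    loglik_free: float
    loglik_fixed: dict[int, float]
    diff: dict[int, float]  # logL_fixed - logL_free
    ratio: dict[int, float]  # logL_fixed / logL_free (printed form)
    score: dict[int, float]  # penalized difference used for selection
    confident: bool
    n_sites: int
    noise_weight: float = 0.0  # noise weight of the selected fixed fit


def extract_allele_balance(
    ds,
    individual: str,
    min_depth: int = 10,
    min_minor_reads: int = 3,
) -> AlleleBalanceSet:
    """Alt/(ref+alt) at sites passing depth and putative-heterozygote filters.

    Sites are retained when total depth >= ``min_depth`` and both alleles are
    seen in at least ``min_minor_reads`` reads; everything else (homozygotes,
    shallow sites) is dropped.
    """
    i = ds.sample_index(individual)
    r = ds.ref_depth[i].astype(float)
    a = ds.alt_depth[i].astype(float)
    n = r + a
    keep = (n >= min_depth) & (r >= min_minor_reads) & (a >= min_minor_reads)
    values = a[keep] / n[keep]
    return AlleleBalanceSet(
        individual=individual,
        values=values,
        n_sites_total=int(ds.n_loci),
        n_sites_retained=int(keep.sum()),
    )


def _em(
    x: np.ndarray,
    means: np.ndarray,
    fixed_means: bool,
    model: str,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> MixtureFit:
    """EM for a shared-variance Gaussian mixture plus a uniform noise component."""
    if x.size == 0:
        raise ValueError("empty allele-balance input")
    if not np.isfinite(x).all():
        raise ValueError("non-finite allele balances")
    n = x.size
    J = means.size
    means = means.astype(float).copy()
    weights = np.full(J, 0.95 / J)
    noise_w = 0.05
    var = 0.01

    # The uniform noise component keeps every site's total density bounded away
    # from zero, so densities can be handled on the natural scale (components
    # whose exponent underflows contribute exactly nothing).
    dx2 = (x[:, None] - means[None, :]) ** 2
    trace: list[float] = []
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        scale = weights / np.sqrt(2.0 * np.pi * var)
        p_comp = np.exp(dx2 * (-0.5 / var))
        p_comp *= scale[None, :]
        denom = p_comp.sum(axis=1) + noise_w  # Uniform(0,1) density = 1
        new_loglik = float(np.log(denom).sum())
        trace.append(new_loglik)

        p_comp /= denom[:, None]  # responsibilities
        nk = p_comp.sum(axis=0)
        weights = nk / n
        noise_w = 1.0 - float(weights.sum())
        if not fixed_means:
            means = np.where(
                nk > 1e-12, (p_comp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12), means
            )
            dx2 = (x[:, None] - means[None, :]) ** 2
        var = float((p_comp * dx2).sum() / max(nk.sum(), 1e-12))
        var = max(var, VARIANCE_FLOOR)

        if new_loglik - loglik < tol and it > 1:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    return MixtureFit(
        model=model,
        means=means,
        weights=weights,
        variance=var,
        noise_weight=noise_w,
        loglik=loglik,
        n_iter=it,
        converged=converged,
        loglik_trace=trace,
    )


def fit_fixed_mixture(balances: AlleleBalanceSet, k: int) -> MixtureFit:
    """Fit the fixed-ploidy mixture: component means pinned at i/k, i=1..k-1."""
    means = np.arange(1, k) / k
    return _em(balances.values, means, fixed_means=True, model=f"fixed_k{k}")


def fit_free_mixture(balances: AlleleBalanceSet, n_components: int = 3) -> MixtureFit:
    """Fit the free mixture: means initialised at evenly spaced data quantiles."""
    q = (np.arange(1, n_components + 1)) / (n_components + 1)
    means = np.quantile(balances.values, q)
    # Separate coincident initial means so components can de-collapse.
    means = means + np.linspace(-1e-3, 1e-3, n_components)
    return _em(balances.values, np.clip(means, 1e-3, 1 - 1e-3), fixed_means=False, model=f"free_{n_components}")


def select_ploidy(
    balances: AlleleBalanceSet,
    candidates: tuple[int, ...] = (2, 3, 4),
) -> PloidyCall:
    """Choose the ploidy whose fixed-mean mixture best matches the free fit.

    One free mixture with ``max(candidates) - 1`` components serves as the
    common reference.  Candidates are ranked by
    ``logL_fixed(k) - logL_free - 0.5 * (k + 1) * ln(n)``; the penalty counts
    the fixed model's fitted parameters (k-1 component weights, noise weight,
    shared variance) so that nested fixed models (the tetraploid mean set
    contains the diploid's 0.5) do not win on flexibility alone.
    """
    if balances.empty:
        raise ValueError(f"no retained sites for {balances.individual}")
    candidates = tuple(sorted(candidates))
    n = balances.values.size

    free = fit_free_mixture(balances, n_components=max(candidates) - 1)
    ll_fixed: dict[int, float] = {}
    diff: dict[int, float] = {}
    ratio: dict[int, float] = {}
    score: dict[int, float] = {}
    noise: dict[int, float] = {}
    for k in candidates:
        fit = fit_fixed_mixture(balances, k)
        ll_fixed[k] = fit.loglik
        diff[k] = fit.loglik - free.loglik
        ratio[k] = fit.loglik / free.loglik if free.loglik != 0 else np.nan
        score[k] = diff[k] - 0.5 * (k + 1) * np.log(n)
        noise[k] = fit.noise_weight

    ordered = sorted(candidates, key=lambda k: score[k], reverse=True)
    selected = ordered[0]
    margin = score[ordered[0]] - score[ordered[1]] if len(ordered) > 1 else np.inf
    # Low confidence when the ranking is tight, the site count is small, or the
    # winning fit explains the data mostly through its uniform noise component.
    confident = (
        margin >= CONFIDENCE_MARGIN
        and n >= MIN_SITES
        and noise[selected] < MAX_NOISE_WEIGHT
    )
    return PloidyCall(
        individual=balances.individual,
        selected=selected,
        loglik_free=free.loglik,
        loglik_fixed=ll_fixed,
        diff=diff,
        ratio=ratio,
        score=score,
        confident=confident,
        n_sites=n,
        noise_weight=noise[selected],
    )
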