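"""Locus-partitioned ancestry analysis and the scenario decision matrix.

The discriminating idea: if highland/lowland ecotype pairs replicated across
drainages arose by *independent emergence*, population trees built from any
subset of loci should group populations by drainage, and the loci under
divergent selection should differ between drainages.  If instead ecotypes
diverged first and later came into secondary contact, genome-wide gene flow
homogenises most loci (drainage-grouped trees) while the selected loci resist
introgression and retain the ecotype-grouped ("species-level") genealogy — and
the admixture leaves a detectable Patterson's D signal on the neutral
background.  Adaptive introgression or parallel selection on shared standing
variation also yield ecotype-grouped outlier trees, but without the
genome-wide admixture signal; at unlinked-SNP resolution these two remain
mutually confounded and are reported as one class.

Loci are partitioned two ways: by the ratio of heterospecific within-drainage
D_XY to conspecific-highland among-drainage D_XY, and by within-drainage
F_ST bins [0, 0.25), [0.25, 0.5), [0.5, 0.75), [0.75, 1].  Each partition gets
an unrooted neighbor-joining population tree on mean-D_XY distances, whose
induced quartet split over {highland_X, lowland_X, highland_Y, lowland_Y} is
classified as drainage-grouped or species-grouped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dstats import QuartetSpec, patterson_d
from .popstats import dxy, dxy_matrix, fst

__all__ = [
    "PopulationLayout",
    "PopTree",
    "TopologyCall",
    "ScenarioCall",
    "FST_BIN_EDGES",
    "dxy_ratio_table",
    "fst_bin_partition",
    "pop_distance_matrix",
    "nj_tree",
    "classify_topology",
    "gather_evidence",
    "classify_scenario",
]

FST_BIN_EDGES = (0.0, 0.25, 0.50, 0.75, 1.0)
ZERO_DENOM_EPS = 1e-6


@dataclass(frozen=True)
class PopulationLayout:
    """Drainage x ecotype naming scheme plus the outgroup."""

    drainages: tuple[str, ...] = ("D1", "D2")
    ecotypes: tuple[str, str] = ("highland", "lowland")
    outgroup: str | None = "outgroup"

    @classmethod
    def from_sample_meta(cls, meta: pd.DataFrame) -> "PopulationLayout":
        sub = meta[meta["drainage"] != ""]
        drainages = tuple(dict.fromkeys(sub["drainage"]))
        ecotypes = tuple(dict.fromkeys(sub["ecotype"]))
        out = meta.loc[meta["drainage"] == "", "population"]
        return cls(
            drainages=drainages,
            ecotypes=(ecotypes[0], ecotypes[1]),
            outgroup=out.iloc[0] if len(out) else None,
        )

    def highland(self, drainage: str) -> str:
        return f"{self.ecotypes[0]}_{drainage}"

    def lowland(self, drainage: str) -> str:
        return f"{self.ecotypes[1]}_{drainage}"

    @property
    def focal_populations(self) -> list[str]:
        return [f"{eco}_{dr}" for dr in self.drainages for eco in self.ecotypes]


@dataclass
class PopTree:
    """Unrooted population tree with branch lengths, from one locus partition."""

    tree: object  # skbio.TreeNode
    source_partition: str
    n_loci: int
    clamped_negative: bool = False

    @property
    def newick(self) -> str:
        return str(self.tree.write(None) if hasattr(self.tree, "write") else self.tree)


@dataclass
class TopologyCall:
    partition: str
    call: str  # drainage_grouped | species_grouped | other
    split: tuple[tuple[str, str], tuple[str, str]] | None
    n_loci: int


@dataclass
class ScenarioCall:
    label: str
    evidence: dict = field(default_factory=dict)
    reason: str = ""


def dxy_ratio_table(
    freqs: pd.DataFrame, layout: PopulationLayout, epsilon: float = ZERO_DENOM_EPS
) -> pd.DataFrame:
    """Per-locus D_XY ratios: heterospecific within-drainage over conspecific
    among-drainage divergence.

    ratio_X = D_XY(highland_X, lowland_X) / D_XY(highland_X, highland_Y).
    A ratio > 1 marks a locus where the ecotype pair stays more diverged than
    conspecific highland populations are from each other.  Loci whose
    denominator falls below ``epsilon`` are excluded (near-zero conspecific
    distances make the ratio unstable).  Label ``both_gt1`` requires every
    drainage's ratio to exceed 1.
    """
    if len(layout.drainages) < 2:
        raise ValueError("D_XY ratios need at least two drainages")
    h = [layout.highland(d) for d in layout.drainages]
    missing = [p for p in layout.focal_populations if p not in freqs.columns]
    if missing:
        raise KeyError(f"populations missing from frequency table: {missing}")
    out = pd.DataFrame(index=freqs.index)
    denom = dxy(freqs[h[0]].to_numpy(), freqs[h[1]].to_numpy())
    out["dxy_conspecific_highland"] = denom
    ok = denom >= epsilon
    for dr in layout.drainages:
        numer = dxy(
            freqs[layout.highland(dr)].to_numpy(), freqs[layout.lowland(dr)].to_numpy()
        )
        out[f"dxy_within_{dr}"] = numer
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"ratio_{dr}"] = np.where(ok, numer / np.where(ok, denom, 1.0), np.nan)
    ratios = out[[f"ratio_{dr}" for dr in layout.drainages]].to_numpy()
    label = np.where(
        ~ok, "excluded_zero_denominator", np.where((ratios > 1.0).all(axis=1), "both_gt1", "other")
    )
    out["label"] = label
    return out


def fst_bin_partition(fst_values: np.ndarray, edges=FST_BIN_EDGES) -> np.ndarray:
    """Bin index 1..4 per locus over half-open F_ST bins (top bin closed at 1);
    0 where F_ST is undefined."""
    v = np.asarray(fst_values, dtype=float)
    bins = np.zeros(v.size, dtype=int)
    defined = np.isfinite(v)
    idx = np.digitize(v[defined], edges[1:-1], right=False) + 1  # [0,.25)->1 ... [.75,...]->4
    bins[defined] = idx
    bins[defined & (v > edges[-1])] = 0  # out of range
    return bins


def pop_distance_matrix(freqs: pd.DataFrame, locus_subset=None) -> pd.DataFrame:
    """Pairwise mean per-SNP D_XY distance matrix (symmetric, zero diagonal).

    Note D_XY(p, p) = 2p(1-p) is not zero, so two populations with identical
    frequencies have equal — not zero — off-diagonal entries to everything
    else; the induced tree then carries a zero-length internal branch.
    """
    return dxy_matrix(freqs, locus_subset)


def nj_tree(dist: pd.DataFrame, source_partition: str = "", n_loci: int = 0) -> PopTree:
    """Neighbor joining on a symmetric non-negative distance matrix.

    Negative branch lengths (a standard NJ artefact) are clamped to zero and
    flagged.  Ties resolve deterministically (lowest index first).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    dm = DistanceMatrix(arr, ids=list(dist.columns))
    tree = _nj(dm, neg_as_zero=False)
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    return PopTree(
        tree=tree, source_partition=source_partition, n_loci=n_loci, clamped_negative=clamped
    )


def classify_topology(poptree: PopTree, layout: PopulationLayout) -> TopologyCall:
    """Classify the tree's induced split of the four focal populations.

    Restricting the tree to {highland_X, lowland_X, highland_Y, lowland_Y},
    the quartet split (hX, lX) | (hY, lY) is drainage-grouped and
    (hX, hY) | (lX, lY) is species-grouped (ecotypes cluster); the third
    pairing, and unresolved (tied) quartets, are ``other``.  The split is read
    from patristic distances via the four-point condition, which matches the
    pruned tree exactly for non-negative branch lengths.
    """
    if len(layout.drainages) != 2:
        raise ValueError("topology classification is defined for exactly two drainages")
    dX, dY = layout.drainages
    hx, lx = layout.highland(dX), layout.lowland(dX)
    hy, ly = layout.highland(dY), layout.lowland(dY)
    tree = poptree.tree
    tips = {t.name for t in tree.tips()}
    missing = {hx, lx, hy, ly} - tips
    if missing:
        raise KeyError(f"tree lacks focal populations: {sorted(missing)}")
    td = tree.tip_tip_distances(list({hx, lx, hy, ly}))

    def d(a, b):
        return float(td[a, b])

    s_drainage = d(hx, lx) + d(hy, ly)
    s_species = d(hx, hy) + d(lx, ly)
    s_cross = d(hx, ly) + d(hy, lx)
    sums = {"drainage_grouped": s_drainage, "species_grouped": s_species, "other": s_cross}
    ordered = sorted(sums.items(), key=lambda kv: kv[1])
    if np.isclose(ordered[0][1], ordered[1][1], rtol=0, atol=1e-12):
        call, split = "other", None
    else:
        call = ordered[0][0]
        split = {
            "drainage_grouped": ((hx, lx), (hy, ly)),
            "species_grouped": ((hx, hy), (lx, ly)),
            "other": ((hx, ly), (hy, lx)),
        }[call]
    return TopologyCall(
        partition=poptree.source_partition, call=call, split=split, n_loci=poptree.n_loci
    )


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def gather_evidence(
    freqs: pd.DataFrame,
    layout: PopulationLayout,
    min_loci: int = 25,
    n_blocks: int = 50,
) -> dict:
    """Assemble everything the scenario decision matrix consumes.

    Per drainage: per-locus within-pair F_ST, its four-bin partition, an NJ
    tree and topology call per populated bin, and the top-bin outlier locus
    set.  Genome-wide: Patterson's D on the non-outlier background for the
    cross-drainage quartets (lowland_X, highland_X; lowland_Y, outgroup) and
    its mirror — the lowland-clade test that fires only under a
    divergence-first history or admixture.  Plus, at each species-grouped top
    bin, the conspecific-highland D_XY against the within-drainage
    heterospecific D_XY (shared-ancestry check).
    """
    if len(layout.drainages) != 2:
        raise ValueError("evidence gathering is defined for exactly two drainages")
    dX, dY = layout.drainages
    focal = layout.focal_populations
    bad = [p for p in focal if p not in freqs.columns]
    if bad:
        raise KeyError(f"populations missing from frequency table: {bad}")

    evidence: dict = {
        "min_loci": min_loci,
        "topology": {},
        "bins": {},
        "n_loci": len(freqs),
        "drainages": list(layout.drainages),
    }
    outlier_sets: dict[str, set] = {}
    for dr in layout.drainages:
        pair = [layout.highland(dr), layout.lowland(dr)]
        pair_f = freqs[pair].to_numpy()
        ok = np.isfinite(pair_f).all(axis=1)
        fst_vals = np.full(len(freqs), np.nan)
        fst_vals[ok] = fst(pair_f[ok])
        bins = fst_bin_partition(fst_vals)
        evidence["bins"][dr] = bins
        outlier_sets[dr] = set(np.flatnonzero(bins == 4).tolist())
        for b in range(1, 5):
            idx = np.flatnonzero(bins == b)
            key = f"{dr}_bin{b}"
            if idx.size < min_loci:
                evidence["topology"][key] = None
                continue
            sub = freqs[focal].iloc[idx].dropna()
            dist = pop_distance_matrix(sub)
            call = classify_topology(nj_tree(dist, key, len(sub)), layout)
            evidence["topology"][key] = call

    evidence["outlier_sets"] = outlier_sets
    evidence["outlier_jaccard"] = _jaccard(outlier_sets[dX], outlier_sets[dY])

    # Genome-wide admixture test on the neutral background: loci in the lowest
    # F_ST bin of *both* drainage pairs.  Loci under (even partial) divergent
    # selection or locus-specific introgression sit in the elevated bins and
    # must not contaminate the genome-wide test.
    neutral = (evidence["bins"][dX] <= 1) & (evidence["bins"][dY] <= 1)
    background = freqs.iloc[np.flatnonzero(neutral)]
    evidence["n_background"] = int(neutral.sum())
    evidence["d_results"] = {}
    if layout.outgroup is not None and layout.outgroup in freqs.columns:
        quartets = [
            QuartetSpec(layout.lowland(dX), layout.highland(dX), layout.lowland(dY), layout.outgroup),
            QuartetSpec(layout.lowland(dY), layout.highland(dY), layout.lowland(dX), layout.outgroup),
        ]
        for q in quartets:
            try:
                res = patterson_d(background.dropna(), q, n_blocks=n_blocks)
            except ValueError:
                res = None
            evidence["d_results"]["|".join(q.names)] = res

    # Shared-ancestry check at species-grouped top bins.
    evidence["shared_ancestry"] = {}
    hX, hY = layout.highland(dX), layout.highland(dY)
    for dr in layout.drainages:
        call = evidence["topology"].get(f"{dr}_bin4")
        if call is None:
            continue
        idx = np.flatnonzero(evidence["bins"][dr] == 4)
        sub = freqs.iloc[idx]
        d_high = dxy(sub[hX].to_numpy(), sub[hY].to_numpy(), genome_mean=True)
        d_within = dxy(
            sub[layout.highland(dr)].to_numpy(),
            sub[layout.lowland(dr)].to_numpy(),
            genome_mean=True,
        )
        evidence["shared_ancestry"][dr] = {
            "dxy_conspecific_highland": d_high,
            "dxy_within_pair": d_within,
        }
    return evidence


def classify_scenario(
    evidence: dict,
    z_crit: float = 3.0,
    jaccard_max: float = 0.1,
    shared_ancestry_factor: float = 0.75,
    min_outliers: int = 5,
) -> ScenarioCall:
    """Apply the scenario decision matrix to gathered evidence.

    The matrix's "high-F_ST partition species-grouped" condition is applied in
    corroborated form: a top-bin species-grouped quartet call counts as shared
    highland ancestry only when conspecific highland populations are also
    markedly closer to each other at those loci than each is to its own
    lowland partner (mean D_XY(highland_X, highland_Y) at the bin at most
    ``shared_ancestry_factor`` times the within-drainage heterospecific D_XY).
    Outlier loci are nearly monomorphic in the unselected populations, so the
    raw quartet call alone is long-branch noise there; the D_XY ratio measures
    the same grouping robustly.

    1. Corroborated shared ancestry at a top bin, drainage-grouped low-F_ST
       background, and a significant genome-wide admixture test
       -> secondary_contact.
    2. Drainage-grouped background, essentially disjoint per-drainage outlier
       sets, and no corroborated shared ancestry -> de_novo_emergence.
    3. Corroborated shared ancestry without a genome-wide admixture signal
       -> standing_or_adaptive_introgression (confounded at unlinked-SNP
       resolution).
    4. Anything else -> inconclusive, with the failing component named.
    """
    topo = evidence.get("topology", {})
    available = {k: v for k, v in topo.items() if v is not None}
    if not available:
        return ScenarioCall("inconclusive", evidence, "no partition had enough loci")

    shared = evidence.get("shared_ancestry", {})
    corroborated: list[str] = []
    for dr in evidence.get("drainages", []):
        call = available.get(f"{dr}_bin4")
        sa = shared.get(dr)
        if (
            call is not None
            and call.call == "species_grouped"
            and sa is not None
            and sa["dxy_conspecific_highland"]
            <= shared_ancestry_factor * sa["dxy_within_pair"]
        ):
            corroborated.append(dr)

    low_calls = [v.call for k, v in available.items() if k.endswith("bin1")]
    low_drainage = bool(low_calls) and all(c == "drainage_grouped" for c in low_calls)

    d_results = [r for r in evidence.get("d_results", {}).values() if r is not None]
    if not d_results:
        return ScenarioCall("inconclusive", evidence, "admixture test unavailable")
    z_max = max(abs(r.z) for r in d_results)
    z_significant = z_max > z_crit

    summary = {
        "shared_ancestry_drainages": corroborated,
        "low_bin_drainage_grouped": low_drainage,
        "z_max": z_max,
        "outlier_jaccard": evidence.get("outlier_jaccard"),
    }
    evidence = {**evidence, "summary": summary}

    if corroborated and low_drainage and z_significant:
        return ScenarioCall("secondary_contact", evidence)

    outliers = evidence.get("outlier_sets", {})
    sets_ok = bool(outliers) and all(len(s) >= min_outliers for s in outliers.values())
    if (
        low_drainage
        and sets_ok
        and evidence["outlier_jaccard"] < jaccard_max
        and not corroborated
    ):
        return ScenarioCall("de_novo_emergence", evidence)

    if corroborated and not z_significant:
        return ScenarioCall("standing_or_adaptive_introgression", evidence)

    return ScenarioCall("inconclusive", evidence, "evidence pattern matches no scenario rule")
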