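"""Locus partitioning, NJ trees against a least-squares oracle, topology calls,
and the scenario decision matrix on hand-built evidence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from paraploid.dstats import DResult
from paraploid.partition import (
    PopulationLayout,
    TopologyCall,
    classify_scenario,
    classify_topology,
    dxy_ratio_table,
    fst_bin_partition,
    nj_tree,
    pop_distance_matrix,
)

LAYOUT = PopulationLayout()

TOPOLOGIES = {  # pair grouped with taxon 0, for taxa (0,1,2,3)
    (0, 1): [(0, 1), (2, 3)],
    (0, 2): [(0, 2), (1, 3)],
    (0, 3): [(0, 3), (1, 2)],
}


def ls_topology_oracle(dm: np.ndarray):
    """Exhaustive least-squares topology search over the 3 unrooted 4-taxon trees.

    Returns (best_pairing, residuals dict).  Branch order: 4 pendants + internal.
    """
    pairs = list(itertools.combinations(range(4), 2))
    results = {}
    for key, (g1, g2) in TOPOLOGIES.items():
        X = np.zeros((6, 5))
        for row, (i, j) in enumerate(pairs):
            X[row, i] = X[row, j] = 1
            same = {i, j} == set(g1) or {i, j} == set(g2)
            if not same:
                X[row, 4] = 1
        y = np.array([dm[i, j] for i, j in pairs])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = float(((X @ beta - y) ** 2).sum())
        results[key] = resid
    best = min(results, key=results.get)
    return best, results


def random_additive_matrix(rng):
    """Distance matrix of ((0,1),(2,3)) with random positive branch lengths."""
    a, b, c, d = rng.uniform(0.1, 2.0, 4)
    e = rng.uniform(0.1, 1.0)
    dm = np.zeros((4, 4))
    dm[0, 1] = dm[1, 0] = a + b
    dm[2, 3] = dm[3, 2] = c + d
    for i, x in [(0, a), (1, b)]:
        for j, y in [(2, c), (3, d)]:
            dm[i, j] = dm[j, i] = x + e + y
    return dm


def tree_split(poptree, names):
    """Which pair of names the tree's internal edge groups together."""
    td = poptree.tree.tip_tip_distances(names)
    sums = {
        (0, 1): td[names[0], names[1]] + td[names[2], names[3]],
        (0, 2): td[names[0], names[2]] + td[names[1], names[3]],
        (0, 3): td[names[0], names[3]] + td[names[1], names[2]],
    }
    return min(sums, key=sums.get)


def test_nj_matches_least_squares_oracle_on_additive_matrices():
    rng = np.random.default_rng(99)
    names = ["w", "x", "y", "z"]
    for rep in range(25):
        dm = random_additive_matrix(rng)
        perm = rng.permutation(4)
        dmp = dm[np.ix_(perm, perm)]
        tree = nj_tree(pd.DataFrame(dmp, index=names, columns=names))
        oracle_best, _ = ls_topology_oracle(dmp)
        assert tree_split(tree, names) == oracle_best
        # additive input: patristic distances reproduce the matrix exactly
        td = tree.tree.tip_tip_distances(names)
        for i, j in itertools.combinations(range(4), 2):
            assert td[names[i], names[j]] == pytest.approx(dmp[i, j], abs=1e-9)


def test_nj_known_tree_exact_branch_lengths():
    # ((A:1,B:2):1,(C:1,D:3)) -> d(A,B)=3, d(C,D)=4, d(A,C)=3, d(A,D)=5, ...
    dm = np.array(
        [[0, 3, 3, 5], [3, 0, 4, 6], [3, 4, 0, 4], [5, 6, 4, 0]], dtype=float
    )
    names = list("ABCD")
    tree = nj_tree(pd.DataFrame(dm, index=names, columns=names))
    assert tree_split(tree, names) == (0, 1)
    td = tree.tree.tip_tip_distances(names)
    assert td["A", "B"] == pytest.approx(3.0)
    assert td["C", "D"] == pytest.approx(4.0)
    assert td["A", "D"] == pytest.approx(5.0)


def test_nj_three_taxa_closed_form():
    dm = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    names = list("ABC")
    tree = nj_tree(pd.DataFrame(dm, index=names, columns=names))
    td = tree.tree.tip_tip_distances(names)
    # three-point formulas: a=(dAB+dAC-dBC)/2=1, b=2, c=3
    assert td["A", "B"] == pytest.approx(3.0)
    assert td["A", "C"] == pytest.approx(4.0)
    assert td["B", "C"] == pytest.approx(5.0)


def test_nj_zero_matrix_star_tree():
    dm = pd.DataFrame(np.zeros((4, 4)), index=list("ABCD"), columns=list("ABCD"))
    tree = nj_tree(dm)
    td = tree.tree.tip_tip_distances(list("ABCD"))
    assert max(td["A", "B"], td["A", "C"], td["C", "D"]) == pytest.approx(0.0)


def test_nj_rejects_asymmetric_and_tiny_input():
    bad = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], index=list("ABC"), columns=list("ABC"))
    with pytest.raises(ValueError):
        nj_tree(bad)
    with pytest.raises(ValueError):
        nj_tree(pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"]))


def _tree_from_freqs(freq_cols):
    freqs = pd.DataFrame(freq_cols)
    return nj_tree(pop_distance_matrix(freqs))


def test_classify_topology_drainage_and_species_and_other():
    pops = LAYOUT.focal_populations  # highland_D1, lowland_D1, highland_D2, lowland_D2
    rng = np.random.default_rng(2)
    base = rng.uniform(0.2, 0.8, 400)

    def jitter(shift):
        return np.clip(base + shift + rng.normal(0, 0.01, 400), 0, 1)

    drainage = {pops[0]: jitter(0.15), pops[1]: jitter(0.15) + 0.001,
                pops[2]: jitter(-0.15), pops[3]: jitter(-0.15) + 0.001}
    assert classify_topology(_tree_from_freqs(drainage), LAYOUT).call == "drainage_grouped"

    species = {pops[0]: jitter(0.15), pops[2]: jitter(0.15) + 0.001,
               pops[1]: jitter(-0.15), pops[3]: jitter(-0.15) + 0.001}
    assert classify_topology(_tree_from_freqs(species), LAYOUT).call == "species_grouped"

    cross = {pops[0]: jitter(0.15), pops[3]: jitter(0.15) + 0.001,
             pops[1]: jitter(-0.15), pops[2]: jitter(-0.15) + 0.001}
    assert classify_topology(_tree_from_freqs(cross), LAYOUT).call == "other"


def test_classify_topology_missing_population():
    freqs = pd.DataFrame({p: np.random.default_rng(0).uniform(0, 1, 50)
                          for p in LAYOUT.focal_populations[:3]})
    dist = pop_distance_matrix(freqs)
    with pytest.raises(KeyError):
        classify_topology(nj_tree(dist), LAYOUT)


def test_dxy_ratio_arithmetic_and_labels():
    from paraploid.popstats import dxy

    freqs = pd.DataFrame(
        {
            # locus 0: generic ratios, checked against direct arithmetic
            # locus 1: conspecific denominator 0 (all 0.5 -> dxy(h1,h2)=0.5, so
            #          use identical 0/0 pair) -> excluded
            # locus 2: ratio > 1 in one drainage only -> other
            "highland_D1": [0.1, 0.0, 0.1],
            "lowland_D1": [0.9, 0.3, 0.9],
            "highland_D2": [0.2, 0.0, 0.2],
            "lowland_D2": [0.5, 0.4, 0.05],
        }
    )
    tab = dxy_ratio_table(freqs, LAYOUT)
    num = dxy(0.1, 0.9)
    den = dxy(0.1, 0.2)
    assert tab["ratio_D1"].iloc[0] == pytest.approx(num / den)
    assert tab["label"].iloc[1] == "excluded_zero_denominator"
    r2 = tab[["ratio_D1", "ratio_D2"]].iloc[2]
    assert (r2 > 1).sum() == 1 and tab["label"].iloc[2] == "other"


def test_dxy_ratio_both_gt1_label():
    freqs = pd.DataFrame(
        {
            "highland_D1": [0.9],
            "lowland_D1": [0.1],
            "highland_D2": [0.85],
            "lowland_D2": [0.15],
        }
    )
    tab = dxy_ratio_table(freqs, LAYOUT)
    assert tab["label"].iloc[0] == "both_gt1"
    assert tab["ratio_D1"].iloc[0] > 1 and tab["ratio_D2"].iloc[0] > 1


def test_fst_bins_half_open_with_closed_top():
    bins = fst_bin_partition(np.array([0.0, 0.249, 0.25, 0.30, 0.49, 0.5, 0.749, 0.75, 1.0, np.nan]))
    assert list(bins) == [1, 1, 2, 2, 2, 3, 3, 4, 4, 0]


def make_evidence(topology, z, jaccard, shared, n_outliers=50):
    dres = DResult(d=0.1, se=0.01, z=z, n_loci=1000, n_blocks=50)
    return {
        "drainages": ["D1", "D2"],
        "topology": topology,
        "outlier_sets": {
            "D1": set(range(n_outliers)),
            "D2": set(range(0 if jaccard else n_outliers, n_outliers * 2 if not jaccard else n_outliers)),
        },
        "outlier_jaccard": jaccard,
        "d_results": {"q": dres},
        "shared_ancestry": shared,
        "bins": {},
    }


def tc(part, call):
    return TopologyCall(partition=part, call=call, split=None, n_loci=100)


def test_decision_matrix_secondary_contact():
    ev = make_evidence(
        {"D1_bin1": tc("D1_bin1", "drainage_grouped"), "D1_bin4": tc("D1_bin4", "species_grouped")},
        z=5.0, jaccard=0.9,
        shared={"D1": {"dxy_conspecific_highland": 0.05, "dxy_within_pair": 0.9}},
    )
    assert classify_scenario(ev).label == "secondary_contact"


def test_decision_matrix_de_novo():
    ev = make_evidence(
        {"D1_bin1": tc("D1_bin1", "drainage_grouped"), "D2_bin1": tc("D2_bin1", "drainage_grouped"),
         "D1_bin4": tc("D1_bin4", "drainage_grouped"), "D2_bin4": tc("D2_bin4", "drainage_grouped")},
        z=0.5, jaccard=0.0,
        shared={"D1": {"dxy_conspecific_highland": 0.85, "dxy_within_pair": 0.9}},
    )
    assert classify_scenario(ev).label == "de_novo_emergence"


def test_decision_matrix_standing_or_adaptive():
    ev = make_evidence(
        {"D1_bin1": tc("D1_bin1", "drainage_grouped"), "D1_bin4": tc("D1_bin4", "species_grouped")},
        z=1.0, jaccard=0.9,
        shared={"D1": {"dxy_conspecific_highland": 0.05, "dxy_within_pair": 0.9}},
    )
    assert classify_scenario(ev).label == "standing_or_adaptive_introgression"


def test_decision_matrix_missing_evidence_inconclusive():
    ev = make_evidence({"D1_bin1": tc("D1_bin1", "drainage_grouped")}, z=1.0, jaccard=0.9,
                       shared={})
    ev["d_results"] = {}
    call = classify_scenario(ev)
    assert call.label == "inconclusive" and call.reason


def test_decision_matrix_uncorroborated_species_call_not_shared_ancestry():
    """A species-grouped top bin without the D_XY corroboration must not trigger
    the shared-ancestry rules."""
    ev = make_evidence(
        {"D1_bin1": tc("D1_bin1", "drainage_grouped"), "D2_bin1": tc("D2_bin1", "drainage_grouped"),
         "D1_bin4": tc("D1_bin4", "species_grouped"), "D2_bin4": tc("D2_bin4", "drainage_grouped")},
        z=0.5, jaccard=0.0,
        shared={"D1": {"dxy_conspecific_highland": 0.85, "dxy_within_pair": 0.9}},
    )
    assert classify_scenario(ev).label == "de_novo_emergence"
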