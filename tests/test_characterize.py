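"""Count matrices, clustering, intersections, rank tests and the case
report."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

import foodcrust as fc
from foodcrust.io import EVIDENCE_COLUMNS


def _design(samples):
    return fc.validate_design(
        pd.DataFrame(
            {
                "sample_id": samples,
                "ingredient": ["T1"] * len(samples),
                "matrix": ["foodcrust"] * len(samples),
                "burial": ["unburied"] * len(samples),
                "replicate": list(range(1, len(samples) + 1)),
                "cofire_group": [""] * len(samples),
                "run_order": list(range(1, len(samples) + 1)),
            }
        )
    )


def _ev(rows):
    return pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS))


# --------------------------------------------------------------------------
# Count matrix
# --------------------------------------------------------------------------


def test_count_matrix_modes_and_conservation():
    ev = _ev(
        [
            ("S1", "AAAAAAK", (), ("P1",), "P1", 2),
            ("S1", "CCCCCCK", (), ("P1",), "P1", 3),
            ("S2", "DDDDDDK", (), ("P2",), "P2", 4),
        ]
    )
    design = _design(["S1", "S2"])
    psm = fc.count_matrix(ev, design, mode="psm_sum")
    assert psm.at["P1", "S1"] == 5
    assert psm.at["P1", "S2"] == 0
    assert psm.to_numpy().sum() == ev["psm_count"].sum()
    rows = fc.count_matrix(ev, design, mode="peptide_rows")
    assert rows.at["P1", "S1"] == 2
    assert rows.at["P2", "S2"] == 1


# --------------------------------------------------------------------------
# Hierarchical clustering
# --------------------------------------------------------------------------


def test_identical_columns_merge_first_at_zero():
    m = pd.DataFrame({"A": [1, 2], "B": [1, 2], "C": [9, 9]}, index=["p", "q"])
    d = fc.hierarchical_cluster(m)
    a, b, h, _ = d.merges[0]
    assert {a, b} == {"A", "B"}
    assert h == pytest.approx(0.0)


def test_three_sample_toy_matrix_merges_closest():
    m = pd.DataFrame({"S1": [0], "S2": [3], "S3": [4]}, index=["p"])
    d = fc.hierarchical_cluster(m, log_transform=False)
    a, b, h, _ = d.merges[0]
    assert {a, b} == {"S2", "S3"}
    assert h == pytest.approx(1.0)


def test_column_permutation_gives_isomorphic_dendrogram():
    rng = np.random.default_rng(2)
    m = pd.DataFrame(
        rng.integers(0, 50, size=(8, 5)),
        columns=list("ABCDE"),
        index=[f"p{i}" for i in range(8)],
    )
    d1 = fc.hierarchical_cluster(m)
    d2 = fc.hierarchical_cluster(m[["D", "B", "E", "A", "C"]])
    assert sorted(h for _, _, h, _ in d1.merges) == pytest.approx(
        sorted(h for _, _, h, _ in d2.merges)
    )
    assert set(d1.leaf_partitions()) == set(d2.leaf_partitions())


def test_merge_heights_monotone_and_scipy_agreement():
    """On tie-free random matrices the merge heights and leaf partitions
    match scipy's average-linkage clustering."""
    rng = np.random.default_rng(9)
    for _ in range(5):
        m = pd.DataFrame(
            rng.normal(size=(6, 7)),
            columns=[f"S{i}" for i in range(7)],
        )
        d = fc.hierarchical_cluster(m, log_transform=False)
        heights = [h for _, _, h, _ in d.merges]
        assert heights == sorted(heights)
        Z = sch.linkage(m.to_numpy().T, method="average", metric="euclidean")
        np.testing.assert_allclose(heights, Z[:, 2], rtol=1e-8)
        ours = {frozenset(p) for p in d.leaf_partitions()}
        labels = list(m.columns)
        theirs = set()
        members = {i: frozenset([labels[i]]) for i in range(7)}
        for k, (a, b, _, _) in enumerate(Z):
            merged = members[int(a)] | members[int(b)]
            members[7 + k] = merged
            theirs.add(merged)
        assert ours == theirs


def test_single_column_degenerate_tree():
    m = pd.DataFrame({"only": [1, 2, 3]})
    d = fc.hierarchical_cluster(m)
    assert d.merges == [] and d.labels == ["only"]
    assert d.to_newick() == "only;"


def test_newick_is_parseable():
    from io import StringIO

    from Bio import Phylo

    m = pd.DataFrame(
        np.arange(12).reshape(3, 4) % 5, columns=list("ABCD")
    )
    d = fc.hierarchical_cluster(m)
    tree = Phylo.read(StringIO(d.to_newick()), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == list("ABCD")


# --------------------------------------------------------------------------
# UpSet intersections
# --------------------------------------------------------------------------


def test_upset_hand_enumeration():
    rep = fc.upset_intersections({"A": {"p1", "p2"}, "B": {"p2"}})
    d = dict(zip(rep["combination"], rep["exclusive_count"]))
    assert d == {"A": 1, "B": 0, "A&B": 1}


def test_upset_partition_property_random_sets():
    rng = np.random.default_rng(4)
    for _ in range(20):
        sets = {
            name: set(rng.integers(0, 30, size=rng.integers(0, 25)))
            for name in "ABCD"
        }
        rep = fc.upset_intersections(sets)
        assert rep["exclusive_count"].sum() == len(set().union(*sets.values()))


def test_upset_matches_bitmask_oracle():
    rng = np.random.default_rng(8)
    sets = {
        name: set(rng.integers(0, 30, size=rng.integers(1, 30)))
        for name in "ABCD"
    }
    rep = fc.upset_intersections(sets)
    got = dict(zip(rep["combination"], rep["exclusive_count"]))
    names = sorted(sets)
    tally = {}
    for el in set().union(*sets.values()):
        mask = tuple(n for n in names if el in sets[n])
        tally[mask] = tally.get(mask, 0) + 1
    for r in range(1, 5):
        for combo in itertools.combinations(names, r):
            assert got["&".join(combo)] == tally.get(combo, 0)


# --------------------------------------------------------------------------
# Rank tests
# --------------------------------------------------------------------------


def test_wilcoxon_identical_groups_p_one():
    """Two identical groups show no shift: p = 1."""
    r = fc.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.p_value == pytest.approx(1.0)
    r2 = fc.wilcoxon_rank_sum([1.0, 4.0], [2.0, 3.0])
    assert r2.method == "exact"
    assert r2.p_value == pytest.approx(1.0)


def test_wilcoxon_hand_example_3v3():
    r = fc.wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert r.statistic == pytest.approx(6.0)  # smaller rank sum
    assert r.method == "exact"
    assert r.p_value == pytest.approx(0.1)  # 2/20, two-sided exhaustive


def _exact_p_oracle(x, y):
    """Exhaustive permutation distribution of the first group's rank sum."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


def test_exact_p_matches_enumeration_small_samples():
    rng = np.random.default_rng(12)
    for n1 in range(1, 6):
        for n2 in range(n1, 7):
            if n1 + n2 > 10:
                continue
            x = rng.normal(size=n1)
            y = rng.normal(size=n2) + rng.normal()
            r = fc.wilcoxon_rank_sum(x, y)
            assert r.method == "exact"
            assert r.p_value == pytest.approx(_exact_p_oracle(x, y), abs=1e-9)


def test_compare_states_runs_omnibus_then_pairs():
    groups = {
        "fresh": [0.1, 0.2, 0.3, 0.15],
        "foodcrust-unburied": [0.2, 0.25, 0.4, 0.35],
        "foodcrust-buried": [0.5, 0.6, 0.55, 0.45],
    }
    results = fc.compare_states(groups, property_name="gravy")
    assert results[0].test == "kruskal_wallis"
    assert len(results[0].groups) == 3
    pair_tests = [r for r in results if r.test == "wilcoxon_rank_sum"]
    assert [r.groups for r in pair_tests] == [
        ("fresh", "foodcrust-unburied"),
        ("foodcrust-unburied", "foodcrust-buried"),
    ]
    assert all(0 <= r.p_value <= 1 for r in results)


def test_compare_states_skips_empty_groups():
    groups = {"fresh": [1.0, 2.0], "buried": []}
    results = fc.compare_states(groups)
    assert any("skipped" in r.note for r in results)


# --------------------------------------------------------------------------
# Case report
# --------------------------------------------------------------------------


def test_case_report_coverage_additivity(small_reference):
    proteins, tree, ann = small_reference
    acc = next(iter(proteins))
    seq = proteins[acc].sequence
    peps = fc.digest(seq, 0, 7, 30)
    (p1, s1, _), (p2, s2, _) = peps[0], peps[1]
    samples = ["U1", "B1"]
    design = _design(samples)
    design.loc["B1", "burial"] = "buried"
    ev = _ev(
        [
            ("U1", p1, (), (acc,), acc, 2),
            ("U1", p2, (), (acc,), acc, 1),
            ("B1", p1, (), (acc,), acc, 3),
        ]
    )
    rep = fc.protein_case_report(acc, ev, design, proteins, ann)
    assert len(rep) == len(seq)
    cov_u = rep["coverage_unburied"].to_numpy()
    cov_b = rep["coverage_buried"].to_numpy()
    np.testing.assert_array_equal(cov_u[s1:s1 + len(p1)], 2)
    np.testing.assert_array_equal(cov_b[s1:s1 + len(p1)], 3)
    np.testing.assert_array_equal(cov_u[s2:s2 + len(p2)], 1)
    # conservation: total coverage mass equals sum(psm * length)
    assert cov_u.sum() + cov_b.sum() == 2 * len(p1) + 1 * len(p2) + 3 * len(p1)
    # per-residue hydropathy at window 1 is the raw scale value
    from foodcrust.properties import KYTE_DOOLITTLE

    assert rep["gravy_window"].iloc[0] == pytest.approx(KYTE_DOOLITTLE[seq[0]])


def test_case_report_absent_protein_errors(small_reference):
    proteins, _, ann = small_reference
    design = _design(["U1"])
    ev = _ev([("U1", "AAAAAAK", (), ("X",), "X", 1)])
    with pytest.raises(fc.FormatError):
        fc.protein_case_report("NOPE", ev, design, proteins, ann)
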