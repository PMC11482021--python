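"""Comparative outputs: count matrices, hierarchical clustering, set
intersections, state-wise rank tests and the per-protein case overlay.

The degradation analysis compares peptide/protein recovery across sample
states (fresh ingredient, cooked foodcrust, buried foodcrust, ceramic):
protein-by-sample count matrices feed average-linkage Euclidean
clustering; UpSet-style exclusive intersections show which proteins are
shared between states; Kruskal-Wallis and Wilcoxon rank-sum tests compare
per-peptide property distributions (GRAVY, length, pI, Tm, ...) between
states; and a per-residue case report overlays peptide coverage on a
single protein's property tracks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FormatError, ProteinRecord, ResidueAnnotationSet
from .properties import KYTE_DOOLITTLE, RSA_THRESHOLDS, map_peptide

# --------------------------------------------------------------------------
# Count matrices
# --------------------------------------------------------------------------


def count_matrix(
    evidence: pd.DataFrame,
    design: pd.DataFrame,
    mode: str = "psm_sum",
) -> pd.DataFrame:
    """Protein-by-sample peptide-count matrix.

    ``mode="psm_sum"`` sums spectral-match counts per (razor protein,
    sample) — the convention behind per-protein "peptide count" in
    abundance tables; ``mode="peptide_rows"`` counts distinct evidence
    rows instead.  Columns follow design (run) order; missing cells are 0.
    """
    if mode not in ("psm_sum", "peptide_rows"):
        raise FormatError(f"count_matrix: unknown mode {mode!r}")
    sample_order = [
        sid
        for sid in design.sort_values("run_order").index
        if design.at[sid, "matrix"] != "wash"
    ]
    if len(evidence):
        grouped = evidence.groupby(["leading_razor_protein", "sample_id"])
        cells = (
            grouped["psm_count"].sum()
            if mode == "psm_sum"
            else grouped.size()
        )
        matrix = cells.unstack(fill_value=0)
    else:
        matrix = pd.DataFrame()
    matrix = matrix.reindex(
        columns=sample_order, fill_value=0
    ).fillna(0).astype(int)
    matrix = matrix.sort_index()
    matrix.index.name = "protein"
    return matrix


# --------------------------------------------------------------------------
# Hierarchical clustering
# --------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` lists ``(left, right, height, size)`` where left/right are
    either leaf labels or earlier cluster ids ``"#<k>"``; heights are
    non-decreasing along every merge path for average linkage.
    """

    labels: list[str]
    merges: list[tuple[str, str, float, int]]

    def leaf_partitions(self) -> list[frozenset]:
        """Leaf sets of every internal node, for topology comparison."""
        members: dict[str, frozenset] = {l: frozenset([l]) for l in self.labels}
        out = []
        for k, (a, b, _, _) in enumerate(self.merges):
            merged = members[a] | members[b]
            members[f"#{k}"] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        node: dict[str, str] = {l: l for l in self.labels}
        height: dict[str, float] = {l: 0.0 for l in self.labels}
        for k, (a, b, h, _) in enumerate(self.merges):
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[f"#{k}"] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[f"#{k}"] = h
        if not self.merges:
            return f"{self.labels[0]};" if self.labels else ";"
        return node[f"#{len(self.merges) - 1}"] + ";"


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "average",
    axis: str = "columns",
    log_transform: bool = True,
) -> Dendrogram:
    """Agglomerative clustering of samples (columns) or proteins (rows).

    Distances are Euclidean (or correlation distance, ``1 - r``) on
    log2(x+1)-transformed counts by default — raw spectral counts are
    heavy-tailed and would otherwise let a handful of abundant proteins
    dominate the geometry.  Linkage is average (UPGMA) or complete or
    single.  At equal merge distance the pair whose (sorted) label pair is
    lexicographically smallest merges first, making the result
    deterministic.
    """
    if axis == "columns":
        data = matrix.to_numpy(dtype=float).T
        labels = [str(c) for c in matrix.columns]
    elif axis == "rows":
        data = matrix.to_numpy(dtype=float)
        labels = [str(r) for r in matrix.index]
    else:
        raise FormatError(f"hierarchical_cluster: unknown axis {axis!r}")
    if log_transform:
        data = np.log2(data + 1.0)

    n = len(labels)
    if n == 0:
        raise FormatError("hierarchical_cluster: empty matrix")
    if n == 1:
        return Dendrogram(labels=labels, merges=[])

    if metric == "euclidean":
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(data, metric="euclidean"))
    elif metric == "correlation":
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(data, metric="correlation"))
    else:
        raise FormatError(f"hierarchical_cluster: unknown metric {metric!r}")

    if linkage not in ("average", "complete", "single"):
        raise FormatError(f"hierarchical_cluster: unknown linkage {linkage!r}")

    # Lance-Williams agglomeration with the documented deterministic
    # tie-break: among minimum-distance pairs, merge the one whose sorted
    # label pair sorts first.
    active: dict[str, np.ndarray | None] = {}
    ids = list(labels)
    sizes = {l: 1 for l in labels}
    d = {
        (ids[i], ids[j]): dist[i, j]
        for i in range(n)
        for j in range(i + 1, n)
    }
    merges: list[tuple[str, str, float, int]] = []
    next_id = 0
    current = set(ids)
    while len(current) > 1:
        best = min(
            d.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0])))
        )
        (a, b), h = best
        a, b = sorted((a, b))
        new = f"#{next_id}"
        next_id += 1
        size = sizes[a] + sizes[b]
        merges.append((a, b, float(h), size))
        for other in current - {a, b}:
            dab = lambda x, y: d[(x, y)] if (x, y) in d else d[(y, x)]
            da, db = dab(a, other), dab(b, other)
            if linkage == "average":
                nd = (sizes[a] * da + sizes[b] * db) / size
            elif linkage == "complete":
                nd = max(da, db)
            else:
                nd = min(da, db)
            d[(new, other)] = nd
        for key in [k for k in d if a in k or b in k]:
            del d[key]
        current -= {a, b}
        current.add(new)
        sizes[new] = size
    return Dendrogram(labels=labels, merges=merges)


# --------------------------------------------------------------------------
# UpSet-style intersections
# --------------------------------------------------------------------------


def upset_intersections(named_sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive membership counts for every non-empty set combination.

    Each element of the union belongs to exactly one combination (the
    full set of names containing it), so exclusive counts over all
    combinations partition the union.  Rows are sorted by descending
    count then by combination label.
    """
    if not named_sets:
        raise FormatError("upset_intersections: at least one named set required")
    names = sorted(named_sets)
    membership: dict = {}
    for el in set().union(*named_sets.values()):
        combo = tuple(n for n in names if el in named_sets[n])
        membership.setdefault(combo, []).append(el)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            members = sorted(map(str, membership.get(combo, [])))
            rows.append(("&".join(combo), len(combo), len(members), ";".join(members)))
    out = pd.DataFrame(
        rows, columns=["combination", "degree", "exclusive_count", "members"]
    )
    return out.sort_values(
        ["exclusive_count", "combination"], ascending=[False, True]
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# State comparisons (rank tests)
# --------------------------------------------------------------------------


@dataclass
class TestResult:
    """One omnibus or pairwise nonparametric comparison."""

    test: str  # "kruskal_wallis" | "wilcoxon_rank_sum"
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str = ""  # "exact" | "asymptotic" | ""
    note: str = ""


def _rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """The smaller of the two group rank sums (reported statistic)."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    w1 = float(ranks[: len(x)].sum())
    w2 = float(ranks[len(x):].sum())
    return min(w1, w2)


def wilcoxon_rank_sum(
    x, y, groups: tuple[str, str] = ("x", "y"), exact_max_n: int = 20
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact small-sample p-values when the combined sample size is at most
    ``exact_max_n`` and the data are tie-free; the normal approximation
    with tie correction otherwise.  The reported statistic is the smaller
    of the two group rank sums.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise FormatError("wilcoxon_rank_sum: empty group")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= exact_max_n and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return TestResult(
        test="wilcoxon_rank_sum",
        groups=groups,
        statistic=_rank_sum_statistic(x, y),
        p_value=float(min(res.pvalue, 1.0)),
        n=(len(x), len(y)),
        method=method,
    )


def compare_states(
    groups: dict[str, "pd.Series | np.ndarray | list"],
    property_name: str = "",
    pairs: list[tuple[str, str]] | None = None,
    exact_max_n: int = 20,
) -> list[TestResult]:
    """Omnibus and pairwise comparisons of one property across states.

    ``groups`` maps state label (e.g. ``fresh``, ``foodcrust-unburied``,
    ``foodcrust-buried``) to that state's per-peptide property values.
    Runs one Kruskal-Wallis across all non-empty states, then a two-sided
    Wilcoxon rank-sum test for each designated pair (default: consecutive
    states in the given order, the fresh-vs-cooked and unburied-vs-buried
    contrasts).  Pairs with an empty side are skipped with a note.
    """
    cleaned = {
        k: np.asarray(pd.Series(v).dropna(), dtype=float) for k, v in groups.items()
    }
    results: list[TestResult] = []
    nonempty = {k: v for k, v in cleaned.items() if len(v) > 0}
    if len(nonempty) >= 2:
        stat, p = sps.kruskal(*nonempty.values())
        results.append(
            TestResult(
                test="kruskal_wallis",
                groups=tuple(nonempty),
                statistic=float(stat),
                p_value=float(p),
                n=tuple(len(v) for v in nonempty.values()),
                note=property_name,
            )
        )
    keys = list(cleaned)
    if pairs is None:
        pairs = list(zip(keys[:-1], keys[1:]))
    for a, b in pairs:
        if len(cleaned[a]) == 0 or len(cleaned[b]) == 0:
            results.append(
                TestResult(
                    test="wilcoxon_rank_sum",
                    groups=(a, b),
                    statistic=float("nan"),
                    p_value=float("nan"),
                    n=(len(cleaned[a]), len(cleaned[b])),
                    note=f"{property_name}: skipped, empty group",
                )
            )
            continue
        r = wilcoxon_rank_sum(cleaned[a], cleaned[b], (a, b), exact_max_n)
        r.note = property_name
        results.append(r)
    return results


def tests_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.test,
                " vs ".join(r.groups),
                r.statistic,
                r.p_value,
                ",".join(map(str, r.n)),
                r.method,
                r.note,
            )
            for r in results
        ],
        columns=["test", "groups", "statistic", "p_value", "n", "method", "note"],
    )


# --------------------------------------------------------------------------
# Per-protein case report
# --------------------------------------------------------------------------


def protein_case_report(
    accession: str,
    evidence: pd.DataFrame,
    design: pd.DataFrame,
    proteins: dict[str, ProteinRecord],
    annotations: ResidueAnnotationSet,
    states: tuple[str, ...] = ("unburied", "buried"),
    window: int = 1,
    rsa_thresholds: tuple[float, float] = RSA_THRESHOLDS,
) -> pd.DataFrame:
    """Residue-resolved coverage and property overlay for one protein.

    For each residue position: summed PSM counts of all peptides (razor
    protein = ``accession``) overlapping the position, split by burial
    state; the local Kyte-Doolittle hydropathy averaged over a centred
    ``window``; and the annotation tracks (amyloid, secondary structure,
    RSA class).  The per-state columns are named ``coverage_<state>``.
    """
    if accession not in proteins:
        raise FormatError(f"protein_case_report: unknown accession {accession!r}")
    protein = proteins[accession]
    length = len(protein.sequence)
    rows = evidence[evidence["leading_razor_protein"] == accession]
    if len(rows) == 0:
        raise FormatError(
            f"protein_case_report: no evidence rows for {accession!r}"
        )
    burial_of = design["burial"].to_dict()
    matrix_of = design["matrix"].to_dict()

    coverage = {s: np.zeros(length, dtype=int) for s in states}
    for row in rows.itertuples(index=False):
        sid = row.sample_id
        if matrix_of.get(sid) == "wash":
            continue
        state = burial_of.get(sid)
        if state not in coverage:
            continue
        start, end = map_peptide(row.sequence, protein)
        coverage[state][start:end] += row.psm_count

    kd = np.array([KYTE_DOOLITTLE[ch] for ch in protein.sequence])
    half = max(window // 2, 0)
    local_gravy = np.array(
        [kd[max(0, i - half): i + half + 1].mean() for i in range(length)]
    )

    ann = annotations.get(accession)
    low, high = rsa_thresholds
    out = pd.DataFrame({"position": np.arange(length), "residue": list(protein.sequence)})
    for s in states:
        out[f"coverage_{s}"] = coverage[s]
    out["gravy_window"] = local_gravy
    if ann is not None:
        out["amyloid"] = ann.amyloid
        out["ss8"] = list(ann.ss8)
        out["rsa_class"] = [
            "deep" if r < low else ("exposed" if r > high else "intermediate")
            for r in ann.rsa
        ]
    return out
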