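"""The identification-filtering ledger.

Post-search evidence tables carry rows that must not reach the
characterisation stage: peptides too short or with too many missed
cleavages to have passed a credible search, peptides explainable by
common laboratory contaminants (cRAP-style keratins, trypsin, BSA),
machine carry-over detected via the blank wash preceding each injection,
and whole samples whose field cross-contamination exceeds the inclusion
threshold.  The stages compose in a fixed, documented order:

    search filters -> contaminant removal -> carry-over ->
    cross-contamination exclusion -> protein support

Every stage is contractive (output rows are a subset of input rows) and
idempotent; each records rows in/out and per-reason removal counts in a
:class:`FilterReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Mapping

import pandas as pd

from .io import FormatError, ProteinRecord, equate_il

PIPELINE_ORDER = (
    "search_filters",
    "contaminant_removal",
    "carryover",
    "crosscontam_exclusion",
    "protein_support",
)


@dataclass
class FilterStage:
    """Row accounting for one filter stage."""

    name: str
    n_in: int
    n_out: int
    removed: dict[str, int] = dataclass_field(default_factory=dict)
    notes: list[str] = dataclass_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - sum(self.removed.values()):
            raise ValueError(
                f"stage {self.name}: rows out ({self.n_out}) != rows in "
                f"({self.n_in}) - rows removed ({sum(self.removed.values())})"
            )


@dataclass
class FilterReport:
    """Composable record of what each stage did.

    ``sample_stats`` (filled by the cross-contamination stage) holds the
    per-sample cross-contaminant peptide percentage and inclusion flag.
    """

    stages: list[FilterStage] = dataclass_field(default_factory=list)
    sample_stats: pd.DataFrame | None = None
    order: tuple[str, ...] = PIPELINE_ORDER

    def extend(self, other: "FilterReport") -> "FilterReport":
        self.stages.extend(other.stages)
        if other.sample_stats is not None:
            self.sample_stats = other.sample_stats
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            if s.removed:
                for reason, n in sorted(s.removed.items()):
                    rows.append((s.name, s.n_in, s.n_out, reason, n))
            else:
                rows.append((s.name, s.n_in, s.n_out, "", 0))
        return pd.DataFrame(
            rows, columns=["stage", "rows_in", "rows_out", "reason", "removed"]
        )


# --------------------------------------------------------------------------
# Search-criteria filters
# --------------------------------------------------------------------------


def count_missed_cleavages(sequence: str) -> int:
    """Number of internal K/R positions not followed by P.

    The terminal residue is excluded: a C-terminal K or R is the cleavage
    that produced the peptide, not a missed one.
    """
    if not sequence:
        raise FormatError("count_missed_cleavages: empty sequence")
    from .io import AMINO_ACIDS

    for ch in sequence:
        if ch not in AMINO_ACIDS:
            raise FormatError(
                f"count_missed_cleavages: non-canonical residue {ch!r}"
            )
    return sum(
        1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    )


def apply_search_filters(
    evidence: pd.DataFrame, min_len: int = 7, max_missed: int = 2
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain rows with length >= ``min_len`` and <= ``max_missed`` missed
    cleavages (the search-parameter envelope)."""
    n_in = len(evidence)
    removed: dict[str, int] = {}
    if n_in == 0:
        out = evidence.copy()
    else:
        length_ok = evidence["sequence"].str.len() >= min_len
        missed_ok = evidence["sequence"].map(count_missed_cleavages) <= max_missed
        n_short = int((~length_ok).sum())
        n_missed = int((length_ok & ~missed_ok).sum())
        if n_short:
            removed["too_short"] = n_short
        if n_missed:
            removed["too_many_missed_cleavages"] = n_missed
        out = evidence[length_ok & missed_ok].copy()
    report = FilterReport(
        stages=[FilterStage("search_filters", n_in, len(out), removed)]
    )
    return out, report


# --------------------------------------------------------------------------
# Contaminant removal
# --------------------------------------------------------------------------


def _occurs_in_any(sequence: str, haystack: str) -> bool:
    return equate_il(sequence) in haystack


def _concatenate(proteins: Mapping[str, ProteinRecord], category: str | None = None,
                 taxon: str | None = None) -> str:
    """I/L-equated concatenation of selected protein sequences, separated
    by a non-residue sentinel so peptides cannot span two proteins."""
    parts = [
        equate_il(p.sequence)
        for p in proteins.values()
        if (category is None or p.category == category)
        and (taxon is None or p.taxon_id == taxon)
    ]
    return "|".join(parts)


def remove_contaminants(
    evidence: pd.DataFrame, proteins: Mapping[str, ProteinRecord]
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove rows whose sequence occurs in any contaminant database entry.

    Matching is I/L-equated substring occurrence.  Peptides shared between
    a contaminant and a target protein are removed too — the conservative
    reading, since such rows cannot be distinguished from contamination.
    """
    n_in = len(evidence)
    haystack = _concatenate(proteins, category="contaminant")
    if n_in == 0 or not haystack:
        out = evidence.copy()
        removed: dict[str, int] = {}
    else:
        hit_cache: dict[str, bool] = {}

        def _is_contam(seq: str) -> bool:
            if seq not in hit_cache:
                hit_cache[seq] = _occurs_in_any(seq, haystack)
            return hit_cache[seq]

        mask = evidence["sequence"].map(_is_contam)
        removed = {"contaminant_match": int(mask.sum())} if mask.any() else {}
        out = evidence[~mask].copy()
    report = FilterReport(
        stages=[FilterStage("contaminant_removal", n_in, len(out), removed)]
    )
    return out, report


# --------------------------------------------------------------------------
# Machine carry-over
# --------------------------------------------------------------------------


def carryover_filter(
    evidence: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove from each sample any peptide observed in the blank wash
    immediately preceding it in the injection sequence.

    Matching is exact-sequence within the wash.  Samples with no preceding
    wash are passed through unchanged (noted in the report).  Wash rows
    themselves are never removed here.
    """
    n_in = len(evidence)
    notes: list[str] = []
    if n_in == 0:
        report = FilterReport(stages=[FilterStage("carryover", 0, 0, {})])
        return evidence.copy(), report

    ordered = design.sort_values("run_order")
    wash_before: dict[str, str | None] = {}
    last_wash: str | None = None
    for sid, row in ordered.iterrows():
        if row["matrix"] == "wash":
            last_wash = sid
        else:
            wash_before[sid] = last_wash

    wash_peptides: dict[str, set[str]] = {}
    for wash_id in set(w for w in wash_before.values() if w):
        wash_peptides[wash_id] = set(
            evidence.loc[evidence["sample_id"] == wash_id, "sequence"]
        )

    drop = pd.Series(False, index=evidence.index)
    for sid, wash_id in wash_before.items():
        if wash_id is None:
            notes.append(f"sample {sid}: no preceding wash, carry-over not assessed")
            continue
        in_sample = evidence["sample_id"] == sid
        drop |= in_sample & evidence["sequence"].isin(wash_peptides[wash_id])
    removed = {"carryover_match": int(drop.sum())} if drop.any() else {}
    out = evidence[~drop].copy()
    report = FilterReport(
        stages=[FilterStage("carryover", n_in, len(out), removed, notes)]
    )
    return out, report


# --------------------------------------------------------------------------
# Field cross-contamination sample exclusion
# --------------------------------------------------------------------------


def crosscontam_exclude(
    evidence: pd.DataFrame,
    design: pd.DataFrame,
    proteins: Mapping[str, ProteinRecord],
    threshold_percent: float = 2.0,
) -> tuple[set[str], FilterReport]:
    """Decide sample inclusion from known cross-contaminant load.

    A peptide row is a *known* cross-contaminant if its sequence occurs
    (I/L-equated) in a co-fired partner's ingredient proteome and not in
    the sample's own; peptides present in both proteomes are ambiguous and
    not counted.  A sample is excluded from property characterisation if
    known cross-contaminants exceed ``threshold_percent`` of its peptide
    rows (the boundary is inclusive: exactly at threshold is kept).
    Samples outside any co-firing group score zero.  Washes are not
    assessed.
    """
    taxa = sorted(
        {p.taxon_id for p in proteins.values() if p.category == "target"}
    )
    haystacks = {t: _concatenate(proteins, category="target", taxon=t) for t in taxa}
    members_by_group: dict[str, list[str]] = {}
    for sid, row in design.iterrows():
        if row["cofire_group"] and row["matrix"] != "wash":
            members_by_group.setdefault(row["cofire_group"], []).append(sid)

    stats = []
    included: set[str] = set()
    for sid, row in design.iterrows():
        if row["matrix"] == "wash":
            continue
        rows = evidence[evidence["sample_id"] == sid]
        own = row["ingredient"]
        partners = sorted(
            {
                design.at[other, "ingredient"]
                for other in members_by_group.get(row["cofire_group"], [])
                if design.at[other, "ingredient"] not in ("", own)
            }
        )
        n_total = len(rows)
        n_cross = 0
        if partners and n_total:
            own_hay = haystacks.get(own, "")
            for seq in rows["sequence"]:
                if _occurs_in_any(seq, own_hay):
                    continue
                if any(_occurs_in_any(seq, haystacks[p]) for p in partners):
                    n_cross += 1
        percent = 100.0 * n_cross / n_total if n_total else 0.0
        keep = percent <= threshold_percent
        if keep:
            included.add(sid)
        stats.append((sid, n_total, n_cross, percent, keep))

    sample_stats = pd.DataFrame(
        stats,
        columns=["sample_id", "n_peptides", "n_crosscontaminant",
                 "crosscontam_percent", "included"],
    ).set_index("sample_id")
    n_in = len(evidence)
    report = FilterReport(
        stages=[FilterStage("crosscontam_exclusion", n_in, n_in, {})],
        sample_stats=sample_stats,
    )
    return included, report


# --------------------------------------------------------------------------
# Protein-level support
# --------------------------------------------------------------------------


def protein_support_filter(
    evidence: pd.DataFrame, min_psm: int = 2
) -> tuple[dict[str, set[str]], FilterReport]:
    """Per sample, retain proteins with at least ``min_psm`` summed PSMs.

    Rows are grouped by leading razor protein within each sample; proteins
    whose summed spectral-match count falls below the threshold are
    dropped from that sample's protein set.  The default ``min_psm=2``
    implements "more than one PSM"; pass 3 for the stricter
    "greater than two PSMs" convention.
    """
    n_in = len(evidence)
    retained: dict[str, set[str]] = {}
    n_dropped = 0
    if n_in:
        sums = evidence.groupby(
            ["sample_id", "leading_razor_protein"], sort=True
        )["psm_count"].sum()
        for (sid, protein), total in sums.items():
            if total >= min_psm:
                retained.setdefault(sid, set()).add(protein)
            else:
                n_dropped += 1
    report = FilterReport(
        stages=[
            FilterStage(
                "protein_support",
                n_in,
                n_in,
                {},
                [f"proteins dropped below {min_psm} summed PSMs: {n_dropped}"],
            )
        ]
    )
    return retained, report


# --------------------------------------------------------------------------
# The composed pipeline
# --------------------------------------------------------------------------


def run_filter_pipeline(
    evidence: pd.DataFrame,
    design: pd.DataFrame,
    proteins: Mapping[str, ProteinRecord],
    min_len: int = 7,
    max_missed: int = 2,
    min_psm: int = 2,
    crosscontam_threshold: float = 2.0,
    drop_excluded_samples: bool = True,
) -> tuple[pd.DataFrame, dict[str, set[str]], FilterReport]:
    """Apply every filter stage in the documented order.

    Returns the surviving evidence rows, the per-sample supported protein
    sets, and the combined report.  When ``drop_excluded_samples`` is
    true, rows of samples failing the cross-contamination threshold are
    removed from the returned evidence (they remain counted in
    ``report.sample_stats``); wash rows are always dropped from the final
    table since they exist only to drive the carry-over filter.
    """
    report = FilterReport(stages=[])
    out, r = apply_search_filters(evidence, min_len, max_missed)
    report.extend(r)
    out, r = remove_contaminants(out, proteins)
    report.extend(r)
    out, r = carryover_filter(out, design)
    report.extend(r)
    included, r = crosscontam_exclude(out, design, proteins, crosscontam_threshold)
    report.extend(r)
    wash_ids = set(design.index[design["matrix"] == "wash"])
    keep_ids = included if drop_excluded_samples else set(design.index) - wash_ids
    mask = out["sample_id"].isin(keep_ids - wash_ids)
    n_in = len(out)
    out = out[mask].copy()
    report.stages.append(
        FilterStage(
            "sample_selection",
            n_in,
            len(out),
            {"excluded_sample_or_wash": n_in - len(out)}
            if n_in - len(out)
            else {},
        )
    )
    proteins_kept, r = protein_support_filter(out, min_psm)
    report.extend(r)
    return out, proteins_kept, report
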