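"""Readers, writers and the shared data model.

Every external format the pipeline touches is defined here: reference
proteomes (FASTA plus a sidecar taxon/category table), post-search peptide
evidence tables (TSV), taxonomies (TSV), per-residue annotation tracks
(TSV) and the sample-design table (TSV).

Conventions, stated once and used everywhere:

* residue positions are zero-based; intervals are half-open ``[start, end)``;
* amino-acid sequences are upper-case strings over the 20 canonical letters;
* evidence collections are :class:`pandas.DataFrame` objects with the
  columns listed under :data:`EVIDENCE_COLUMNS`; ``modifications`` holds a
  tuple of ``(type, position)`` pairs and ``protein_ids`` a tuple of
  accessions;
* all written files carry a header line and are byte-stable for a fixed
  input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# --------------------------------------------------------------------------
# Alphabets and controlled vocabularies
# --------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

SS8_CLASSES = "GHIEBTSL"  # 310/alpha/pi helix, strand, bridge, turn, bend, coil
_SS8_SET = frozenset(SS8_CLASSES)

#: Modification types and the residues they are compatible with.  ``None``
#: means the modification anchors to the protein/peptide N-terminus
#: (position 0) rather than a specific residue letter.
MODIFICATION_RESIDUES: dict[str, str | None] = {
    "oxidation_M": "M",
    "acetyl_protein_Nterm": None,
    "deamidation_NQ": "NQ",
    "gln_to_pyroglu": "Q",
    "carbamidomethyl_C": "C",
}

#: Search-engine-style spelling of each modification type, used in the
#: evidence TSV dialect ("<Name>@<zero-based position>").
MODIFICATION_NAMES: dict[str, str] = {
    "oxidation_M": "Oxidation (M)",
    "acetyl_protein_Nterm": "Acetyl (Protein N-term)",
    "deamidation_NQ": "Deamidation (NQ)",
    "gln_to_pyroglu": "Gln->pyro-Glu",
    "carbamidomethyl_C": "Carbamidomethyl (C)",
}
_NAME_TO_TYPE = {v: k for k, v in MODIFICATION_NAMES.items()}
# accept the canonical identifiers too
_NAME_TO_TYPE.update({k: k for k in MODIFICATION_RESIDUES})

PROTEIN_CATEGORIES = ("target", "contaminant")
MATRICES = ("fresh", "foodcrust", "ceramic", "wash")
BURIALS = ("unburied", "buried")

RANKS = (
    "root",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "subspecies",
)
RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}

EVIDENCE_COLUMNS = (
    "sample_id",
    "sequence",
    "modifications",
    "protein_ids",
    "leading_razor_protein",
    "psm_count",
)

_EVIDENCE_FILE_COLUMNS = {
    "Sample": "sample_id",
    "Sequence": "sequence",
    "Modifications": "modifications",
    "Proteins": "protein_ids",
    "Leading razor protein": "leading_razor_protein",
    "MS/MS count": "psm_count",
}


class FormatError(ValueError):
    """Raised when an input file violates the documented format or an
    invariant of the data model."""


def equate_il(sequence: str) -> str:
    """Collapse isoleucine onto leucine.

    Leucine and isoleucine are isobaric and indistinguishable by the
    underlying MS/MS measurement, so all peptide-to-proteome matching in
    this package is performed on I/L-equated strings.
    """
    return sequence.replace("I", "L")


def _check_sequence(sequence: str, context: str) -> None:
    for i, ch in enumerate(sequence):
        if ch not in _AA_SET:
            raise FormatError(
                f"{context}: non-canonical residue {ch!r} at position {i}"
            )


# --------------------------------------------------------------------------
# Protein records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One reference-database entry.

    ``category`` distinguishes genuine candidate source proteins
    (``"target"``) from common-laboratory-contaminant entries
    (``"contaminant"``, cRAP-style keratins, trypsin, BSA ...).
    """

    accession: str
    sequence: str
    taxon_id: str
    category: str = "target"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.accession!r}: empty sequence")
        _check_sequence(self.sequence, f"protein {self.accession!r}")
        if self.category not in PROTEIN_CATEGORIES:
            raise FormatError(
                f"protein {self.accession!r}: unknown category {self.category!r}"
            )


def read_fasta(path: str | Path, sidecar: str | Path) -> dict[str, ProteinRecord]:
    """Read a reference proteome.

    ``path`` is standard FASTA with ``>accession [description]`` headers;
    ``sidecar`` is a TSV mapping ``accession`` to ``taxon_id`` and
    ``category`` (UniProt-style header conventions vary too much to parse
    taxonomy out of the description line).  Order of the FASTA file is
    preserved.
    """
    meta = pd.read_csv(sidecar, sep="\t", dtype=str)
    for col in ("accession", "taxon_id", "category"):
        if col not in meta.columns:
            raise FormatError(f"sidecar {sidecar}: missing column {col!r}")
    meta = meta.set_index("accession")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise FormatError(f"sidecar {sidecar}: duplicate accession {dup!r}")

    proteins: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in proteins:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        if acc not in meta.index:
            raise FormatError(f"{path}: accession {acc!r} missing from sidecar")
        proteins[acc] = ProteinRecord(
            accession=acc,
            sequence=str(rec.seq).upper(),
            taxon_id=str(meta.at[acc, "taxon_id"]),
            category=str(meta.at[acc, "category"]),
        )
    if not proteins:
        raise FormatError(f"{path}: no FASTA entries found")
    return proteins


def write_fasta(
    proteins: Mapping[str, ProteinRecord],
    path: str | Path,
    sidecar: str | Path,
) -> None:
    """Write a protein collection as FASTA plus its taxon/category sidecar."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description="")
        for p in proteins.values()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")
    meta = pd.DataFrame(
        {
            "accession": [p.accession for p in proteins.values()],
            "taxon_id": [p.taxon_id for p in proteins.values()],
            "category": [p.category for p in proteins.values()],
        }
    )
    meta.to_csv(sidecar, sep="\t", index=False)


# --------------------------------------------------------------------------
# Peptide evidence tables
# --------------------------------------------------------------------------


def _parse_modifications(token_string: str, sequence: str) -> tuple:
    """Parse the ``Name@pos;Name@pos`` modification dialect.

    Positions are zero-based indices into ``sequence``.  Residue
    compatibility (e.g. deamidation only on N/Q) is enforced here.
    """
    token_string = token_string.strip()
    if token_string in ("", "Unmodified"):
        return ()
    mods = []
    for token in token_string.split(";"):
        token = token.strip()
        if "@" not in token:
            raise FormatError(f"malformed modification token {token!r}")
        name, _, pos_str = token.rpartition("@")
        name = name.strip()
        if name not in _NAME_TO_TYPE:
            raise FormatError(f"malformed modification token {token!r}")
        mtype = _NAME_TO_TYPE[name]
        try:
            pos = int(pos_str)
        except ValueError:
            raise FormatError(f"malformed modification token {token!r}") from None
        if not 0 <= pos < len(sequence):
            raise FormatError(
                f"modification {token!r}: position {pos} outside peptide "
                f"of length {len(sequence)}"
            )
        residues = MODIFICATION_RESIDUES[mtype]
        if residues is None:
            if pos != 0:
                raise FormatError(
                    f"modification {token!r}: N-terminal modification at "
                    f"non-zero position {pos}"
                )
        elif sequence[pos] not in residues:
            raise FormatError(
                f"modification {token!r}: residue {sequence[pos]!r} at "
                f"position {pos} is incompatible with {mtype}"
            )
        mods.append((mtype, pos))
    return tuple(mods)


def _format_modifications(mods: Iterable[tuple[str, int]]) -> str:
    return ";".join(f"{MODIFICATION_NAMES[t]}@{p}" for t, p in mods)


def validate_evidence(evidence: pd.DataFrame) -> pd.DataFrame:
    """Enforce the evidence-record invariants on a frame built in memory."""
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise FormatError(f"evidence frame missing columns {missing}")
    for row in evidence.itertuples(index=False):
        _check_sequence(row.sequence, f"evidence peptide {row.sequence!r}")
        if row.psm_count <= 0:
            raise FormatError(
                f"evidence peptide {row.sequence!r}: non-positive PSM count"
            )
        if not row.protein_ids:
            raise FormatError(
                f"evidence peptide {row.sequence!r}: empty protein list"
            )
        if row.leading_razor_protein not in row.protein_ids:
            raise FormatError(
                f"evidence peptide {row.sequence!r}: razor protein "
                f"{row.leading_razor_protein!r} not among protein ids"
            )
        for mtype, pos in row.modifications:
            if not 0 <= pos < len(row.sequence):
                raise FormatError(
                    f"evidence peptide {row.sequence!r}: modification "
                    f"position {pos} out of range"
                )
            residues = MODIFICATION_RESIDUES[mtype]
            if residues is not None and row.sequence[pos] not in residues:
                raise FormatError(
                    f"evidence peptide {row.sequence!r}: {mtype} at "
                    f"position {pos} sits on {row.sequence[pos]!r}"
                )
    return evidence


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read a peptide evidence table.

    The dialect mirrors a search-engine evidence export: one row per
    identified peptide per sample, tab-separated, with columns ``Sample``,
    ``Sequence``, ``Modifications``, ``Proteins`` (semicolon-separated
    accessions), ``Leading razor protein`` and ``MS/MS count``.
    Rows with zero PSM count are rejected.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _EVIDENCE_FILE_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    rows = []
    for i in range(len(raw)):
        sequence = raw["Sequence"].iat[i].upper()
        _check_sequence(sequence, f"{path}: peptide {sequence!r}")
        mods = _parse_modifications(raw["Modifications"].iat[i], sequence)
        protein_ids = tuple(
            p.strip() for p in raw["Proteins"].iat[i].split(";") if p.strip()
        )
        razor = raw["Leading razor protein"].iat[i].strip()
        psm_raw = raw["MS/MS count"].iat[i]
        try:
            psm = int(psm_raw)
        except ValueError:
            raise FormatError(
                f"{path}: non-integer MS/MS count {psm_raw!r}"
            ) from None
        if psm <= 0:
            raise FormatError(
                f"{path}: peptide {sequence!r} has PSM count {psm} (must be > 0)"
            )
        rows.append((raw["Sample"].iat[i], sequence, mods, protein_ids, razor, psm))
    evidence = pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS))
    return validate_evidence(evidence)


def write_evidence(evidence: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "Sample": evidence["sample_id"],
            "Sequence": evidence["sequence"],
            "Modifications": [
                _format_modifications(m) for m in evidence["modifications"]
            ],
            "Proteins": [";".join(p) for p in evidence["protein_ids"]],
            "Leading razor protein": evidence["leading_razor_protein"],
            "MS/MS count": evidence["psm_count"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Taxonomy
# --------------------------------------------------------------------------


@dataclass
class TaxonomyTree:
    """A rooted taxonomy over candidate source taxa.

    ``parent`` maps every taxon to its parent; the root maps to itself.
    """

    names: dict[str, str]
    ranks: dict[str, str]
    parent: dict[str, str]
    root: str = field(init=False)

    def __post_init__(self) -> None:
        roots = [t for t, p in self.parent.items() if p == t]
        if len(roots) != 1:
            raise FormatError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for t in self.parent:
            if self.ranks[t] not in RANK_DEPTH:
                raise FormatError(f"taxon {t!r}: unknown rank {self.ranks[t]!r}")
        # every node must reach the root without revisiting a node
        for t in self.parent:
            seen = {t}
            node = t
            while node != self.root:
                node = self.parent.get(node)
                if node is None:
                    raise FormatError(f"taxon {t!r}: orphan (parent chain leaves tree)")
                if node in seen:
                    raise FormatError(f"taxonomy contains a cycle through {node!r}")
                seen.add(node)

    def path_to_root(self, taxon: str) -> list[str]:
        """Nodes from ``taxon`` up to and including the root."""
        if taxon not in self.parent:
            raise KeyError(f"unknown taxon {taxon!r}")
        path = [taxon]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def is_ancestor(self, ancestor: str, node: str) -> bool:
        """True if ``ancestor`` is ``node`` or an ancestor of it."""
        return ancestor in self.path_to_root(node)

    def depth(self, taxon: str) -> int:
        return len(self.path_to_root(taxon)) - 1

    def taxa(self) -> list[str]:
        return list(self.parent)


def read_taxonomy(path: str | Path) -> TaxonomyTree:
    """Read a parent-child taxonomy table.

    TSV columns: ``taxon_id``, ``parent_id``, ``name``, ``rank``; exactly
    one row must have ``taxon_id == parent_id`` (the root).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("taxon_id", "parent_id", "name", "rank"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    names = dict(zip(raw["taxon_id"], raw["name"]))
    ranks = dict(zip(raw["taxon_id"], raw["rank"]))
    parent = dict(zip(raw["taxon_id"], raw["parent_id"]))
    if len(parent) != len(raw):
        raise FormatError(f"{path}: duplicate taxon_id rows")
    for t, p in parent.items():
        if p not in parent:
            raise FormatError(f"{path}: taxon {t!r} has unknown parent {p!r}")
    return TaxonomyTree(names=names, ranks=ranks, parent=parent)


def write_taxonomy(tree: TaxonomyTree, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "taxon_id": list(tree.parent),
            "parent_id": [tree.parent[t] for t in tree.parent],
            "name": [tree.names[t] for t in tree.parent],
            "rank": [tree.ranks[t] for t in tree.parent],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Per-residue annotation tracks
# --------------------------------------------------------------------------


@dataclass
class ProteinAnnotation:
    """Per-residue predictor tracks plus a scalar melting temperature.

    ``ss8`` is an 8-state secondary-structure string (DSSP-style classes
    G/H/I/E/B/T/S/L); ``rsa`` is the relative solvent accessibility
    fraction; ``disorder`` and ``amyloid`` are per-residue propensities,
    all in [0, 1]; ``tm_celsius`` is the predicted protein melting
    temperature.
    """

    ss8: str
    rsa: np.ndarray
    disorder: np.ndarray
    amyloid: np.ndarray
    tm_celsius: float

    def __len__(self) -> int:
        return len(self.ss8)


ResidueAnnotationSet = dict[str, ProteinAnnotation]


def _check_annotation(acc: str, ann: ProteinAnnotation, seq_len: int) -> None:
    for ch in ann.ss8:
        if ch not in _SS8_SET:
            raise FormatError(f"annotation {acc!r}: ss8 character {ch!r} not in {SS8_CLASSES}")
    for track_name in ("rsa", "disorder", "amyloid"):
        track = getattr(ann, track_name)
        if len(track) != seq_len or len(ann.ss8) != seq_len:
            raise FormatError(
                f"annotation {acc!r}: track {track_name} length "
                f"{len(track)} != protein length {seq_len}"
            )
        if np.any((track < 0) | (track > 1)):
            raise FormatError(f"annotation {acc!r}: {track_name} values outside [0, 1]")


def read_annotations(
    path: str | Path, proteins: Mapping[str, ProteinRecord]
) -> ResidueAnnotationSet:
    """Read per-protein annotation tracks.

    TSV with one row per accession and columns ``accession``,
    ``tm_celsius``, ``ss8`` (string), ``rsa``, ``disorder``, ``amyloid``
    (comma-separated reals).  Every accession must exist in ``proteins``
    and every track must match the protein length.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("accession", "tm_celsius", "ss8", "rsa", "disorder", "amyloid"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    annotations: ResidueAnnotationSet = {}
    for r in raw.itertuples(index=False):
        acc = r.accession
        if acc not in proteins:
            raise FormatError(f"{path}: unknown accession {acc!r}")
        ann = ProteinAnnotation(
            ss8=r.ss8,
            rsa=np.array([float(x) for x in r.rsa.split(",")]),
            disorder=np.array([float(x) for x in r.disorder.split(",")]),
            amyloid=np.array([float(x) for x in r.amyloid.split(",")]),
            tm_celsius=float(r.tm_celsius),
        )
        _check_annotation(acc, ann, len(proteins[acc].sequence))
        annotations[acc] = ann
    return annotations


def _fmt_track(track: np.ndarray) -> str:
    return ",".join(format(float(x), ".4f") for x in track)


def write_annotations(annotations: ResidueAnnotationSet, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "accession": list(annotations),
            "tm_celsius": [
                format(annotations[a].tm_celsius, ".2f") for a in annotations
            ],
            "ss8": [annotations[a].ss8 for a in annotations],
            "rsa": [_fmt_track(annotations[a].rsa) for a in annotations],
            "disorder": [_fmt_track(annotations[a].disorder) for a in annotations],
            "amyloid": [_fmt_track(annotations[a].amyloid) for a in annotations],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Sample design
# --------------------------------------------------------------------------

DESIGN_COLUMNS = (
    "sample_id",
    "ingredient",
    "matrix",
    "burial",
    "replicate",
    "cofire_group",
    "run_order",
)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Enforce sample-design invariants.

    Fresh ingredient samples are always unburied; blank machine washes
    carry no ingredient.  ``design`` is indexed by ``sample_id``.
    """
    frame = design.copy()
    if frame.index.name != "sample_id":
        if "sample_id" not in frame.columns:
            raise FormatError("design must carry a sample_id column or index")
        frame = frame.set_index("sample_id")
    if frame.index.has_duplicates:
        raise FormatError("design contains duplicate sample ids")
    for sid, row in frame.iterrows():
        if row["matrix"] not in MATRICES:
            raise FormatError(f"sample {sid!r}: unknown matrix {row['matrix']!r}")
        if row["burial"] not in BURIALS:
            raise FormatError(f"sample {sid!r}: unknown burial {row['burial']!r}")
        if row["matrix"] == "fresh" and row["burial"] != "unburied":
            raise FormatError(f"sample {sid!r}: fresh samples are always unburied")
        if row["matrix"] == "wash" and row["ingredient"] not in ("", None):
            raise FormatError(f"sample {sid!r}: wash samples carry no ingredient")
    if frame["run_order"].duplicated().any():
        raise FormatError("design run_order positions must be unique")
    return frame


def read_design(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DESIGN_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    raw["replicate"] = raw["replicate"].replace("", "0").astype(int)
    raw["run_order"] = raw["run_order"].astype(int)
    return validate_design(raw)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.reset_index().to_csv(path, sep="\t", index=False)
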