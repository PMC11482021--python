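"""Per-peptide physicochemical and structural characteristics.

The degradation analysis asks, for every identified peptide, how
hydrophobic it is (GRAVY), how acidic/basic (isoelectric point), how long,
whether it carries heating-induced deamidation, and where it sits in its
parent protein's predicted structure (secondary-structure class, solvent
accessibility, disorder, amyloid propensity, melting temperature).  These
per-peptide records are the raw material for the fresh/cooked/buried
state comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS,
    FormatError,
    ProteinRecord,
    ResidueAnnotationSet,
    equate_il,
)

# --------------------------------------------------------------------------
# Hydropathy (GRAVY)
# --------------------------------------------------------------------------

#: Kyte & Doolittle per-residue hydropathy constants.  GRAVY conventionally
#: denotes the mean of these values over a sequence; positive = hydrophobic.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    if not sequence:
        raise FormatError("gravy: empty sequence")
    try:
        return sum(KYTE_DOOLITTLE[ch] for ch in sequence) / len(sequence)
    except KeyError as exc:
        raise FormatError(f"gravy: non-canonical residue {exc.args[0]!r}") from None


# --------------------------------------------------------------------------
# Isoelectric point
# --------------------------------------------------------------------------

#: IPC_peptide pKa set (Kozlowski 2016, table of optimised peptide pKa
#: values).  Keys: "Nterm"/"Cterm" for the termini, residue letters for the
#: ionisable side chains.
IPC_PEPTIDE_PKA = {
    "Nterm": 9.564,
    "Cterm": 2.383,
    "D": 3.887,
    "E": 4.317,
    "C": 8.297,
    "Y": 10.071,
    "H": 6.018,
    "K": 10.517,
    "R": 12.503,
}

_POSITIVE_GROUPS = ("Nterm", "H", "K", "R")
_NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")


def net_charge(sequence: str, ph: float, pka_set: dict | None = None) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH.

    Positive groups contribute ``1/(1+10^(pH-pKa))`` each; negative groups
    contribute ``-1/(1+10^(pKa-pH))``.  Strictly decreasing in pH.
    """
    pka = IPC_PEPTIDE_PKA if pka_set is None else pka_set
    charge = 0.0
    for group in _POSITIVE_GROUPS:
        n = 1 if group == "Nterm" else sequence.count(group)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[group]))
    for group in _NEGATIVE_GROUPS:
        n = 1 if group == "Cterm" else sequence.count(group)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[group] - ph))
    return charge


def isoelectric_point(
    sequence: str, pka_set: dict | None = None, tol: float = 1e-4
) -> float:
    """pH at which the peptide's net charge is zero.

    Found by bisection on [0, 14]; the charge model is strictly decreasing
    in pH and every peptide carries both termini, so the zero crossing
    exists and is unique.
    """
    if not sequence:
        raise FormatError("isoelectric_point: empty sequence")
    for ch in sequence:
        if ch not in AMINO_ACIDS:
            raise FormatError(f"isoelectric_point: non-canonical residue {ch!r}")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _isoelectric_points_bulk(sequences: pd.Series) -> np.ndarray:
    """Vectorised bisection pI for an array of peptides.

    Identical model and tolerance as :func:`isoelectric_point`; peptides are
    reduced to counts of their ionisable groups and all bisections run in
    lock-step numpy.
    """
    groups = ["D", "E", "C", "Y", "H", "K", "R"]
    counts = np.array(
        [[s.count(g) for g in groups] for s in sequences], dtype=float
    )
    pka_side = np.array([IPC_PEPTIDE_PKA[g] for g in groups])
    sign = np.array([-1, -1, -1, -1, +1, +1, +1], dtype=float)

    lo = np.zeros(len(counts))
    hi = np.full(len(counts), 14.0)
    # 14 / 2**18 < 1e-4, matching the scalar tolerance
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        charge = 1.0 / (1.0 + 10.0 ** (mid - IPC_PEPTIDE_PKA["Nterm"]))
        charge = charge - 1.0 / (1.0 + 10.0 ** (IPC_PEPTIDE_PKA["Cterm"] - mid))
        frac = 1.0 / (1.0 + 10.0 ** (sign * (mid[:, None] - pka_side[None, :])))
        charge = charge + (counts * sign * frac).sum(axis=1)
        positive = charge > 0
        lo = np.where(positive, mid, lo)
        hi = np.where(positive, hi, mid)
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Pooled composition and deamidation
# --------------------------------------------------------------------------


def aa_composition(sequences) -> pd.Series:
    """Pooled relative amino-acid frequencies over a set of peptides.

    Residue counts over all sequences, normalised to sum to one; the result
    is indexed by the 20 canonical letters.
    """
    seqs = list(sequences)
    if not seqs:
        raise FormatError("aa_composition: empty peptide subset")
    counts = pd.Series(0, index=list(AMINO_ACIDS), dtype=float)
    joined = "".join(seqs)
    for ch, n in pd.Series(list(joined)).value_counts().items():
        if ch not in counts.index:
            raise FormatError(f"aa_composition: non-canonical residue {ch!r}")
        counts[ch] = n
    return counts / counts.sum()


def is_deamidated(modifications: tuple) -> bool:
    return any(m[0] == "deamidation_NQ" for m in modifications)


def deamidation_proportion(evidence: pd.DataFrame) -> float:
    """Fraction of peptide rows carrying at least one N/Q deamidation.

    Returns NaN for an empty subset (the proportion is then undefined).
    """
    if len(evidence) == 0:
        return float("nan")
    flags = [is_deamidated(m) for m in evidence["modifications"]]
    return float(np.mean(flags))


# --------------------------------------------------------------------------
# Peptide-to-protein mapping and structural summaries
# --------------------------------------------------------------------------


def map_peptide(sequence: str, protein: ProteinRecord) -> tuple[int, int]:
    """Locate a peptide in its parent protein.

    Matching is I/L-equated; the leftmost occurrence wins when the peptide
    occurs more than once.  Returns a zero-based half-open interval.
    """
    start = equate_il(protein.sequence).find(equate_il(sequence))
    if start < 0:
        raise FormatError(
            f"peptide {sequence!r} does not occur in protein "
            f"{protein.accession!r}"
        )
    return start, start + len(sequence)


#: Fixed priority used to break ties for the modal secondary-structure
#: class of a peptide (most common classes first).
SS_PRIORITY = "HELTSGBI"

RSA_THRESHOLDS = (0.10, 0.40)  # deep below, exposed above


def peptide_structure_summary(
    sequence: str,
    protein: ProteinRecord,
    annotations: ResidueAnnotationSet,
    rsa_thresholds: tuple[float, float] = RSA_THRESHOLDS,
    disorder_stat: str = "mean",
    amyloid_stat: str = "max",
) -> tuple[str, tuple[float, float, float], float, float]:
    """Structural characteristics of a peptide within its parent protein.

    Over the mapped interval: the dominant (modal) secondary-structure
    class with ties broken by :data:`SS_PRIORITY`; the fractions of
    residues buried deep in the tertiary structure (RSA < low),
    intermediate, and solvent-exposed (RSA > high); the mean disorder; and
    the maximum amyloid propensity.  ``disorder_stat`` / ``amyloid_stat``
    accept ``"mean"`` or ``"max"`` so either summary convention can be
    used.
    """
    ann = annotations[protein.accession]
    start, end = map_peptide(sequence, protein)
    if end > len(ann):
        raise FormatError(
            f"peptide interval [{start}, {end}) exceeds annotation length "
            f"{len(ann)} for {protein.accession!r}"
        )
    ss_slice = ann.ss8[start:end]
    counts = {c: ss_slice.count(c) for c in set(ss_slice)}
    best = max(counts.values())
    ss_dominant = next(c for c in SS_PRIORITY if counts.get(c, 0) == best)

    rsa = ann.rsa[start:end]
    low, high = rsa_thresholds
    n = end - start
    deep = float(np.sum(rsa < low)) / n
    exposed = float(np.sum(rsa > high)) / n
    fractions = (deep, 1.0 - deep - exposed, exposed)

    stat = {"mean": np.mean, "max": np.max}
    disorder = float(stat[disorder_stat](ann.disorder[start:end]))
    amyloid = float(stat[amyloid_stat](ann.amyloid[start:end]))
    return ss_dominant, fractions, disorder, amyloid


# --------------------------------------------------------------------------
# Assembling the property table
# --------------------------------------------------------------------------

STRUCTURE_COLUMNS = (
    "ss_dominant",
    "rsa_deep",
    "rsa_intermediate",
    "rsa_exposed",
    "disorder_mean",
    "amyloid_max",
    "tm_celsius",
)


def annotate_properties(
    evidence: pd.DataFrame,
    proteins: dict[str, ProteinRecord] | None = None,
    annotations: ResidueAnnotationSet | None = None,
    rsa_thresholds: tuple[float, float] = RSA_THRESHOLDS,
    disorder_stat: str = "mean",
    amyloid_stat: str = "max",
) -> pd.DataFrame:
    """One property record per evidence row.

    Sequence-only characteristics (length, GRAVY, pI, residue counts,
    deamidation flag) are always computed.  Structural characteristics and
    the melting temperature follow the leading razor protein; rows whose
    razor protein has no annotation keep those fields missing but are
    retained.  Amino-acid counts are emitted as ``count_<residue>``
    columns.
    """
    out = evidence.reset_index(drop=True).copy()
    seqs = out["sequence"]
    out["length"] = seqs.str.len()
    out["gravy"] = [gravy(s) for s in seqs]
    out["pi"] = _isoelectric_points_bulk(seqs) if len(out) else []
    out["is_deamidated"] = [is_deamidated(m) for m in out["modifications"]]
    for aa in AMINO_ACIDS:
        out[f"count_{aa}"] = seqs.str.count(aa)

    ss_dom: list = []
    struct_cols: dict[str, list] = {c: [] for c in STRUCTURE_COLUMNS[1:]}
    for row in out.itertuples(index=False):
        razor = row.leading_razor_protein
        protein = proteins.get(razor) if proteins else None
        ann_present = (
            protein is not None
            and annotations is not None
            and razor in annotations
        )
        if not ann_present:
            ss_dom.append(None)
            for c in struct_cols:
                struct_cols[c].append(np.nan)
            continue
        ss, fr, dis, amy = peptide_structure_summary(
            row.sequence,
            protein,
            annotations,
            rsa_thresholds,
            disorder_stat,
            amyloid_stat,
        )
        ss_dom.append(ss)
        struct_cols["rsa_deep"].append(fr[0])
        struct_cols["rsa_intermediate"].append(fr[1])
        struct_cols["rsa_exposed"].append(fr[2])
        struct_cols["disorder_mean"].append(dis)
        struct_cols["amyloid_max"].append(amy)
        struct_cols["tm_celsius"].append(annotations[razor].tm_celsius)
    out["ss_dominant"] = ss_dom
    for c, values in struct_cols.items():
        out[c] = values
    return out
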