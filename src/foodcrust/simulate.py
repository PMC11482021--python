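"""Synthetic extractome simulator.

Generates reference proteomes, a taxonomy, per-residue annotation tracks
and post-search peptide evidence tables with the statistical structure the
degradation analysis assumes, so the whole pipeline can be exercised — and
its parameter-recovery behaviour measured against ground truth — without
any external data.

The generative model, in the order it runs per sample:

1. the ingredient proteome is digested in silico (tryptic rule, proline
   suppression, up to two missed cleavages);
2. each protein receives a log-normal base abundance; a peptide is
   *detected* in the fresh state with probability
   ``logit^-1(detect_intercept + detect_slope * log(abundance))``;
3. cooking retains each detected peptide with probability
   ``logit^-1(beta0_cook + beta_gravy*GRAVY + beta_len*length)`` and
   deamidates each N/Q residue of retained peptides independently with
   probability ``deamidation_rate_cook``;
4. burial further retains with the ``beta0_bury`` logit;
5. ceramic samples multiply the detection probability by
   ``ceramic_yield`` (proteins barely impregnate the ceramic wall);
6. laboratory contaminant peptides (keratin-like reference entries) and —
   for samples cooked over the same fire — a fraction of a co-fired
   partner ingredient's detected peptides are injected;
7. blank machine washes between injections carry over a small subsample
   of the preceding run's peptides.

Every random draw flows from per-(sample, stage) child streams of the
single ``seed``, so identical inputs give byte-identical bundles and
changing one stage's parameters leaves the other stages' draws untouched
(common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    EVIDENCE_COLUMNS,
    FormatError,
    ProteinAnnotation,
    ProteinRecord,
    ResidueAnnotationSet,
    TaxonomyTree,
    equate_il,
    validate_design,
    write_annotations,
    write_design,
    write_evidence,
    write_fasta,
    write_taxonomy,
)

# --------------------------------------------------------------------------
# In-silico tryptic digestion
# --------------------------------------------------------------------------


def digest(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 7,
    max_len: int = 45,
) -> list[tuple[str, int, int]]:
    """Tryptic digestion with missed cleavages.

    Cleaves after K or R except when the next residue is P; returns every
    peptide carrying 0..``max_missed`` internal cleavage sites whose length
    lies in ``[min_len, max_len]``, as ``(peptide, start, missed)`` with
    zero-based start positions.
    """
    if max_missed < 0:
        raise FormatError("digest: max_missed must be >= 0")
    if not sequence:
        return []
    sites = [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0, *sites, len(sequence)]
    out = []
    for i in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j >= len(bounds):
                break
            s, e = bounds[i], bounds[j]
            if min_len <= e - s <= max_len:
                out.append((sequence[s:e], s, m))
    return out


# --------------------------------------------------------------------------
# Reference generation
# --------------------------------------------------------------------------

#: Background amino-acid frequencies (approximate UniProt averages).
AA_BACKGROUND = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: Secondary-structure background, the 34:21:20:11:9:4:1:0 ratio of
#: alpha-helix : beta-strand : irregular : beta-turn : high-curvature loop
#: : 310-helix : beta-bridge : pi-helix.
SS8_BACKGROUND = {
    "H": 0.34, "E": 0.21, "L": 0.20, "T": 0.11,
    "S": 0.09, "G": 0.04, "B": 0.01, "I": 0.00,
}

# Beta-distribution shapes for the per-residue tracks and the Tm normal.
# RSA is broad (surfaces and cores both common); disorder and amyloid
# propensity are right-skewed (most residues ordered / non-amyloidogenic).
_RSA_BETA = (1.8, 2.5)
_DISORDER_BETA = (1.0, 3.0)
_AMYLOID_BETA = (1.2, 5.0)
_TM_NORMAL = (55.0, 7.0)  # degrees Celsius


def _random_protein(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list(AA_BACKGROUND))
    probs = np.array(list(AA_BACKGROUND.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    if rate <= 0:
        return sequence
    seq = np.array(list(sequence))
    mask = rng.random(len(seq)) < rate
    if mask.any():
        letters = np.array(list(AA_BACKGROUND))
        probs = np.array(list(AA_BACKGROUND.values()))
        probs = probs / probs.sum()
        seq[mask] = rng.choice(letters, size=int(mask.sum()), p=probs)
    return "".join(seq)


def _annotate_protein(rng: np.random.Generator, length: int) -> ProteinAnnotation:
    classes = np.array(list(SS8_BACKGROUND))
    probs = np.array(list(SS8_BACKGROUND.values()))
    ss8 = "".join(rng.choice(classes, size=length, p=probs / probs.sum()))
    return ProteinAnnotation(
        ss8=ss8,
        rsa=rng.beta(*_RSA_BETA, size=length),
        disorder=rng.beta(*_DISORDER_BETA, size=length),
        amyloid=rng.beta(*_AMYLOID_BETA, size=length),
        tm_celsius=float(rng.normal(*_TM_NORMAL)),
    )


def generate_reference(
    n_taxa: int = 3,
    proteins_per_taxon: int = 40,
    shared_fraction: float = 0.3,
    mean_length: int = 400,
    seed: int = 0,
    substitution_rate: float = 0.02,
    n_contaminants: int = 5,
) -> tuple[dict[str, ProteinRecord], TaxonomyTree, ResidueAnnotationSet]:
    """Generate reference proteomes, their taxonomy and annotation tracks.

    Each taxon is a species leaf under its own family/order/kingdom
    lineage.  ``shared_fraction`` of each taxon's proteins are orthologs
    copied across all taxa with a small per-site substitution rate, so a
    subset of tryptic peptides is identical across taxa and resolves to a
    non-specific LCA.  Contaminant (keratin-like) entries live under a
    separate contaminant kingdom.  Protein lengths are Poisson around
    ``mean_length``; secondary structure is drawn from the
    34:21:20:11:9:4:1:0 background, RSA/disorder/amyloid from beta
    distributions and Tm from a normal (see module docstring).
    """
    if n_taxa < 2:
        raise FormatError("generate_reference: n_taxa must be >= 2")
    if not 0.0 <= shared_fraction <= 1.0:
        raise FormatError(
            f"generate_reference: shared_fraction {shared_fraction} outside [0, 1]"
        )
    rng = np.random.default_rng(seed)

    names: dict[str, str] = {"root": "cellular organisms"}
    ranks: dict[str, str] = {"root": "root"}
    parent: dict[str, str] = {"root": "root"}
    species: list[str] = []
    lineages = [f"taxon{i + 1}" for i in range(n_taxa)] + ["contam"]
    for label in lineages:
        for rank, prefix, up in (
            ("kingdom", "K", "root"),
            ("order", "O", "K"),
            ("family", "F", "O"),
            ("species", "S", "F"),
        ):
            node = f"{prefix}_{label}"
            names[node] = f"{label} {rank}"
            ranks[node] = rank
            parent[node] = up if up == "root" else f"{up}_{label}"
        if label != "contam":
            species.append(f"S_{label}")
    taxonomy = TaxonomyTree(names=names, ranks=ranks, parent=parent)

    n_shared = int(round(shared_fraction * proteins_per_taxon))
    shared_bases = [
        _random_protein(rng, max(20, rng.poisson(mean_length)))
        for _ in range(n_shared)
    ]

    proteins: dict[str, ProteinRecord] = {}
    annotations: ResidueAnnotationSet = {}
    for t, taxon in enumerate(species):
        label = lineages[t]
        for j in range(proteins_per_taxon):
            if j < n_shared:
                seq = _mutate(rng, shared_bases[j], substitution_rate)
                acc = f"{label}_ORTH{j:03d}"
            else:
                seq = _random_protein(rng, max(20, rng.poisson(mean_length)))
                acc = f"{label}_PROT{j:03d}"
            proteins[acc] = ProteinRecord(acc, seq, taxon, "target")
            annotations[acc] = _annotate_protein(rng, len(seq))
    for j in range(n_contaminants):
        seq = _random_protein(rng, max(20, rng.poisson(mean_length)))
        acc = f"CONTAM{j:03d}"
        proteins[acc] = ProteinRecord(acc, seq, "S_contam", "contaminant")
        annotations[acc] = _annotate_protein(rng, len(seq))
    return proteins, taxonomy, annotations


# --------------------------------------------------------------------------
# Sample design
# --------------------------------------------------------------------------


def make_design(
    ingredients: Sequence[str],
    replicates: int = 3,
    matrices: Sequence[tuple[str, str]] = (
        ("fresh", "unburied"),
        ("foodcrust", "unburied"),
        ("foodcrust", "buried"),
        ("ceramic", "unburied"),
        ("ceramic", "buried"),
    ),
    washes: bool = True,
    cofire: bool = True,
) -> pd.DataFrame:
    """Build a sample-design table for the cooking/burial experiment.

    One fresh replicate per ingredient and ``replicates`` replicates of
    each cooked matrix/burial combination; every cooked sample shares one
    co-firing group (all vessels over the same open fire).  When
    ``washes`` is true a blank machine wash precedes every injection.
    """
    rows = []
    run = 1
    for taxon in ingredients:
        for matrix, burial in matrices:
            n_rep = 1 if matrix == "fresh" else replicates
            for rep in range(1, n_rep + 1):
                if washes:
                    rows.append((f"W{run:03d}", "", "wash", "unburied", 0, "", run))
                    run += 1
                sid = f"{taxon}_{matrix}_{burial}_r{rep}"
                group = "fire1" if (cofire and matrix != "fresh") else ""
                rows.append((sid, taxon, matrix, burial, rep, group, run))
                run += 1
    design = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "ingredient",
            "matrix",
            "burial",
            "replicate",
            "cofire_group",
            "run_order",
        ],
    )
    return validate_design(design)


# --------------------------------------------------------------------------
# Survival model parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalParams:
    """Parameters of the property-biased peptide survival model.

    ``beta0_cook`` / ``beta0_bury`` are baseline log-odds of retention
    across the fresh-to-cooked and cooked-to-buried transitions;
    ``beta_gravy`` and ``beta_len`` tilt the retention log-odds by peptide
    hydropathy and length (negative ``beta_len`` makes long peptides rare
    in degraded samples).  ``ceramic_yield`` multiplies the detection
    probability in ceramic extracts.  Defaults reproduce the qualitative
    ordering fresh >= cooked foodcrust > buried foodcrust >> ceramic.
    """

    beta0_cook: float = 2.5
    beta0_bury: float = 1.5
    beta_gravy: float = 0.3
    beta_len: float = -0.08
    ceramic_yield: float = 0.02
    deamidation_rate_cook: float = 0.3
    deamidation_rate_base: float = 0.01
    crosscontam_frac: float = 0.005
    contam_peptides_per_sample: int = 30
    seed: int = 0
    # detection model and nuisance parameters; the intercept puts mean
    # detection around 15% of a proteome's tryptic peptides, the sparse
    # regime typical of single-shot LC-MS/MS
    detect_intercept: float = -2.0
    detect_slope: float = 1.0
    psm_scale: float = 1.5
    cook_inflation_fraction: float = 0.1
    cook_inflation_multiplier: float = 5.0
    wash_carryover_frac: float = 0.01
    digest_min_len: int = 7
    digest_max_len: int = 45
    digest_max_missed: int = 2

    def __post_init__(self) -> None:
        for name in (
            "ceramic_yield",
            "deamidation_rate_cook",
            "deamidation_rate_base",
            "crosscontam_frac",
            "wash_carryover_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"SurvivalParams.{name} = {v} outside [0, 1]")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


# --------------------------------------------------------------------------
# Peptide pools (digestion cached per reference)
# --------------------------------------------------------------------------


@dataclass
class PeptidePools:
    """Digested, de-duplicated peptide pools per taxon plus global lookup.

    ``by_taxon[taxon]`` is a frame with one row per unique peptide of the
    taxon's proteome (sequence, candidate accessions, GRAVY, length, N/Q
    positions); ``protein_ids`` maps an exact sequence to every reference
    accession (any taxon, any category) whose digest yields it;
    ``n_taxa_matching`` counts reference taxa containing the peptide.
    """

    by_taxon: dict[str, pd.DataFrame]
    contaminant_pool: pd.DataFrame
    protein_ids: dict[str, tuple[str, ...]]
    taxa_matching: dict[str, int]


def prepare_pools(
    proteins: Mapping[str, ProteinRecord], params: SurvivalParams
) -> PeptidePools:
    """Digest every reference protein once and build the lookup tables."""
    from .properties import gravy as _gravy

    seq_to_accs: dict[str, set[str]] = {}
    seq_to_taxa: dict[str, set[str]] = {}
    per_taxon_raw: dict[str, dict[str, list[str]]] = {}
    contam_raw: dict[str, list[str]] = {}
    for acc, rec in proteins.items():
        peptides = {
            p
            for p, _, _ in digest(
                rec.sequence,
                params.digest_max_missed,
                params.digest_min_len,
                params.digest_max_len,
            )
        }
        for p in peptides:
            seq_to_accs.setdefault(p, set()).add(acc)
            if rec.category == "target":
                # taxa are counted on I/L-equated sequences, the matching
                # convention used throughout the analysis
                seq_to_taxa.setdefault(equate_il(p), set()).add(rec.taxon_id)
                per_taxon_raw.setdefault(rec.taxon_id, {}).setdefault(p, []).append(acc)
            else:
                contam_raw.setdefault(p, []).append(acc)

    protein_ids = {s: tuple(sorted(a)) for s, a in seq_to_accs.items()}
    taxa_matching = {s: len(seq_to_taxa.get(equate_il(s), ())) for s in seq_to_accs}

    def _pool_frame(raw: dict[str, list[str]]) -> pd.DataFrame:
        seqs = sorted(raw)
        return pd.DataFrame(
            {
                "sequence": seqs,
                "candidates": [tuple(sorted(raw[s])) for s in seqs],
                "gravy": [_gravy(s) for s in seqs],
                "length": [len(s) for s in seqs],
                "nq_positions": [
                    tuple(i for i, ch in enumerate(s) if ch in "NQ") for s in seqs
                ],
            }
        )

    return PeptidePools(
        by_taxon={t: _pool_frame(raw) for t, raw in per_taxon_raw.items()},
        contaminant_pool=_pool_frame(contam_raw),
        protein_ids=protein_ids,
        taxa_matching=taxa_matching,
    )


# --------------------------------------------------------------------------
# The simulator proper
# --------------------------------------------------------------------------


@dataclass
class ExtractomeBundle:
    """A complete simulated study: inputs, evidence and generative truth.

    ``truth`` has exactly one row per evidence row (same order) recording
    the peptide's origin (``ingredient`` / ``contaminant`` /
    ``crosscontam`` / ``carryover``), its source taxon, the number of
    reference taxa containing it, and how many deamidations it received.
    """

    proteins: dict[str, ProteinRecord]
    taxonomy: TaxonomyTree
    annotations: ResidueAnnotationSet
    design: pd.DataFrame
    evidence: pd.DataFrame
    truth: pd.DataFrame


_TRUTH_COLUMNS = (
    "sample_id",
    "sequence",
    "origin",
    "source_taxon",
    "n_taxa_matching",
    "n_deamidated",
)

# stage ids for per-(sample, stage) random streams
_STAGE_DETECT, _STAGE_COOK, _STAGE_BURY, _STAGE_PSM = 0, 1, 2, 3
_STAGE_DEAM, _STAGE_CONTAM, _STAGE_CROSS, _STAGE_WASH = 4, 5, 6, 7
_STAGE_GLOBAL = 1_000_000


class _SampleAccumulator:
    """Column-wise accumulation of evidence plus aligned truth rows."""

    def __init__(self) -> None:
        self.columns: dict[str, list] = {c: [] for c in EVIDENCE_COLUMNS}
        self.truth: dict[str, list] = {c: [] for c in _TRUTH_COLUMNS}

    def add(self, sample_id, sequence, mods, protein_ids, razor, psm,
            origin, source_taxon, n_taxa, n_deam) -> None:
        c = self.columns
        c["sample_id"].append(sample_id)
        c["sequence"].append(sequence)
        c["modifications"].append(mods)
        c["protein_ids"].append(protein_ids)
        c["leading_razor_protein"].append(razor)
        c["psm_count"].append(psm)
        t = self.truth
        t["sample_id"].append(sample_id)
        t["sequence"].append(sequence)
        t["origin"].append(origin)
        t["source_taxon"].append(source_taxon)
        t["n_taxa_matching"].append(n_taxa)
        t["n_deamidated"].append(n_deam)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _draw_deamidations(
    rng: np.random.Generator, nq_positions: tuple[int, ...], rate: float
) -> tuple:
    if rate <= 0 or not nq_positions:
        return ()
    k = rng.binomial(len(nq_positions), rate)
    if k == 0:
        return ()
    chosen = rng.choice(len(nq_positions), size=k, replace=False)
    return tuple(
        ("deamidation_NQ", nq_positions[i]) for i in sorted(chosen)
    )


def simulate_extractome(
    proteins: Mapping[str, ProteinRecord],
    taxonomy: TaxonomyTree,
    annotations: ResidueAnnotationSet,
    design: pd.DataFrame,
    params: SurvivalParams,
    pools: PeptidePools | None = None,
) -> ExtractomeBundle:
    """Run the generative survival model over every sample in the design.

    ``pools`` may carry pre-digested peptide pools (from
    :func:`prepare_pools`) when many simulations share one reference;
    otherwise they are built here.  Identical inputs and seed give a
    byte-identical bundle.
    """
    design = validate_design(design)
    for taxon in design.loc[design["matrix"] != "wash", "ingredient"].unique():
        if taxon not in taxonomy.parent:
            raise FormatError(f"simulate_extractome: unknown ingredient taxon {taxon!r}")
    if pools is None:
        pools = prepare_pools(proteins, params)
    for taxon in design.loc[design["matrix"] != "wash", "ingredient"].unique():
        if taxon not in pools.by_taxon:
            raise FormatError(
                f"simulate_extractome: ingredient {taxon!r} has no target proteome"
            )
    seed = params.seed

    # per-simulation protein abundances and cook-inflated protein subset
    rng_global = _rng(seed, _STAGE_GLOBAL)
    accessions = sorted(proteins)
    abundance = dict(
        zip(accessions, np.exp(rng_global.normal(0.0, 1.0, size=len(accessions))))
    )
    n_inflate = int(round(params.cook_inflation_fraction * len(accessions)))
    inflated = set(
        rng_global.choice(accessions, size=n_inflate, replace=False)
        if n_inflate
        else []
    )

    # per-taxon cached arrays
    taxon_cache: dict[str, dict] = {}

    def _taxon_arrays(taxon: str) -> dict:
        if taxon in taxon_cache:
            return taxon_cache[taxon]
        pool = pools.by_taxon[taxon]
        razor = [
            max(cands, key=lambda a: (abundance[a], a)) for cands in pool["candidates"]
        ]
        ab = np.array([abundance[r] for r in razor])
        arrays = {
            "pool": pool,
            "razor": razor,
            "abundance": ab,
            "log_ab": np.log(ab),
            "gravy": pool["gravy"].to_numpy(),
            "length": pool["length"].to_numpy(dtype=float),
            "protein_ids": [pools.protein_ids[s] for s in pool["sequence"]],
            "n_taxa": [pools.taxa_matching.get(s, 0) for s in pool["sequence"]],
            "inflation": np.array(
                [
                    params.cook_inflation_multiplier if r in inflated else 1.0
                    for r in razor
                ]
            ),
        }
        taxon_cache[taxon] = arrays
        return arrays

    ordered = design.sort_values("run_order")
    acc = _SampleAccumulator()
    # rows of the immediately preceding non-wash run, for wash carry-over
    previous_rows: list[tuple] | None = None
    sample_indices = {sid: i for i, sid in enumerate(ordered.index)}
    cofire_members: dict[str, list[str]] = {}
    for sid, row in ordered.iterrows():
        if row["cofire_group"]:
            cofire_members.setdefault(row["cofire_group"], []).append(sid)

    for sid, row in ordered.iterrows():
        sidx = sample_indices[sid]
        matrix = row["matrix"]
        if matrix == "wash":
            rng_wash = _rng(seed, sidx, _STAGE_WASH)
            if previous_rows:
                n_take = max(1, int(round(params.wash_carryover_frac * len(previous_rows))))
                chosen = rng_wash.choice(len(previous_rows), size=min(n_take, len(previous_rows)), replace=False)
                for i in sorted(chosen):
                    seq, mods, pids, razor, src_taxon, n_taxa, n_deam = previous_rows[i]
                    acc.add(sid, seq, mods, pids, razor, 1,
                            "carryover", src_taxon, n_taxa, n_deam)
            continue

        taxon = row["ingredient"]
        arrays = _taxon_arrays(taxon)
        pool = arrays["pool"]
        n_pool = len(pool)
        cooked = matrix in ("foodcrust", "ceramic")
        buried = row["burial"] == "buried"

        p_detect = _sigmoid(
            params.detect_intercept + params.detect_slope * arrays["log_ab"]
        )
        if matrix == "ceramic":
            p_detect = p_detect * params.ceramic_yield
        u_detect = _rng(seed, sidx, _STAGE_DETECT).random(n_pool)
        u_cook = _rng(seed, sidx, _STAGE_COOK).random(n_pool)
        u_bury = _rng(seed, sidx, _STAGE_BURY).random(n_pool)

        final = u_detect < p_detect
        if cooked:
            p_cook = _sigmoid(
                params.beta0_cook
                + params.beta_gravy * arrays["gravy"]
                + params.beta_len * arrays["length"]
            )
            final = final & (u_cook < p_cook)
        if buried:
            p_bury = _sigmoid(
                params.beta0_bury
                + params.beta_gravy * arrays["gravy"]
                + params.beta_len * arrays["length"]
            )
            final = final & (u_bury < p_bury)

        mu = params.psm_scale * arrays["abundance"] * (
            arrays["inflation"] if cooked else 1.0
        )
        psm = _rng(seed, sidx, _STAGE_PSM).geometric(1.0 / (1.0 + mu))

        rng_deam = _rng(seed, sidx, _STAGE_DEAM)
        deam_rate = (
            params.deamidation_rate_cook if cooked else params.deamidation_rate_base
        )
        own_rows: list[tuple] = []
        nq_all = pool["nq_positions"]
        seq_all = pool["sequence"]
        razor_all = arrays["razor"]
        pids_all = arrays["protein_ids"]
        ntaxa_all = arrays["n_taxa"]
        for i in np.flatnonzero(final):
            mods = _draw_deamidations(rng_deam, nq_all.iat[i], deam_rate)
            entry = (
                seq_all.iat[i],
                mods,
                pids_all[i],
                razor_all[i],
                taxon,
                ntaxa_all[i],
                len(mods),
            )
            own_rows.append(entry)
            acc.add(sid, entry[0], mods, entry[2], entry[3], int(psm[i]),
                    "ingredient", taxon, entry[5], entry[6])

        # laboratory contaminant injection (keratin-like entries)
        contam_pool = pools.contaminant_pool
        rng_contam = _rng(seed, sidx, _STAGE_CONTAM)
        n_contam = min(params.contam_peptides_per_sample, len(contam_pool))
        contam_rows: list[tuple] = []
        if n_contam:
            chosen = rng_contam.choice(len(contam_pool), size=n_contam, replace=False)
            for i in sorted(chosen):
                s = contam_pool["sequence"].iat[i]
                cands = contam_pool["candidates"].iat[i]
                razor = max(cands, key=lambda a: (abundance[a], a))
                c_psm = rng_contam.geometric(
                    1.0 / (1.0 + params.psm_scale * abundance[razor])
                )
                entry = (s, (), pools.protein_ids[s], razor, "S_contam",
                         pools.taxa_matching.get(s, 0), 0)
                contam_rows.append(entry)
                acc.add(sid, s, (), entry[2], razor, int(c_psm),
                        "contaminant", "S_contam", entry[5], 0)

        # co-firing cross-contamination from partner ingredients
        cross_rows: list[tuple] = []
        if cooked and row["cofire_group"] and params.crosscontam_frac > 0:
            partners = sorted(
                {
                    ordered.at[other, "ingredient"]
                    for other in cofire_members[row["cofire_group"]]
                    if ordered.at[other, "ingredient"] not in ("", taxon)
                }
            )
            for p_idx, partner in enumerate(partners):
                parr = _taxon_arrays(partner)
                rng_cross = _rng(seed, sidx, _STAGE_CROSS, p_idx)
                pp_detect = _sigmoid(
                    params.detect_intercept + params.detect_slope * parr["log_ab"]
                )
                pp_cook = _sigmoid(
                    params.beta0_cook
                    + params.beta_gravy * parr["gravy"]
                    + params.beta_len * parr["length"]
                )
                virtual = rng_cross.random(len(parr["pool"])) < pp_detect * pp_cook
                candidates = np.flatnonzero(virtual)
                n_take = int(round(params.crosscontam_frac * len(candidates)))
                if n_take == 0:
                    continue
                chosen = rng_cross.choice(candidates, size=n_take, replace=False)
                if buried:
                    # cross-contamination deposits during cooking and is
                    # then subject to the same burial attrition
                    pp_bury = _sigmoid(
                        params.beta0_bury
                        + params.beta_gravy * parr["gravy"][chosen]
                        + params.beta_len * parr["length"][chosen]
                    )
                    chosen = chosen[rng_cross.random(len(chosen)) < pp_bury]
                ppool = parr["pool"]
                for i in sorted(chosen):
                    s = ppool["sequence"].iat[i]
                    entry = (s, (), parr["protein_ids"][i], parr["razor"][i],
                             partner, parr["n_taxa"][i], 0)
                    cross_rows.append(entry)
                    acc.add(sid, s, (), entry[2], entry[3], 1,
                            "crosscontam", partner, entry[5], 0)

        previous_rows = own_rows + contam_rows + cross_rows

    evidence = pd.DataFrame(acc.columns)
    truth = pd.DataFrame(acc.truth)
    return ExtractomeBundle(
        proteins=dict(proteins),
        taxonomy=taxonomy,
        annotations=annotations,
        design=design,
        evidence=evidence,
        truth=truth,
    )


# --------------------------------------------------------------------------
# Bundle export
# --------------------------------------------------------------------------


def write_bundle(bundle: ExtractomeBundle, outdir: str | Path) -> None:
    """Write a simulated bundle as the pipeline's on-disk file set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.proteins, outdir / "proteins.fasta", outdir / "proteins_meta.tsv")
    write_taxonomy(bundle.taxonomy, outdir / "taxonomy.tsv")
    write_annotations(bundle.annotations, outdir / "annotations.tsv")
    write_design(bundle.design, outdir / "design.tsv")
    write_evidence(bundle.evidence, outdir / "evidence.tsv")
    truth = bundle.truth.copy()
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
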