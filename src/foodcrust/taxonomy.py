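"""Peptide taxonomy: lowest-common-ancestor assignment and source
classification.

Each identified peptide is matched (I/L-equated, tryptic index) against
the reference proteomes; the set of taxa containing it collapses to its
lowest common ancestor in the supplied taxonomy.  Against a sample's
known input ingredient, an LCA then classifies the peptide or protein as

* ``input_ingredient`` — the LCA is at family rank or more specific and
  its subtree contains the ingredient;
* ``non_specific``    — the subtree contains the ingredient but the LCA
  sits above family rank (conserved muscle proteins, orthologs);
* ``contaminant``     — the LCA's subtree cannot contain the ingredient,
  so the peptide must derive from another source;
* ``unassigned``      — the peptide matches nothing in the reference.

Matching here is against the supplied proteomes only, not a full
UniProt-scale tryptic index, so assignments can only be more specific
than a Unipept-style lookup against the public database.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .io import (
    FormatError,
    ProteinRecord,
    RANK_DEPTH,
    TaxonomyTree,
    equate_il,
)
from .simulate import digest

SOURCE_CLASSES = ("input_ingredient", "non_specific", "contaminant", "unassigned")


# --------------------------------------------------------------------------
# Peptide index
# --------------------------------------------------------------------------


def build_peptide_index(
    proteins: Mapping[str, ProteinRecord],
    max_missed: int = 2,
    min_len: int = 7,
    max_len: int = 45,
) -> dict[str, set[str]]:
    """Map every I/L-equated tryptic peptide to the taxa containing it.

    Uses the same digestion rule as the simulator (cleave after K/R unless
    P follows).  Contaminant entries contribute their taxon like any
    other, so keratin-like peptides resolve to the contaminant lineage.
    """
    index: dict[str, set[str]] = {}
    for rec in proteins.values():
        for peptide, _, _ in digest(rec.sequence, max_missed, min_len, max_len):
            index.setdefault(equate_il(peptide), set()).add(rec.taxon_id)
    return index


# --------------------------------------------------------------------------
# Lowest common ancestor
# --------------------------------------------------------------------------


def lca(taxa: Iterable[str], tree: TaxonomyTree) -> str:
    """Deepest node that is an ancestor-or-self of every input taxon."""
    taxa = list(taxa)
    if not taxa:
        raise FormatError("lca: empty taxon set")
    common: set[str] | None = None
    for t in taxa:
        if t not in tree.parent:
            raise FormatError(f"lca: unknown taxon {t!r}")
        path = set(tree.path_to_root(t))
        common = path if common is None else common & path
    assert common  # the root is always shared
    return max(common, key=tree.depth)


# --------------------------------------------------------------------------
# Source classification
# --------------------------------------------------------------------------


def classify_source(
    lca_node: str,
    ingredient: str,
    tree: TaxonomyTree,
    specificity_rank: str = "family",
) -> str:
    """Classify an LCA against a sample's known input ingredient.

    ``specificity_rank`` is inclusive: an LCA at exactly that rank (or any
    more specific rank) whose subtree contains the ingredient counts as a
    match to the input ingredient.
    """
    if specificity_rank not in RANK_DEPTH:
        raise FormatError(f"classify_source: unknown rank {specificity_rank!r}")
    if not tree.is_ancestor(lca_node, ingredient):
        return "contaminant"
    if RANK_DEPTH[tree.ranks[lca_node]] >= RANK_DEPTH[specificity_rank]:
        return "input_ingredient"
    return "non_specific"


# --------------------------------------------------------------------------
# Sample-level assignment
# --------------------------------------------------------------------------


def assign_sample_sources(
    evidence: pd.DataFrame,
    index: Mapping[str, set[str]],
    tree: TaxonomyTree,
    design: pd.DataFrame,
    specificity_rank: str = "family",
    top_n: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Assign LCAs and source classes per peptide and per protein.

    Returns three frames:

    * per peptide row — its taxa set size, LCA and source class;
    * per (sample, razor protein) — the LCA of the union of its peptides'
      taxa sets ("protein LCA") and the resulting class;
    * the top-``top_n`` proteins per sample by summed PSM-bearing peptide
      count (descending, ties broken lexicographically by accession), the
      analogue of the paper-style most-abundant-protein tables.

    Peptides absent from the index are ``unassigned`` and excluded from
    protein LCAs.
    """
    ingredient_of = design["ingredient"].to_dict()

    pep_rows = []
    union_taxa: dict[tuple[str, str], set[str]] = {}
    psm_sums: dict[tuple[str, str], int] = {}
    for row in evidence.itertuples(index=False):
        sid = row.sample_id
        ingredient = ingredient_of.get(sid, "")
        taxa = index.get(equate_il(row.sequence))
        if taxa:
            node = lca(taxa, tree)
            cls = (
                classify_source(node, ingredient, tree, specificity_rank)
                if ingredient
                else "unassigned"
            )
        else:
            node, cls = "", "unassigned"
        pep_rows.append(
            (sid, row.sequence, len(taxa) if taxa else 0, node, cls)
        )
        key = (sid, row.leading_razor_protein)
        psm_sums[key] = psm_sums.get(key, 0) + row.psm_count
        if taxa:
            union_taxa.setdefault(key, set()).update(taxa)

    peptide_table = pd.DataFrame(
        pep_rows, columns=["sample_id", "sequence", "n_taxa", "lca", "source_class"]
    )

    prot_rows = []
    for (sid, protein), psm in sorted(psm_sums.items()):
        ingredient = ingredient_of.get(sid, "")
        taxa = union_taxa.get((sid, protein))
        if taxa:
            node = lca(taxa, tree)
            cls = (
                classify_source(node, ingredient, tree, specificity_rank)
                if ingredient
                else "unassigned"
            )
        else:
            node, cls = "", "unassigned"
        prot_rows.append((sid, protein, psm, node, cls))
    protein_table = pd.DataFrame(
        prot_rows,
        columns=["sample_id", "protein", "psm_count", "lca", "source_class"],
    )

    top_rows = []
    for sid, group in protein_table.groupby("sample_id", sort=True):
        ranked = group.sort_values(
            ["psm_count", "protein"], ascending=[False, True]
        ).head(top_n)
        for r in ranked.itertuples(index=False):
            top_rows.append(tuple(r))
    top_table = pd.DataFrame(top_rows, columns=list(protein_table.columns))
    return peptide_table, protein_table, top_table
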