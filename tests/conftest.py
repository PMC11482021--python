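"""Shared fixtures: the committed toy filtering study and small simulated
bundles reused across test modules."""

from pathlib import Path

import pytest

import foodcrust as fc

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_study():
    """The committed 20-row evidence fixture with known filter violations."""
    proteins = fc.read_fasta(DATA / "proteins.fasta", DATA / "proteins_meta.tsv")
    return {
        "proteins": proteins,
        "taxonomy": fc.read_taxonomy(DATA / "taxonomy.tsv"),
        "design": fc.read_design(DATA / "design.tsv"),
        "evidence": fc.read_evidence(DATA / "evidence.tsv"),
    }


@pytest.fixture(scope="session")
def small_reference():
    """A compact simulated reference (2 taxa, short proteins)."""
    return fc.generate_reference(
        n_taxa=2, proteins_per_taxon=6, mean_length=150, seed=7
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default-parameter simulation over the full experimental design."""
    proteins, tree, ann = fc.generate_reference(seed=11)
    params = fc.SurvivalParams(seed=11)
    ingredients = sorted(
        {p.taxon_id for p in proteins.values() if p.category == "target"}
    )
    design = fc.make_design(ingredients)
    bundle = fc.simulate_extractome(proteins, tree, ann, design, params)
    return bundle
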