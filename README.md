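# foodcrust

Degradation analysis of proteins extracted from experimentally cooked and
buried food residues — charred foodcrusts and the ceramic vessels they
formed on — for palaeoproteomics researchers who need to understand which
peptides survive cooking and burial, and why.

Ancient cooking residues preserve dietary proteins, but the recovered
*extractome* is a biased subsample of the original proteome. This package
implements the full comparative analysis of that bias:

* **Filtering** of post-search peptide evidence tables: search-criteria
  envelope (length ≥ 7, ≤ 2 missed tryptic cleavages), cRAP-style
  laboratory-contaminant removal, machine carry-over removal via blank
  washes, exclusion of samples whose known field cross-contamination
  exceeds 2% of peptide rows, and per-protein PSM support.
* **Per-peptide characterisation**: amino-acid composition, length,
  GRAVY (mean Kyte–Doolittle hydropathy), isoelectric point (bisection on
  the Henderson–Hasselbalch net charge, IPC_peptide pKa set),
  deamidation flags, and structural context sliced from per-residue
  predictor tracks (8-state secondary structure, relative solvent
  accessibility, disorder, amyloid propensity) plus protein melting
  temperature.
* **Taxonomic source classification**: a Unipept-style lowest-common-
  ancestor assignment of each peptide over an I/L-equated tryptic index
  of the reference proteomes, then classification against the sample's
  known input ingredient (input ingredient / non-specific / contaminant).
* **State comparisons**: protein-by-sample count matrices, average-
  linkage Euclidean clustering, UpSet-style exclusive intersections, and
  Kruskal–Wallis plus two-sided Wilcoxon rank-sum tests of property
  distributions across fresh / cooked / buried states, with exact
  small-sample p-values; per-protein residue-resolved coverage overlays.
* **A synthetic extractome simulator** whose property-biased survival
  model — peptide retention probability
  logit⁻¹(β₀ + β_gravy·GRAVY + β_len·length) across the fresh→cooked and
  cooked→buried transitions, ceramic detection yield, heating-induced
  N/Q deamidation, contaminant and co-firing cross-contamination
  injection — makes every stage testable against generative truth with
  no external data.

See `docs/methods.md` for the model details and every documented
convention.

## Worked example

Simulate a complete three-ingredient cooking/burial experiment, filter
it, and test the burial hydrophobicity effect:

```python
import foodcrust as fc

proteins, tree, annotations = fc.generate_reference(seed=1)
ingredients = sorted({p.taxon_id for p in proteins.values()
                      if p.category == "target"})
design = fc.make_design(ingredients)           # fresh + foodcrust/ceramic
params = fc.SurvivalParams(seed=1)             # documented defaults
bundle = fc.simulate_extractome(proteins, tree, annotations, design, params)

filtered, kept_proteins, report = fc.run_filter_pipeline(
    bundle.evidence, bundle.design, proteins)
print(report.to_frame())
```

With seed 1 the simulated study has 9,023 evidence rows; the contaminant
stage removes 1,190 rows (100% of the injected contaminant-only peptides,
audited against truth) and the carry-over stage 11 rows; 22 of 39 samples
pass the 2% cross-contamination rule — every fresh and unburied-foodcrust
sample, most buried foodcrusts, and no ceramics, whose mean
cross-contaminant load is ~25% of rows. Mean recovered protein counts per
state reproduce the qualitative recovery ordering:

| state | proteins | peptide rows |
|---|---|---|
| fresh ingredient | 37.3 | 637 |
| foodcrust, unburied | 36.9 | 459 |
| foodcrust, buried | 32.2 | 242 |
| ceramic, unburied | 6.8 | 43 |
| ceramic, buried | 2.4 | 35 |

i.e. fresh ≈ cooked foodcrust > buried foodcrust ≫ ceramic, with ceramic
rows dominated by injected contamination. Source classification against
the taxonomy recovers the generative truth exactly: 100% of
ingredient-unique peptides classify as input ingredient, 100% of fully
shared orthologs as non-specific, 100% of foreign-lineage injections as
contaminant (n = 6,105 / 804 / 1,245). Heating-induced deamidation shows
the expected pattern — 31.5% of cooked peptide rows deamidated versus
1.0% of fresh, against an analytic expectation of 33.0% from the
per-residue rate (each N/Q deamidates independently with probability 0.3,
so a peptide with k such residues escapes with probability 0.7ᵏ).

At this default scale the buried-vs-unburied GRAVY shift is small and not
significant in a single study (two-sided Wilcoxon p = 0.23); a dedicated
power sweep at the simulator's documented power scale (β_gravy = 0.6,
~12,000-peptide reference, 3 replicates per state) rejects with a
positive hydrophobic shift in 20/20 seeds.

## Command line

The same stages are exposed as subcommands of the `foodcrust` script:
`simulate`, `filter`, `annotate`, `lca`, `compare`, `report` — each a
thin wrapper reading/writing the documented TSV/FASTA formats
(`foodcrust simulate --seed 1 --out study/` then
`foodcrust filter --evidence study/evidence.tsv ...`).

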