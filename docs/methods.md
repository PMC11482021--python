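# Methods

## Scope and data model

`foodcrust` analyses the *extractome* — the set of peptides actually
recovered and identified from a sample — of experimentally cooked and
buried food residues: fresh ingredient, charred foodcrust adhering to
vessel walls, and the ceramic fabric itself, each unburied or after
burial. Inputs are post-search peptide evidence tables (one row per
identified peptide per sample, with modifications, protein assignments
and PSM counts), reference proteomes with taxon and contaminant labels,
a rooted taxonomy, per-residue structure-predictor tracks, and the sample
design (ingredient, matrix, burial, replicate, co-firing group, injection
order). Search-engine internals (target–decoy FDR, spectra) are upstream
of this package: evidence tables are consumed as given.

Conventions used throughout: residue positions are zero-based, intervals
half-open; peptide-to-proteome matching is I/L-equated, because leucine
and isoleucine are isobaric and indistinguishable in the underlying
measurement.

## Identification filtering

Filters compose in a fixed order — search-criteria filters (length ≥ 7,
missed cleavages ≤ 2), contaminant removal, machine carry-over removal,
cross-contamination sample exclusion, protein-level support — because the
stages do not commute (removing contaminants before the carry-over check
changes what a wash can explain). Each stage is contractive and
idempotent and reports per-reason removal counts.

Decisions where the procedure was genuinely open:

* **Contaminant-ambiguous peptides** (present in both a contaminant entry
  and a target protein) are removed. This is the conservative choice:
  such rows cannot be distinguished from keratin/trypsin contamination,
  which dominates low-yield ceramic extracts.
* **Carry-over** is detected by exact-sequence match against the nearest
  preceding blank wash in the injection sequence. Identity matching (not
  intensity) is used; both the removed-row count and per-sample notes are
  reported so the convention can be audited.
* **Cross-contamination** counts unique peptide rows, not PSM-weighted
  counts: a row is a *known* cross-contaminant when its sequence occurs
  in a co-fired partner ingredient's proteome and not the sample's own;
  peptides in both proteomes are ambiguous and not counted. The 2%
  inclusion threshold is inclusive (exactly 2.0% is kept).
* **Protein support** defaults to ≥ 2 summed PSMs per (sample, razor
  protein) — "more than one PSM"; the stricter "more than two" convention
  is available via `min_psm=3`.

## Peptide characteristics

* **GRAVY** is the mean Kyte–Doolittle hydropathy per residue. The scale
  is stated explicitly because "GRAVY" conventionally denotes this table.
* **Isoelectric point** solves net Henderson–Hasselbalch charge = 0 by
  bisection on pH ∈ [0, 14] to 1e-4, using the IPC_peptide pKa set
  (optimised peptide pKa values; N-term 9.564, C-term 2.383, D 3.887,
  E 4.317, C 8.297, Y 10.071, H 6.018, K 10.517, R 12.503). The charge
  model is strictly decreasing in pH and every peptide carries both
  termini, so the root exists and is unique. Agreement claimed is to this
  charge-model family, not to any external predictor's output.
* **Structural summaries** slice the razor protein's per-residue tracks
  over the peptide's mapped interval (leftmost occurrence, I/L-equated):
  dominant 8-state secondary-structure class with a fixed tie-break
  priority H > E > L > T > S > G > B > I (most common classes win ties);
  RSA classes deep (< 0.10), intermediate, exposed (> 0.40) — thresholds
  follow common solvent-accessibility conventions and are configurable;
  disorder summarised by mean and amyloid propensity by max (both
  switchable to the other statistic, since either convention is
  defensible); Tm inherited from the razor protein, never computed.
  Multi-protein peptides follow the leading razor protein throughout.
* **Deamidation** is a row-level flag (≥ 1 N/Q deamidation) and
  proportions are reported over peptide rows; the proportion of an empty
  subset is undefined and reported as missing.

## State comparisons

Count matrices aggregate summed PSM counts per (razor protein, sample) by
default — per-protein "peptide count" in abundance tables aggregates
spectral matches — with a distinct-row mode for sensitivity analysis.
Counts are log2(x+1)-transformed before clustering distances, otherwise a
handful of abundant proteins dominate the geometry. Clustering is
agglomerative with Euclidean distance and average linkage (correlation
distance and complete/single linkage available); at equal merge distance
the lexicographically smallest label pair merges first, making the
dendrogram deterministic. The agglomeration loop is written here because
that tie-break is part of the contract; it is cross-checked against
scipy's linkage on tie-free inputs in the tests.

Property distributions are compared with a Kruskal–Wallis omnibus across
states followed by two-sided Wilcoxon rank-sum tests for designated pairs
(fresh vs cooked, unburied vs buried). Exact p-values are used when the
combined sample size is ≤ 20 and the data are tie-free; otherwise the
normal approximation with tie correction. The reported statistic is the
smaller of the two group rank sums. Pairwise p-values are reported raw; a
Benjamini–Hochberg column can be added downstream by the caller.

UpSet-style intersections report exclusive membership counts: each
element of the union belongs to exactly one combination, so the counts
partition the union (asserted property).

## The synthetic extractome generator

The generator exists so the full analysis is exercisable and auditable
against ground truth with no external data. It emulates:

* **Reference structure** — species leaves under per-lineage
  family/order/kingdom nodes; a `shared_fraction` of each taxon's
  proteins are orthologs copied across taxa with a small per-site
  substitution rate (default 0.02), so some tryptic peptides are
  identical across taxa and resolve to non-specific LCAs; contaminant
  (keratin-like) entries live under a separate contaminant kingdom.
  Protein sequences draw residues from UniProt-average background
  frequencies; lengths are Poisson around `mean_length` (default 400).
* **Annotations** — secondary structure sampled from the published
  34 : 21 : 20 : 11 : 9 : 4 : 1 : 0 background ratio
  (H : E : L : T : S : G : B : I); RSA ~ Beta(1.8, 2.5) (broad: cores and
  surfaces both common); disorder ~ Beta(1, 3) and amyloid ~ Beta(1.2, 5)
  (right-skewed: most residues ordered/non-amyloidogenic);
  Tm ~ Normal(55 °C, 7 °C), the typical predicted melting-temperature
  range for mesophile proteomes.
* **Detection** — tryptic digestion (cleave after K/R unless P follows,
  ≤ 2 missed cleavages, length 7–45), per-protein log-normal abundance,
  and detection probability logit⁻¹(−2.0 + log abundance), i.e. roughly
  15% of a proteome's tryptic peptides detected per run — the sparse
  regime typical of single-shot LC-MS/MS. PSM counts are geometric with
  mean tied to protein abundance (heavy-tailed); a random 10% of proteins
  get a ×5 PSM multiplier in cooked samples, emulating the observed
  inflation of spectral matches for particular proteins after heating.
* **Survival** — peptide-level logistic retention across the
  fresh→cooked and cooked→buried transitions:
  p = logit⁻¹(β₀ + β_gravy·GRAVY + β_len·length), with
  β₀_cook = 2.5, β₀_bury = 1.5, β_gravy = 0.3, β_len = −0.08. Hydropathy
  and length are the only property effects wired into the default model —
  they are the consistently supported global effects; the other
  characteristics are carried as annotations and can be given
  coefficients by extending the logit. Ceramic samples multiply detection
  by `ceramic_yield` = 0.02, reproducing the sharp foodcrust-vs-ceramic
  recovery gap.
* **Nuisance processes** — heating deamidates each N/Q residue of
  retained cooked peptides independently (default rate 0.3; fresh
  baseline 0.01, a small nonzero background so fresh/cooked proportions
  are comparable); every non-wash sample receives keratin-like
  contaminant injections (default 30 peptides); co-fired samples receive
  a fraction (default 0.005) of each partner ingredient's virtually
  detected cooked peptides, themselves subjected to burial attrition in
  buried samples — cross-contamination deposits during cooking, before
  burial. At these defaults foodcrusts carry ~1% cross-contaminant load
  (analysable) while ceramics carry tens of percent (excluded), the
  outcome the analysis assumes. Washes carry 1% of the preceding run's
  peptides at PSM 1, giving the carry-over filter something to remove
  without dominating.

Randomness is structured as per-(sample, stage) child streams of one
seed: identical inputs give byte-identical bundles, and changing one
stage's parameter leaves other stages' draws untouched (common random
numbers), which is what makes the monotonicity property — raising
β₀_bury never shrinks a buried sample's peptide count — hold pointwise.

**What the generator does not emulate:** spectra, retention times,
FDR/decoy competition, soil proteome background, site-specific
deamidation kinetics, label-free quantification, and any correlation
between the annotation tracks and the sequence (structure tracks are
independent noise). Passing tests therefore demonstrate the *pipeline's*
correctness and the recoverability of effects the generative model
encodes — not that real foodcrust data satisfy the model.

## Problem sizes and statistical checks

The test suite and acceptance script run simulations at desk scale,
chosen as the package's own study conditions: the default reference is
3 taxa × 40 proteins (~3,800 tryptic peptides per taxon, ~600 detected
per fresh sample); power and calibration studies of the burial GRAVY
comparison use 130 proteins/taxon (~12,000 tryptic peptides, ~1,400–1,700
detected per sample), 3 replicates per state, 50 seeds for the
effect-recovery sweep (β_gravy = 0.6; rejection with positive shift
required in ≥ 90% of seeds) and 500 replicates for null calibration
(rejection rate required within [0.02, 0.09] at α = 0.05). The sparse
detection regime matters here: if detection were near-census of the
digest, both compared groups would be near-complete copies of one finite
peptide pool and the rank test would be grossly conservative under the
null.

## Known limitations

* Peptide matching is against the supplied proteomes only; a
  Unipept-style lookup against the full public database can only be less
  specific. Taxa absent from the supplied tree are reported as
  unassigned, not resolved.
* The evidence dialect is a documented, search-engine-agnostic TSV; it
  does not reproduce any vendor's exact column set.
* Retention coefficients are not calibrated to absolute archaeological
  rates (one burial experiment, one climate cannot constrain them);
  defaults reproduce the qualitative recovery ordering
  fresh ≥ cooked foodcrust > buried foodcrust ≫ ceramic, not
  quantitative counts.
* Wilcoxon/Kruskal–Wallis on pooled peptide rows treat rows as
  independent; rows of the same peptide in different replicates are
  correlated, which makes the tests conservative rather than
  anti-conservative in the regimes used here (verified by the null
  calibration study).
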