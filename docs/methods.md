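# Methods

This note documents the models and procedures implemented in `immunoscape`,
the parameters that matter, the numerical choices, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Enrichment scoring

For a sample with *G* genes, expression values are converted to
rank-normalized values (G − r + 1)/G where *r* is the descending rank (ties
take their average rank; exact ties are ordered by gene name so the ranked
universe is deterministic). Given a gene set *S* with |S ∩ L| = N_h genes in
the universe, the running sum after position *i* is

    RS_i = Σ_{j ≤ i, hit} v_j^α / Σ_{hit} v^α  −  (# misses ≤ i) / (G − N_h)

and the enrichment score is ES(S) = (Σ_i RS_i) / G — the running sum
integrated over the whole list and normalized by the universe size. The
statistic is the integrated form (not the maximum deviation), which is what
the final division by the number of genes presupposes.

Parameters:

* `alpha` (default 0). At 0 every hit contributes equally and RS is exactly
  ECDF_hit − ECDF_miss; at 0.25 hits are weighted by their rank-normalized
  value, matching the convention of widely used ssGSEA implementations. The
  default follows the unweighted running-sum description the scoring method
  is based on; both are exposed because the literature is not unambiguous
  about the exponent.
* `protein_coding` — optional gene list restricting the universe. The
  statistic's denominator is "all genes in the matrix"; restricting to
  protein-coding genes is the caller's responsibility and this hook does it.
* Signature genes missing from the matrix are dropped with a warning as long
  as at least one remains (gene-symbol drift across annotation releases is
  routine); zero overlap is an error.

Properties enforced by tests: equivalence with an independently coded
integrated-ECDF oracle to 1e-9; invariance under strictly monotone
transforms of expression; sign symmetry (a set at the bottom of the list
mirrors the same set at the top); zero mean under random placement.

## Signature construction

Candidate markers for a cell type are filtered by three statistics computed
on pure-cell data:

* **ARS** — mean within-sample rank percentile 1 − (r − 1)/(G − 1) across
  cognate samples; 1 means the gene is the top-expressed gene of every
  cognate sample. Rank-based, hence platform-robust.
* **MES** — (cognate mean − max non-cognate type mean) / pooled within-type
  SD. The pooled SD is sqrt(Σ (n_i − 1) s_i² / (N − k)). A positive MES means
  no other lineage expresses the gene as highly; the best *competing* type is
  used rather than the average so that genes shared by two lineages are
  penalized. The exact marker statistics in the literature this design
  follows are not fully specified; ARS and MES as implemented here are this
  package's concrete, testable definitions with the same selection intent.
* **Median cognate expression** in a second (e.g. RNA-seq) data set, so the
  marker is expressed across platforms.

Defaults: `ars_min 0.9`, `mes_min 1.0`, `expr_min 1.0` (FPKM-scale),
`max_genes_per_type 25`. These are deliberate, overridable choices — the
source analysis quantifies none of them ("minimal" signatures are not given
a size). Survivors are ranked by MES, capped, and made globally disjoint by
assigning each gene to the type where its MES is largest (ties broken by
type name). Zero pooled SD with unequal means is a degenerate-input error at
the single-gene API; in the vectorized table it maps to signed infinity (the
noise-free limit), so noiseless synthetic data still ranks correctly.
Manual curation is supported as allow/deny gene lists, not automated.

## Landscape operations

* **Quartiles** are global: all scored samples are sorted descending by one
  cell type's score and split into four groups differing in size by at most
  one, remainders going to the higher-score quartiles and boundary ties
  broken by sample ID (determinism). Occupancy is each cancer's fraction of
  samples per quartile, so a cancer's row sums to 1.
* **Correlations** (co-infiltration, chemoattractant-vs-infiltration) are
  Pearson with two-sided p-values; constant columns yield NaN with a
  warning rather than an error.
* **Stage trends**: pathological stage strings collapse to ordinal 1–4 by
  their leading roman or arabic numeral (sub-stage letters dropped); stages
  with fewer than 2 samples are excluded from the one-way ANOVA and cancers
  with fewer than 2 usable stages are skipped.
* **Clustering** is agglomerative with Euclidean distance and complete
  linkage on the 8 score dimensions, cut at k (default 4). Samples are
  processed in lexicographic order and clusters relabelled by smallest
  member, so the partition is invariant to input row order. The dendrogram
  is exported as newick.

## Mutation–infiltration association

Per (cancer, gene, cell type), carriers vs non-carriers are compared with a
Welch two-sample t-test — the unequal-variance form is the robust default
for the heavily unbalanced carrier groups typical of mutation data, and
"t-test" alone does not pin down the pooled form. `min_carriers` defaults
to 5; below that the test is meaningless. Two significance conventions
appear in practice (0.05 and 0.005); the stricter 0.005 is the default
`alpha` and both are reachable by flag. Raw p-values are the filter, as is
common in pan-cancer association screens, but a Benjamini–Hochberg column is
always emitted alongside for honest reuse. `variant_level=True` groups by gene + protein change instead
of gene, since "mutation in gene X" and "specific substitution" are both
legitimate carrier definitions.

## Survival analysis

* **Stratified survival**: per cancer, the top ceil(f·n) and bottom
  floor(f·n) samples by score (default f = 0.2, ties by sample ID) form the
  high/low arms; cancers with an arm below `min_group` (default 30) are
  dropped. Kaplan–Meier curves, the log-rank test and a univariate Cox fit
  of the high/low indicator (HR with 95% CI) are reported. With f = 0.5 the
  ceil/floor split partitions every sample. The dual-cell variant intersects
  the arms of two cell types.
* **Differential screen**: fold change (mean_a + 1)/(mean_b + 1) with a
  pseudo-count of 1 on FPKM-scale means; genes with FC > 2 (or < 1/2) are
  reported. Outcome groups are taken from vital status directly, which
  carries an immortal-time caveat: longer follow-up mechanically inflates
  the chance of being observed "deceased".
* **Activation score**: Σ w_i x_i / Σ w_i, w_i = 1/Var(x_i). Weights are
  computed on the analysis cohort by default (reproducible without any
  external reference) and can be frozen from a reference cohort for
  transfer. Zero-variance genes are excluded with a warning. The deprecated
  symbol CTSL2 resolves to CTSV via an alias map.
* **Optimal cutoff**: all midpoints between consecutive unique score values
  with both arms ≥ `min_group` (default 10% of n) are scanned; at each, a
  univariate Cox model of the indicator is fitted and the cutoff with the
  largest |log HR| wins, ties broken toward the more balanced split, then
  the smaller cutoff. The arm floor is essential — unconstrained
  maximization degenerates to extreme splits. The per-cutoff fits use an
  in-package Newton solver for the one-covariate Cox partial likelihood
  with Efron tie handling (log-likelihood step-halving, trust region of 5
  per step, |beta| capped at 20 to handle monotone likelihoods); tests
  verify it against exhaustive lifelines-based search. This is a
  post-selection procedure: the log-rank p at the chosen cutoff is
  anti-conservative (a dedicated test documents the inflation), and no
  correction is applied — downstream users should validate the cutoff on
  independent data.
* **Adjusted Cox**: lifelines proportional-hazards fit with covariates
  activation (binary indicator, or continuous z-scored per SD), age in
  years, and stage as an ordinal 1–4 covariate (categorical encoding by
  flag; ordinal is the parsimonious default for four ordered levels).
  Univariate fits per covariate are reported alongside.

## Synthetic data

The generators define the test conditions for the whole package.

* **Pure cells** (`simulate_pure_cells`): 8 cell types, 25 markers each,
  400 background genes, 20 samples per type by default. Expression is
  log-normal: exp(μ + σZ) with marker mean μ = 4 (≈ 55 on the FPKM scale)
  in cognate samples, background mean μ = 1 (≈ 2.7) elsewhere, σ = 0.5.
  These defaults emulate a purified-immune-cell compendium with clearly
  expressed, specific markers and realistic right-skewed noise. Marker sets
  are disjoint by construction.
* **Bulk mixtures**: fractions for the 8 immune types plus one tumor
  component are Dirichlet (flat by default); each bulk column is the
  fraction-weighted combination of mean pure-cell profiles plus an
  independent random tumor profile, times log-normal noise (σ = 0.25).
  The tumor profile is independent of the immune profiles so that
  epithelial content does not entangle the immune ground truth. Optional
  knobs plant positive co-infiltration (a shared gamma component added to
  two types' Dirichlet draws) and chemoattractant genes whose expression is
  proportional to a type's fraction.
* **Clinical tables**: exponential event times under a proportional-hazards
  model, hazard = baseline · exp(β_act z + β_age age′ + β_stage stage′)
  with standardized covariates; independent exponential censoring; ages
  uniform 40–80; stages 1–4 with probabilities (0.35, 0.30, 0.20, 0.15),
  roughly the early-stage skew of pan-cancer cohorts. A `confound_age` knob
  (years per SD of activation) couples age to the activation covariate so
  tests can separate adjusted from unadjusted estimates. Defaults:
  baseline 1e-3/day, censoring 5e-4/day.
* **Mutations**: per effect gene, carrier probability
  sigmoid(logit(base_rate) + shift · z) of the standardized score of the
  gene's coupled cell type; decoy genes mutate at the base rate.

What the generators do **not** emulate: batch and platform effects,
probe-level microarray artifacts, gene-gene correlation structure beyond
the planted markers, non-proportional hazards, informative censoring,
tumor purity gradients within a cancer type, or realistic mutational
signatures. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
failure mode of real cohorts.

## Problem sizes and numerics

The test suite and the reproduction script run on deliberately compact
cohorts — 160 pure-cell samples, 120–300 bulk mixtures, n = 1000 survival
cohorts over 50 replicates, 40–100-sample cutoff instances — sizes at which
every stochastic check has comfortable power while the full suite completes
in a few minutes. Oracle comparisons use 1e-9 tolerances; determinism is
byte-exact for equal seeds. All randomness flows through
`numpy.random.default_rng` with explicit integer seeds.

## Known limitations

* Enrichment scores are relative within a sample and cohort; they are not
  calibrated cell fractions and should not be compared across universes of
  different size or content.
* The gene-level association tests ignore mutation functional class;
  carrier status is taken at face value.
* The HR-maximizing cutoff is reported without selection-corrected
  inference (by design, mirroring common practice; see above).
* Signature building assumes pure-cell inputs; applying it to mixed samples
  will produce diluted, non-specific markers.
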