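# immunoscape

Immune-cell enrichment scoring and immunogenomic landscape analysis for bulk
tumor transcriptomes.

Bulk tumor RNA-seq mixes malignant, stromal and immune cells. `immunoscape`
estimates the infiltration of eight immune cell types (CD8+ and CD4+ T cells,
Tregs, B cells, NK cells, macrophages, monocytes, neutrophils) from a
gene × sample expression matrix, without full deconvolution: each cell type is
represented by a small, disjoint marker signature, and each sample is scored
by how strongly that signature concentrates at the top of the sample's
expression ranking. On top of the scores, the package stratifies the immune
landscape of a cohort (quartiles, co-infiltration correlations, stage trends,
hierarchical clustering), tests mutations for association with infiltration,
and links CD8+ T-cell functional state to survival. It is aimed at
computational biologists analyzing TCGA-style cohorts or their own bulk
expression data.

## The statistics at the core

**Enrichment score.** For one sample, expression values are rank-normalized:
the gene with rank *r* among *G* genes gets the value (G − r + 1)/G (ties get
average ranks). Walking down the ranked universe *L*, a running sum rises by
v^α / Σ_hits v^α at every gene of the set *S* and falls by 1/(G − |S|)
elsewhere; the enrichment score is the mean of the running sum over all *G*
positions,

    ES(S) = (1/G) Σ_i RS_i .

With the default α = 0 this is exactly the integrated difference of the hit
and miss empirical CDFs; α = 0.25 gives the rank-weighted convention of common
ssGSEA implementations. ES > 0 means *S* concentrates among the sample's most
expressed genes. Only ranks enter the statistic, so scores are invariant to
monotone normalization differences (FPKM vs RSEM vs log).

**Signature construction.** From pure-cell profiles, candidate markers are
ranked by the average rank score (ARS — mean within-sample rank percentile in
the cognate cell type) and the marker evaluation score (MES — cognate mean
minus best non-cognate mean, over the pooled within-type SD), filtered by a
median-expression floor, capped per type, and made globally disjoint.

**T-cell activation score.** An inverse-variance-weighted mean of TCR-signaling
gene expression, score = Σ w_i x_i / Σ w_i with w_i = 1/Var(x_i), over the
panel GRAP2, CD247, CD3E, CD3D, ZAP70, CD8B, CD1C, TDGF1, TCF7, SH2D1A, LCK,
CTSL2 (CTSV). Patients are dichotomized at the cutoff maximizing the absolute
log hazard ratio (subject to a minimum arm size) and assessed with age- and
stage-adjusted Cox proportional-hazards regression.

## Worked example

Everything below runs on synthetic data with planted ground truth — the
package ships its own generators, so the example is fully reproducible.

```python
import numpy as np, pandas as pd
import immunoscape as im
from immunoscape import signature_builder as sb, ssgsea_engine as se
from immunoscape import prognosis_pipeline as pp

# pure immune-cell profiles with planted markers; build signatures from them
pure = im.simulate_pure_cells(im.SimulationConfig(seed=42))
sigs = sb.build_signatures(pure.expression, pure.labels)

# 300 bulk mixtures with known immune fractions; score them
bulk, truth = im.simulate_bulk_mixtures(pure, 300, seed=43)
scores = se.score_matrix(bulk, sigs)
print(scores.head(3).round(3))
```

```
               B    CD4    CD8  Macrophage  Monocyte     NK  Neutrophil   Treg
sample_id
BULK.0000  0.446  0.213  0.311       0.029     0.399  0.153       0.489  0.399
BULK.0001  0.496  0.189  0.321       0.454     0.393  0.263       0.213  0.316
BULK.0002  0.484  0.387  0.077       0.471     0.244  0.006      -0.036  0.174
```

Each row is one tumor; each column the enrichment of one immune cell type.
The planted CD8 fraction and the recovered CD8 score agree at Spearman
rho = 0.989. Now attach survival driven by the CD8 score with a planted
hazard ratio of 0.5 per SD and fit the adjusted Cox model:

```python
act = pd.Series(scores["CD8"].to_numpy(), index=scores.index)
clin = im.simulate_clinical(300, im.SurvivalTruth(beta_activation=np.log(0.5)),
                            act.to_numpy(), seed=46, sample_ids=list(scores.index))
res = pp.cox_adjusted(act, clin)
print(res.multivariate.round(4))
cut = pp.optimal_cutoff(act, clin)
print(f"cutoff={cut.cutoff:.4f} HR={cut.hazard_ratio:.3f} "
      f"n_high={cut.n_high} n_low={cut.n_low}")
```

```
                  hazard_ratio  ci_lower  ci_upper       p
covariate
activation_score        0.4763    0.4052    0.5598  0.0000
age                     1.0089    0.9963    1.0218  0.1682
stage                   1.0037    0.8837    1.1400  0.9544
cutoff=0.0637 HR=0.185 n_high=254 n_low=46
```

The adjusted model recovers the planted protective effect (HR 0.48, CI
covering 0.5) while age and stage, simulated without effect, stay null. The
dichotomized hazard ratio at the optimal cutoff is more extreme than the
per-SD effect — expected, since the cutoff is chosen to maximize it; treat
post-selection p-values with care.

The same operations are available from the shell:

```bash
immunoscape simulate pure --seed 42 --out sim/
immunoscape build-signatures --rnaseq sim/pure_expression.tsv \
    --labels sim/pure_labels.tsv --out markers.gmt
immunoscape score --expr bulk.tsv --gmt markers.gmt --out scores.tsv
immunoscape survival strat --scores scores.tsv --clinical clinical.tsv \
    --cell-type CD8 --out survival.tsv
```

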