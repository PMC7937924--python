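# stabmark

Stability-driven biomarker discovery from blood gene-expression cohorts.

The package implements an end-to-end discovery pipeline for predicting a
binary clinical outcome (e.g. a complicated sepsis course) from
log2-scale expression matrices:

1. **Preprocessing** — quantile normalization, surrogate-variable
   diagnostics, parametric empirical-Bayes batch adjustment and
   probe-to-gene collapsing (`stabmark.preprocess`).
2. **Differential expression** — two-group moderated-t with
   Benjamini–Hochberg FDR control and fold-change filters
   (`stabmark.dge`).
3. **Variable selection** — random-forest importance, L1-logistic and
   mRMR selections pooled with the DEG list and clinical covariates,
   then recursive feature elimination (`stabmark.selection`).
4. **Class-imbalance resampling** — SMOTE, random undersampling,
   cluster centroids, ENN/RENN and instance-hardness thresholding, all
   with explicit provenance (`stabmark.imbalance`).
5. **Repeated stratified cross-validation** — per-fold selection,
   AUROC-scored grid tuning and training; features surviving RFE are
   tallied into a normalized stability score (percentage of the R·K
   iterations in which a feature was selected)
   (`stabmark.stability_cv`).
6. **Evaluation** — sensitivity/specificity/FPR/MCC/AUROC, fine
   threshold sweeps, two-sample Kolmogorov–Smirnov tests (with a
   bootstrap/permutation variant for small cohorts) and Gaussian KDE
   summaries (`stabmark.evaluation`).
7. **External validation** — train-on-derivation, test-on-external
   cohort with cross-platform feature alignment, per-gene z-scoring and
   dual (honest / post-hoc) threshold reporting
   (`stabmark.external_validation`).

A synthetic-data module (`stabmark.synthetic_data`) generates cohorts
with planted differential expression, batch shifts, an outcome-correlated
severity score and nested mortality, so the full pipeline is testable
without any external download.

## Command line

Every subcommand takes `--seed`, `--config` (JSON, see
`stabmark.io_config.RunConfig` for keys and defaults) and `--out`
(output directory). The resolved configuration is written next to the
outputs.

```sh
# synthetic derivation + attenuated validation cohort
stabmark simulate --seed 1 --out runs/sim --attenuation 0.5

# batch adjustment with surrogate-variable diagnostics
stabmark preprocess --seed 1 --out runs/prep \
    --expr runs/sim/expression.tsv --pheno runs/sim/phenotype.csv

# differential expression
stabmark dge --seed 1 --out runs/dge \
    --expr runs/prep/expression_adjusted.tsv --pheno runs/sim/phenotype.csv

# repeated-CV discovery with stability scores (5-fold x 10 repeats)
stabmark discover --seed 1 --out runs/disc \
    --expr runs/prep/expression_adjusted.tsv --pheno runs/sim/phenotype.csv

# external validation of a feature panel
stabmark validate --seed 1 --out runs/val \
    --derivation-expr runs/prep/expression_adjusted.tsv \
    --derivation-pheno runs/sim/phenotype.csv \
    --validation-expr runs/sim/validation_expression.tsv \
    --validation-pheno runs/sim/validation_phenotype.csv \
    --panel runs/disc/shortlist.txt

# per-feature class-wise KS table
stabmark ks-report --seed 1 --out runs/ks \
    --expr runs/prep/expression_adjusted.tsv --pheno runs/sim/phenotype.csv
```

Expression matrices are TSV (genes as rows, first column the gene id,
header row the sample ids) or the value block of the GEO series-matrix
text dialect; phenotype tables are CSV with at least `sample_id` and
`outcome` (`complicated` / `uncomplicated`) columns.

## Notes and limitations

- Probe-level array background correction is out of scope; quantile
  normalization of the provided matrix is the declared stand-in.
- Batch adjustment uses the declared batch label; surrogate variables
  are reported as a diagnostic, not regressed out.
- Enrichment analysis (GO/KEGG/Reactome) and figure aesthetics are out
  of scope; the pipeline emits the underlying tables.
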