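# immunosig

A tested, reusable pipeline for building immunotherapy-response gene
signatures from single-cell and bulk transcriptomics:

- **Single-cell core** (`immunosig.sc_core`): QC filtering (detected-gene
  bounds, mitochondrial fraction, rare genes), library-size log
  normalization, SNN-graph community clustering, Wilcoxon rank-sum
  marker derivation (exact enumeration for small groups), per-patient
  composition tables, and a normality-driven two-group test selector.
- **CNV scoring** (`immunosig.cnv_score`): reference-centered
  moving-average copy-number profiles along the genome (window 100,
  expression cutoff 0.1, per-chromosome smoothing) with a per-cell
  burden score to separate malignant from reference cells.
- **Gene-set scoring** (`immunosig.geneset_scoring`): bin-matched
  control module scores per cell plus subgroup ranking with pairwise
  tests.
- **Signature construction** (`immunosig.signature_builder`):
  empirical-Bayes batch adjustment, per-gene Welch t-tests giving the
  responder-up gene list Gx, intersection with four subgroup marker
  lists (MM.sig, B.sig, DC.sig, CAF.sig) and their union
  (Comprehensive.sig).
- **Model harness** (`immunosig.model_harness`): a 7-algorithm x
  5-signature grid (SVM, Gaussian naive Bayes, random forest, KNN,
  AdaBoost, boosted logistic stumps, and a correlation-to-centroid
  classifier) tuned by repeated stratified 5-fold CV AUC, selected by
  held-out test AUC, with an 80/20 stratified cohort split and a
  rank-formulation AUC.
- **Survival** (`immunosig.survival_eval`): Kaplan-Meier estimation,
  log-rank testing, and PD/NPD -> high/low-risk stratification.
- **Synthetic data** (`immunosig.synthetic_data`): seeded generators for
  a multi-patient single-cell cohort (planted subgroup markers,
  mitochondrial content, chromosomal gain/loss segments confined to
  malignant cells) and a pooled pre-treatment bulk cohort (planted
  response signal, batch effects, censored exponential survival), so
  every stage is testable with no external downloads.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the structural/worked-example
acceptance criteria (grid cardinality, split arithmetic, exact-test
oracles, CNV worked examples, signature recovery, model-selection
sanity, survival power, end-to-end determinism). Large simulations are
desk-scaled; the full suite runs in well under half an hour on one CPU.

## CLI

```bash
immunosig simulate --seed 0 --out data/            # synthetic file set
immunosig sc-qc --data data --out qc/              # filter + lognorm
immunosig sc-cluster --data qc --out clusters.tsv
immunosig sc-markers --data qc --clusters clusters.tsv --out markers.tsv
immunosig cnv --data qc --cells qc/cell_annotation.tsv --out cnv.tsv \
    --window 100 --cutoff 0.1 --reference CD8T
immunosig score --data qc --gmt sets.gmt --out scores.tsv
immunosig build-sig --cohort expr.csv --clinical clin.tsv \
    --markers markers.gmt --out sigs.gmt
immunosig train --cohort expr.csv --clinical clin.tsv \
    --signatures sigs.gmt --out models/ --seed 7
immunosig survival --predictions preds.tsv --clinical clin.tsv --out surv/
```

File formats: Matrix Market + gene/cell TSV sidecars for expression,
GMT for gene sets, samples x genes CSV plus a clinical TSV
(`sample_id`, `response` in {PD, NPD}, `batch`, `os_time`, `os_event`)
for bulk cohorts.

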