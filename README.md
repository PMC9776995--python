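# rccc-pred

A reproducible pipeline for three-class classification of DNA gene sequences
(kidney-tumor driver vs. other-tumor driver vs. unknown/non-driver):

1. **Benchmark construction** — apply a catalog of single-nucleotide
   substitutions (CSV: `gene_id,position,ref,alt,label`) to reference
   sequences (FASTA), prune near-identical sequences with greedy
   longest-first identity clustering, and split 70:30 with stratification.
2. **Feature extraction** — embed each sequence in the smallest square
   matrix that holds it, compute raw, central and discrete orthogonal Hahn
   moments up to combined order 3 (30 values), then summarize them into a
   6-value vector `[M1, M2, M3, M4, Min, Max]`.
3. **Classification** — histogram gradient boosting (final model) plus a
   comparison suite (gradient boosting, random forest, decision tree,
   Gaussian naive Bayes, feed-forward neural net with early stopping and
   max 3000 iterations).
4. **Evaluation** — one-vs-rest specificity / sensitivity / accuracy / MCC
   with four protocols: self-consistency, stratified 10-fold CV (pooled
   out-of-fold scoring, per-fold accuracies, vertically averaged ROC),
   jackknife (leave-one-out), and an independent 70:30 split.

A seeded synthetic-data module generates references, consistent mutation
catalogs, and three-class datasets whose base composition separates by a
controllable `delta`, so the whole pipeline runs and is benchmarked fully
offline.

## CLI

All stages are exposed through one entry point (`rccc-pred --help`):

```sh
# generate a separable synthetic dataset (FASTA + label CSV)
rccc-pred synth --mode dataset --n 100 --delta 0.9 --seed 1 --out-dir fixtures/

# or: synthetic references + a consistent mutation catalog, then build the benchmark
rccc-pred synth --mode catalog --n 50 --seed 1 --out-dir fixtures/
rccc-pred build-dataset --references fixtures/references.fasta \
    --catalog fixtures/catalog.csv --threshold 0.7 \
    --out fixtures/samples.fasta --labels fixtures/labels.csv

# features, training, prediction, evaluation
rccc-pred extract-features --sequences fixtures/samples.fasta \
    --labels fixtures/labels.csv --out fixtures/features.csv
rccc-pred train --features fixtures/features.csv \
    --algorithm hist_gradient_boosting --seed 1 --out fixtures/model.bin
rccc-pred predict --model fixtures/model.bin \
    --features fixtures/features.csv --out fixtures/predictions.csv
rccc-pred evaluate --features fixtures/features.csv --protocol cv --k 10 \
    --seed 1 --out fixtures/report.json --csv-summary fixtures/summary.csv
```

Exit codes: 0 success, 1 data/contract error, 2 usage error.  All
randomness flows from `--seed`; identical invocations produce byte-identical
outputs.  Flags override an optional `--config key=value` defaults file.

## Layout

```
src/rccc_pred/
  io_formats.py       FASTA / catalog CSV / feature-table CSV readers+writers
  dataset_builder.py  mutation application, redundancy filter, stratified split
  features.py         square embedding; raw/central/Hahn moments; 6-value summary
  model.py            classifier suite behind one train/predict interface
  evaluation.py       one-vs-rest metrics, 4 validation protocols, ROC
  synthetic.py        seeded generators for offline fixtures and benchmarks
  cli.py              click entry point
tests/                pytest suite (unit, property, acceptance criteria)
scripts/acceptance.py acceptance-target report
```
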