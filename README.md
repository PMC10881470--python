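# explantkit

Analysis toolkit for multimodal *ex vivo* checkpoint-inhibitor response
profiling of tumor-explant histocultures, driven by a seeded synthetic-cohort
generator. It implements, as tested and reusable components:

- **Normalization** — T0-normalized cytokine time courses, treated-vs-control
  fold changes (cytokines, histology, viability), housekeeping geometric-mean
  count normalization, the baseline tumor-content qualification filter and the
  PD-L1 combined positive score (`explantkit.normalization`).
- **Stratification** — seeded t-SNE embedding of the 10-parameter log2
  fold-change matrix, a 2-means primary responder split, and the rule-based
  reinvigoration / cytotoxicity phenotype classifier producing the SC1 /
  SC2a–d sub-cohorts with a strict > 1.2 fold-change relevance threshold
  (`explantkit.stratification`).
- **Gene signatures** — per-gene Wald differential expression on log2
  normalized counts, p < 0.05 filtering, PC1-loading (> 0.7) selection, panel
  intersection, GES scoring (mean log2 counts), rank-based ROC with the
  Youden-cutoff rule, Kaplan–Meier / log-rank survival splits, row z-scoring,
  Euclidean hierarchical clustering and Spearman correlation
  (`explantkit.signatures`).
- **Spatial statistics** — union-of-disks tumor-region reconstruction from
  panCK+ cell coordinates, per-CD8 distances to the tumor region and to the
  nearest FoxP3 cell, Mann–Whitney distance-shift calls and phenotype counts
  (`explantkit.spatial`).
- **Synthetic cohorts** — seeded generation of all of the above modalities
  with class-dependent effect sizes and ground-truth response classes, an
  exponential survival generator with score-dependent hazard, and the
  replicate-arm equivalence Monte-Carlo simulation
  (`explantkit.synthetic`).
- **IO / CLI / pipeline** — CSV readers/writers with schema validation, TOML
  configuration, provenance records, and an end-to-end pipeline
  (`explantkit.io`, `explantkit.pipeline`, `explantkit.cli`).

## CLI

```sh
# generate a synthetic cohort (CSV directory) + replicate-arm simulation
explantkit simulate --seed 1 --out cohort/ --arm-equivalence

# full pipeline: QC -> fold changes -> stratification -> signatures -> spatial
explantkit run-all --seed 1 --out results/

# individual stages
explantkit stratify --fc-matrix results/fc_matrix.csv --seed 1 --out strat/
explantkit signature derive --counts cohort/counts.csv \
    --columns cohort/counts_columns.csv --groups groups.csv --out sig/
explantkit signature validate --expression expr.csv --clinical clinical.csv \
    --signature sig/signature.json --out val/
explantkit spatial --cells cohort/cells.csv --out spatial/
```

Every run writes a machine-readable JSON summary and (for `run-all`) a
provenance record with the config hash, seeds and per-output digests.

Python usage mirrors the CLI:

```python
from explantkit.synthetic import CohortConfig, generate_cohort
from explantkit.normalization import build_fc_matrix
from explantkit.stratification import stratify_cohort, TsneParams

cohort = generate_cohort(CohortConfig(seed=1))
fc = build_fc_matrix(cohort.samples)            # samples x 10 log2 fold changes
labels = stratify_cohort(fc, TsneParams(seed=1))  # SC1 / SC2a-d per sample
```

## Conventions

- Coordinates are in µm, origin at the field's top-left.
- Fold-change thresholds are strict (`> 1.2`); the qualification filter is
  strict (`< 10%` tumor content fails).
- Tumor-content fold change is cytotoxicity-oriented (control / treated), so
  one `> 1.2` rule covers "tumor content decreased".
- All generators and the embedding are seeded; seeds are part of provenance.
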