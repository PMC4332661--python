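# cortsep

Group-separability analysis of interregional cortical-thickness
correlations. Given two cohorts of subjects with per-region cortical
thickness (70 bilateral Desikan–Killiany regions), the pipeline:

1. computes a cohort-wise 70×70 Pearson correlation matrix of regional
   thickness (structural covariance),
2. ranks region pairs by the absolute cross-cohort correlation difference
   and selects the top 15 as features,
3. re-evaluates those 15 correlations within 500 random six-subject
   subsets per cohort, yielding a 1000×15 feature matrix,
4. quantifies group separability with the minimal-spanning-tree
   (Friedman–Rafsky) estimate of the Henze–Penrose divergence, mapped to a
   separability score in [0.5, 1], cumulatively over the ranked features,
5. trains an L1-penalized (sparse) linear classifier under two protocols —
   Experiment 1 (random 700/300 row split, subjects may overlap) and
   Experiment 2 (subject-disjoint pools: 40 case / 24 control training
   subjects, remainder held out) — and reports bootstrap ROC curves,
6. renders correlation heatmaps, the separability curve, a 2-D PCA
   embedding and both ROC curves.

A synthetic-cohort generator (multivariate normal with planted,
positive-definite-repaired correlation structure; default: one
temporal-pole-like hub region strongly correlated with 15 neighbours in
the case cohort only) stands in for MRI-derived data, so the entire
pipeline is testable offline.

## CLI

```bash
cortsep simulate --seed 0 --out-dir out/            # two cohort TSVs + provenance
cortsep features  --case-table out/case.tsv --control-table out/control.tsv \
                  --k 15 --out out/features.tsv
cortsep featmatrix --case-table out/case.tsv --control-table out/control.tsv \
                   --features out/features.tsv --n-subsets 500 --out out/fm.csv
cortsep hpd --feature-matrix out/fm.csv --out out/hpd.json
cortsep classify --experiment 2 --n-boot 100 --seed 0 --out-dir out/
cortsep run --seed 0 --out-dir out/                 # full pipeline + figures
```

`cortsep run` accepts `--config config.yaml` (YAML or JSON) where every
protocol constant (feature count, subset size, subset counts, split
sizes, pool sizes, penalty grid, CV folds, bootstrap replicates, seed)
can be overridden; defaults mirror the study protocol. Runs are
deterministic given the master seed.

Input tables are tab-separated: either the FreeSurfer `aparcstats2table`
dialect (columns `lh_bankssts_thickness`, …, first column = subject ID)
or a plain dialect (`subject_id`, optional `cohort`, columns
`lh_bankssts`, …). Column order is irrelevant; non-atlas columns are
ignored with a warning.

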