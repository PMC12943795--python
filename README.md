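# immunexpo

A reusable pipeline for exposure–immunome–omics association studies:

- **synthetic** — seeded synthetic cohorts (correlated exposure blocks,
  covariate/batch/seasonal effects on phenotypes, right-skewed columns, MCAR
  missingness, planted exposure→mediator→outcome chains in both directions)
  with exact ground truth for parameter-recovery testing.
- **preprocess** — skewness-gated cleaning (reflection of left-skewed columns
  at |skew| > 2.15, iterative long-tail outlier removal), sampling-day batch
  correction via shrunken random-intercept estimates, rank-based inverse
  normal transform (Blom offsets) for |skew| > 1, kNN imputation (k = 5),
  SD clipping, detection filters, energy-extreme exclusion and PDI/hPDI/uPDI
  diet-index scoring from 16 food groups.
- **variance** — PERMANOVA variance decomposition of the immunome distance
  matrix (single-factor scans and sequential multi-factor models, 1,000
  permutations), BH-FDR screening and |Spearman r| > 0.4 redundancy pruning.
- **ewas** — exposure-wide association via covariate-adjusted linear models
  (coefficient t-test + LRT, BH-FDR across all pairs), gender/age strata,
  90%/80% subsample stability, sensitivity covariate sets (BMI, genetic PCs),
  age/gender/season basic-factor tests and 12-month cosinor fits.
- **composite** — composite-exposure latent variables: thresholded Spearman
  matrix (Bonferroni + |r| > 0.2), Ward clustering, PLS path model (mode A,
  saturated inner model, centroid scheme), cluster count grown until no LV
  pair is significantly correlated.
- **mediation** — bidirectional mediation with interaction
  (y ~ x + m + x·m): ACME = β1·β2, ADE = γ1, mediation proportion
  ACME/(ACME+ADE), 1,000-draw row-resampling bootstrap CIs, dual-FDR
  candidate screening, and D1/D2 direction classification.
- **indexes** — mediation-proportion-weighted omics signatures (T-/M-index):
  per-feature PropSum weights (signed mediation proportions), per-sample
  weighted sums, outcome GLMs, rank-sum group tests and transfer to external
  cohorts on overlapping features.
- **pipeline / cli** — end-to-end orchestration with one seed, per-stage
  substreams, TSV/JSON artifacts and a SHA-256 manifest.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(oracle equivalence, parameter recovery, calibration, determinism); the rest
are per-module unit and property tests. One acceptance sub-assertion
(cluster-count selection stopping at the planted block count) is expected to
fail by construction of the stopping rule; see the test and module notes.

## CLI

```bash
immunexpo simulate   --config cohort.yaml --out data/ --seed 1
immunexpo preprocess --in data/ --config qc.yaml --out clean/
immunexpo variance   --pheno clean/phenotypes.tsv --exposures clean/exposures.tsv \
                     --covars clean/covariates.tsv --nperm 1000 --seed 1 --out variance.tsv
immunexpo ewas       --pheno clean/phenotypes.tsv --exposures clean/exposures.tsv \
                     --covars clean/covariates.tsv --out ewas.tsv [--stratify gender]
immunexpo composite  --exposures clean/exposures.tsv --out composite/ --rmin 0.2
immunexpo mediate    --pairs pairs.tsv --exposures clean/exposures.tsv \
                     --pheno clean/phenotypes.tsv --omics clean/omics.tsv \
                     --nboot 1000 --seed 1 --out mediation.tsv
immunexpo index      --records mediation.tsv --omics clean/omics.tsv \
                     --exposure EXP001 --out index/
immunexpo run        --config pipeline.yaml --out run1/    # all stages
immunexpo validate   --config pipeline.yaml
```

All tables are tab-separated with a header row and `NA` for missing values.
`immunexpo run` writes a `manifest.json` whose content hashes are
bit-identical across runs with the same config and seed.

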