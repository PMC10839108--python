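# cortivar

Analysis pipeline for hair-cortisol concentration (HCC) cohorts of
finishing pigs sampled in batches across farms: variance partitioning,
farm typology, and an exhaustive subsampling study of how mean and SD
estimates degrade with batch sample size.

## What it does

Given a long-format pig-level table (`farm_id, batch_id, pig_id,
hcc_pg_mg`), the package provides:

- **`cortivar.cohort`** — validated data model, CSV readers/writers,
  per-(farm, batch) summaries (n, mean, SD, CV).
- **`cortivar.simulate`** — synthetic cohorts with a prescribed hierarchical
  variance structure (farm / batch / farm-by-batch / residual fractions),
  additive-Gaussian or lognormal noise, dropout, seeded determinism. Every
  downstream stage is testable against known ground truth.
- **`cortivar.anova`** — sequential (Type I) two-way ANOVA in the fixed
  order batch → farm → batch:farm with eta-squared per term, residual
  diagnostics (Shapiro–Wilk, Levene, QQ coordinates), Tukey–Kramer
  within-farm batch comparisons, combined-sample Cohen's d, and the
  batch-level mean–SD regression.
- **`cortivar.typology`** — standardized PCA of the 4-column active matrix
  (per-farm batch means and SDs), Ward hierarchical clustering on component
  scores, and v.test cluster characterization for quantitative and
  categorical (hypergeometric) variables.
- **`cortivar.subsample`** — for each batch, every subsample of sizes
  {5, 10, 15, 20} (exact enumeration up to a cap, seeded Monte Carlo
  beyond it), relative differences of means and SDs versus the full batch,
  and 5/50/95-percentile summaries per batch and averaged across batches.
- **`cortivar.cli`** — pipeline runner writing CSV/JSON artifacts with a
  hashed manifest, plus a report renderer.
- **`cortivar.reference`** — the published 20-farm summary table bundled as
  a worked example and validation input.

## CLI

```bash
# synthetic cohort shaped like the reference study design (950 pigs)
cortivar simulate --seed 1 --out cohort.csv

# individual stages or everything; artifacts + manifest.json in --out-dir
cortivar summaries cohort.csv --out-dir out
cortivar anova cohort.csv --out-dir out
cortivar typology cohort.csv --out-dir out --k 3
cortivar subsample cohort.csv --out-dir out --sizes 5 --sizes 10
cortivar all cohort.csv --out-dir out --seed 1

# human-readable summary of a finished run
cortivar report out/manifest.json
```

Options can also be supplied as a JSON file via `--config`. Running a stage
command without a cohort path generates the synthetic study-design cohort
from `--seed`.

## Conventions worth knowing

- Sums of squares are sequential (Type I); with unbalanced cells the term
  order (batch, farm, batch:farm) is part of the contract.
- Descriptive SDs use denominator n−1 throughout; the v.test uses the
  population variance (denominator N), which is what reproduces the
  published cluster statistics.
- Cohen's d divides by the SD of the combined two-batch sample
  (reconstructed from summary statistics), not the pooled within-group SD.
- Exact subsample enumeration is capped at 2,000,000 subsets per
  (batch, size); larger problems fall back to seeded Monte Carlo with a
  logged notice.
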