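# dtmr — drug-target genetic risk scores and Mendelian randomization

`dtmr` is a Python toolkit for drug-target genetic association analysis of
treatment-response cohorts. It covers the full chain from genotype quality
control and drug-target genetic risk score (GRS) construction through
one-sample causal estimation (two-stage least squares), mediation by
conditioning, 2×2 factorial MR, two-sample summary-statistics MR estimators
(IVW, weighted median, Egger, a PRESSO-style outlier test), Bayesian
colocalization, and a regression-diagnostics protocol — exercised end-to-end
on a built-in synthetic cohort generator with known ground truth.

## Modules

| module | contents |
| --- | --- |
| `dtmr.simulate` | synthetic genotype panels (HWE hard calls, block LD), phenotypes (traits, PANSS-style outcomes), matched summary statistics, fixture suites |
| `dtmr.gwas_io` | summary-statistics / target-gene TSV I/O, allele harmonization (strand flips, palindromic resolution), region windowing |
| `dtmr.qc` | exact Hardy-Weinberg test, variant filters (missingness / MAF / HWE), sample filters (missingness / heterozygosity / PI-hat relatedness / PC outliers), exclusion-cascade ledgers |
| `dtmr.grs` | LD clumping, instrument selection, trait-lowering orientation, pQTL action-sign adjustment, weighted scores, R²/F instrument strength |
| `dtmr.onesample` | PANSS percentage reductions, covariate-adjusted linear/logistic fits with HC3 inference, trend tests, 2SLS, unit rescaling, stratified + interaction models, mediation conditioning, factorial groups/effects, BH/Bonferroni |
| `dtmr.twosample` | IVW (fixed/random), Cochran's Q, weighted median, Egger intercept test, PRESSO-style global/outlier test |
| `dtmr.coloc` | sliding-window LD pruning, Wakefield approximate Bayes factors, five-hypothesis posteriors with per-SNP PP.H4 and lead-variant reporting |
| `dtmr.diagnostics` | Breusch-Pagan / White tests, HC3 sandwich SEs, Cook's distance and studentized deleted residuals with refit, VIF, stable/sensitive classification |
| `dtmr.pipeline`, `dtmr.cli` | YAML-configured orchestration of every stage with seeded reproducibility |

## CLI

```bash
dtmr --seed 1 --outdir results run-all          # full synthetic pipeline
dtmr --config config.yaml --seed 1 qc           # one stage (runs prerequisites)
```

Subcommands: `simulate`, `qc`, `scores`, `assoc`, `factorial`, `mr2`,
`coloc`, `report`, `run-all`. A YAML config can override the simulation,
QC thresholds and instrument-selection rules; unknown keys are rejected.
Example:

```yaml
seed: 7
simulation: {n_samples: 2000, n_variants: 500, ld_rho: 0.3}
qc: {variant_maf_min: 0.01, hwe_p_min: 1.0e-6}
selection: {p_max: 5.0e-8, r2_max: 0.1, maf_min: 0.005, window_bp: 100000}
```

Artifacts (all plain text) land in the output directory: cohort and score
TSVs, QC ledgers, association/factorial/MR result tables, a colocalization
JSON, a diagnostics JSON, and a human-readable `report.txt`. Rerunning with
the same config and seed reproduces byte-identical tables.

## Library notes

Regression machinery (OLS/GLM fits, HC3 covariances, heteroskedasticity
tests, influence measures) is backed by statsmodels; the tests check each
against independently coded textbook-formula oracles. The MR estimators,
exact HWE test, LD clumping/pruning, scoring, colocalization enumeration and
the instrumental-variable variance are implemented in-package from their
defining formulas.
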