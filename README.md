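# oxiscan

Signature-based tumour hypoxia scoring and mixed-effect association scans
for multi-cancer cohorts.

Given a bulk expression matrix and one or more hypoxia gene signatures,
`oxiscan` assigns every tumour an integer hypoxia score (sum of ±1 votes,
+1 per signature gene whose abundance is above the cohort median), then
relates that score to genomic features — mutational density summaries,
binary driver status (SNV/CNA/SV/compound), mutational-signature exposure
proportions, and subclonal architecture — with Gaussian linear mixed
models carrying a cancer-type random intercept and purity/age/sex as
fixed adjusters. Every feature is assessed by a full-vs-null ML
likelihood-ratio test; scans are corrected with Bonferroni (< 20 tests)
or Benjamini–Hochberg FDR, and each fit reports marginal and conditional
variance explained plus simulation-based scaled-residual diagnostics. A
dedicated interaction test asks whether dichotomized hypoxia and a driver
gene's mutation status jointly shape polyclonality.

A fully synthetic cohort generator with planted effects (latent hypoxia
axis, cancer-type intercepts, fixed-effect slopes, logistic driver links,
a hypoxia×driver interaction on clonality) makes the whole pipeline
testable without any external data.

## CLI

```sh
# synthetic cohort with known ground truth
oxiscan simulate --config cohort.yaml --out cohort/ --seed 17

# hypoxia scores for every signature in a GMT file
oxiscan score --expr cohort/expression.tsv \
              --signatures cohort/signatures.gmt --out scores.tsv

# merged per-sample modelling table
oxiscan features --cohort cohort/ --scores scores.tsv --out merged.tsv

# one association scan
oxiscan associate --data merged.tsv --features pga,total_deletions \
                  --out density.tsv

# hypoxia x driver interaction on clonality
oxiscan interaction --data merged.tsv --out interaction.json

# everything at once (scores, summaries, 5 scans, interaction, diagnostics)
oxiscan pipeline --cohort cohort/ --out results/ --seed 17
oxiscan report --results results/
```

Exit codes: 0 success, 2 validation error, 3 model-fitting error.

## Library layout

| module               | contents |
|----------------------|----------|
| `oxiscan.scoring`    | hypoxia scores, median scaling, Spearman/AS 89 concordance, tumour-vs-normal rank tests, per-type summaries, median dichotomization |
| `oxiscan.lmm`        | single-random-intercept Gaussian LMM (profiled ML/REML, validated against lme4), LRT, marginal/conditional R², simulation-based residuals, p-value adjustment |
| `oxiscan.features`   | driver status collapsing (compound events), exposure proportions, clonality classes, table assembly |
| `oxiscan.associations` | min-samples filtering, association scans, independence and interaction tests, stratified abundance summaries |
| `oxiscan.simulate`   | synthetic cohort generator with planted ground truth |
| `oxiscan.io` / `oxiscan.pipeline` / `oxiscan.cli` | TSV/GMT/JSON round-tripping, end-to-end orchestration, command line |

Conventions worth knowing: "top 50%" scoring votes use strictly-greater-
than-median (ties vote −1); quantiles use linear interpolation; LRTs
always refit with ML; binary clonality responses use the linear
probability parameterisation (a logistic option is deliberately out of
scope for the scans).

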