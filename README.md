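# plasmasig

Analysis pipeline for **plasma-induced transcriptional signatures in
recent-onset type 1 diabetes**: discriminative signature selection, composite
inflammatory-index scoring, beta cell function endpoints, index–outcome and
survival association, CTLA4-Ig responder stratification, and
co-expression-module subgroup discovery — exercised end-to-end on a
synthetic-data generator that plants the statistical structure every stage
assumes.

## The scientific problem

In the plasma-induced transcription bioassay, a participant's plasma or serum
is co-cultured with reporter PBMCs from a single healthy donor; the induced
reporter transcriptome reads out the participant's soluble immune milieu.
Newly diagnosed (recent-onset) type 1 diabetes patients induce an
inflammatory program, while high-HLA-risk unaffected siblings and healthy
controls induce a regulatory (IL-10/TGF-β–biased) program. This package
implements, as reusable and tested components:

- **Composite inflammatory index (I.I.)** — for a disjoint partition of
  probes into an inflammatory set *I* and regulatory set *R*, each sample's
  score is the log-scale contrast

  ```
  I.I. = mean(x_I) − mean(x_R),   x = per-probe-centered log2 intensity
  ```

  the log of a ratio of geometric means; higher = inflammatory bias.
- **Dual-criteria signature selection** — probes regulated at
  |log2 ratio| > 0.263 (1.2-fold) with Benjamini–Hochberg FDR < 20 % in at
  least one cohort contrast, **and** highly ranked by mean decrease in Gini
  impurity in a seeded tree ensemble classifying one cohort against the
  rest; selected probes are partitioned into inflammatory/regulatory sets by
  the cohort where their mean expression peaks.
- **Beta cell function endpoints** — percent change of 2 h stimulated
  C-peptide AUC from baseline, per-participant decline slope by truncated
  linear regression, IDAA1c = HbA1c(%) + 4 × insulin dose (U kg⁻¹ day⁻¹),
  partial-remission durations (C-peptide ≥ 0.2 nmol/l, or IDAA1c ≤ 9), and
  the Jenks natural-breaks two-class split.
- **Survival association** — Weibull accelerated-failure-time and Cox
  fits of remission duration on the baseline index, and Kaplan–Meier curves
  with a logrank test for the median-split index groups.
- **Responder stratification** — placebo reference regressions of outcome
  on baseline index (one line per timepoint plus one for the decline slope);
  treated participants > 1.5 residual SD above the line at ≥ 3 timepoints
  *and* > 1 SD above the slope line are responders, compared against
  index-matched placebo rapid progressors at or below the slope line.
- **Co-expression modules** — soft-thresholded correlation network
  (β = 12, scale-free fit R² > 0.8), topological-overlap dissimilarity,
  average-linkage module detection, module eigengenes (first principal
  component), eigengene–trait correlations, and participant subgroup
  discovery by hierarchical clustering on correlation distance.

Real cohort data are not required: `plasmasig.synthetic_data` generates
cross-sectional cohorts (47/42/30/44 participants), a 2:1 treated:placebo
trial (54/20) with a planted index–outcome coupling (slope −0.85 in the
placebo arm only), Weibull-distributed remission times, four latent
subgroups with three trait-linked module blocks, and planted treated
responders — all pure functions of `(config, seed)`.

## Worked example

```python
import plasmasig as ps

config = ps.SimulationConfig(seed=1)
study = ps.generate_cross_sectional(config)
scores = ps.compute_index(study.matrix, study.truth.partition())
series = ps.scores_as_series(scores)
cohort = study.samples.cohort_of()
for c in ("ROT1D", "LRS", "uHC", "HRS"):
    members = [s for s, cc in cohort.items() if cc == c]
    print(f"{c:6s} mean I.I. = {series[members].mean():+.3f}")
auc, _ = ps.roc_auc(scores, set(study.samples.samples_in_cohort("ROT1D")))
print(f"ROC AUC (diabetes vs rest) = {auc:.3f}")
```

prints

```
ROT1D  mean I.I. = +0.548
LRS    mean I.I. = +0.432
uHC    mean I.I. = -0.537
HRS    mean I.I. = -0.674
ROC AUC (diabetes vs rest) = 0.977
```

The diabetic cohort scores highest, low-HLA-risk siblings are intermediate,
and the regulatory-biased cohorts score negative — the planted ordering —
and the index separates the diabetic cohort from the rest almost perfectly
when scored with the true partition.

The same stages are available from a shell:

```sh
plasmasig simulate --seed 7 --design trial --out run/
plasmasig score --matrix run/matrix.tsv --partition run/truth_partition.tsv \
    --out run/scores.tsv
plasmasig endpoints --clinical run/clinical.tsv --out run/endpoints.tsv
plasmasig survival --scores run/scores.tsv --endpoints run/endpoints.tsv \
    --samples run/samples.tsv --out run/
plasmasig stratify --scores run/scores.tsv --endpoints run/endpoints.tsv \
    --samples run/samples.tsv --out run/
plasmasig report --dir run/ --out run/report.json
```

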