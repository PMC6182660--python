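# Methods

This note documents the statistical model behind each pipeline stage, the
conventions adopted where the procedure admitted more than one reading, the
design of the synthetic-data generator, and the limits of what the tests
show.

## The inflammatory index

The composite index contrasts the mean induced expression of an
inflammatory probe set against a regulatory probe set. On the log2 scale a
"ratio of average signal intensities" becomes a difference of set means —
the log of a ratio of geometric means. `compute_index` defaults to
**per-probe centering across samples** before taking the contrast. Two
reasons: (1) published index values for these assays run from negative to
positive around zero, which is impossible for a literal ratio of positive
intensities but is exactly the behaviour of a centered log-scale contrast;
(2) centering makes the score invariant to per-probe intensity offsets (a
probe's affinity) and to per-sample offsets common to all probes (a
loading/normalisation shift), which is what a relative inflammatory-bias
score should be. The uncentered difference is available (`center=False`);
a literal intensity ratio can be formed by exponentiating.

Cohort comparisons use Welch's two-tailed unpaired *t* on the per-sample
scores. ROC discrimination uses the rank (Mann–Whitney) formulation with
ties counted 0.5, which the tests check against exhaustive pair
enumeration.

## Signature selection

Two screens intersect:

- **Regulation** — per-probe group contrasts: pairwise Welch *t*
  (log2 ratio = difference of group means) or one-way ANOVA across all
  cohorts, with Benjamini–Hochberg FDR computed within contrast. A probe
  passes at |log2 ratio| > 0.263 (1.2-fold) and FDR < 0.20; an optional
  alpha mode additionally requires the raw p below a cut. BH was chosen as
  the FDR procedure: the upstream analyses name only "false-discovery
  rates" computed by a commercial suite, and step-up BH is the field
  default. The implementation delegates to statsmodels and is tested
  against a brute-force step-up oracle.
- **Importance** — per-probe mean decrease in Gini impurity from a seeded
  tree ensemble classifying one cohort versus the rest (one run per
  cohort), feature subsampling √p, 1000 trees by default. Three consumption
  modes: an absolute Gini cut (the published 3.49 is data- and
  tool-specific, so this mode is only meaningful when the importance scale
  matches), a global top-k, and a **top-k within each one-vs-rest
  contrast** — the analog of an absolute cut applied per comparison.
  scikit-learn normalises importances to sum to one, so the absolute-cut
  mode is not portable to it.

For recovery analyses on synthetic data the pipeline uses **extremely
randomised trees** (`ensemble="extra_trees"`) with the per-contrast top-200
rule. With hundreds of correlated informative probes and ~160 samples,
bootstrap-forest impurity importances are a high-variance ranking (trees
repeatedly split on the currently strongest probes and starve the rest);
the extra randomisation spreads splits across the informative set and
stabilises the ranking markedly at equal cost. The bootstrap forest remains
the default for fidelity to the original tool.

Selected probes are partitioned by the **cohort-peak rule**: a signature
probe whose mean expression peaks in the diabetic or low-HLA-risk sibling
cohort is inflammatory; peaking in the high-HLA-risk sibling or unrelated
control cohort is regulatory. This is an automated proxy for the original
ontology-based curation, which cannot be reproduced mechanically.

## Clinical endpoints

- **Percent change**: 100 × (AUC_t − AUC_0)/AUC_0 per post-baseline visit.
- **Decline slope**: OLS of AUC (nmol/l) on time (years). "Truncated"
  regression is interpreted as: visits after the series first reaches its
  floor are excluded (the floor-reaching visit itself is kept), so a run of
  floor values does not attenuate the slope toward zero. A flag fits all
  visits instead.
- **IDAA1c** = HbA1c(%) + 4 × insulin dose (U kg⁻¹ day⁻¹).
- **Remission duration**: last-compliant-visit convention — the time of the
  last visit at which the criterion holds before its first violation; 0 if
  violated at the first post-baseline assessment; censored when it still
  holds at the final visit. No interpolation between visits. Values exactly
  at a threshold (C-peptide 0.2 nmol/l; IDAA1c 9.0) count as in remission.
- **Jenks two-class split**: exact exhaustive minimisation of within-class
  sums of squares over all contiguous splits of the sorted values.

## Survival association

The Weibull model is fit in **accelerated-failure-time parameterisation**
(log duration linear in the index, constant shape), matching an analysis
that plots median remission duration against the index; the hazard-ratio
translation (−shape × coefficient) is reported alongside. Cox fits use the
partial likelihood. Both are delegated to lifelines. OLS slope p-values use
the *t* distribution with n − 2 df. In the Kaplan–Meier median split,
scores exactly at the median go to the "below" group (a determinism
choice). The logrank p is the χ²(1) evaluation of the standard statistic,
cross-checked in the tests against a hand-written statistic and a
permutation null.

## Responder stratification

Reference lines are OLS fits on the placebo arm: outcome = percent change
at each post-baseline timepoint, plus one line for the decline slope. The
"SD" in the selection rules is the **SD of placebo residuals about each
line** (n − 2 denominator). A treated participant is selected when their
residual exceeds 1.5 SD above the line at ≥ 3 available timepoints
(missing visits count neither way) and exceeds 1 SD above the slope line;
"above" always means better-preserved C-peptide. Matched placebos are
drawn from those at or below the slope line (residual ≤ 0) by
**minimum-total-|index-difference| assignment** (Hungarian algorithm)
rather than a greedy pass: the original report gives no algorithm, and the
optimal assignment is deterministic and testable against an exhaustive
oracle.

Note a structural property the synthetic trial makes visible: because
treated outcomes are decoupled from the index while the reference lines
slope downward in it, treated participants with high baseline index sit
systematically above the placebo expectation — they are genuine
"responders" in the clinical sense even without a planted displacement, and
a few of them pass both criteria. Specificity against the *planted*
responder set is therefore slightly below one by design, not by defect.

## Co-expression network modules

- Adjacency: |cor|^β (unsigned, default) or ((1+cor)/2)^β (signed) between
  probe profiles; β = 12 by default. The scale-free fit for the
  soft-threshold scan is the r² of log10 frequency on log10 mean
  connectivity over 10 **equal-width** connectivity bins (equal-count bins
  would make the frequency constant by construction).
- Topological overlap: TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)
  with l = A², unit diagonal; dissimilarity 1 − TOM.
- Module detection: average-linkage clustering with a **static absolute
  height cut at 0.99 on the 1 − TOM scale**. Clusters formed below the cut
  with ≥ 30 probes become modules (colour labels by decreasing size);
  everything else is grey. A quantile-based cut was rejected: for a pure
  noise network the merge heights concentrate just below 1, so any
  high-quantile cut returns one giant pseudo-module, whereas the absolute
  cut correctly leaves noise unassigned. Modules whose eigengenes correlate
  above 1 − merge_cut (default |r| > 0.75) are merged.
- Eigengene: first principal component of the probe-standardised module
  submatrix across samples, unit norm, sign-oriented to correlate
  positively with the module mean profile.
- Module–trait correlation: Pearson r with two-sided p, pairwise deletion
  of missing trait values. The decline-slope trait is computed within the
  placebo arm, where the natural disease course is observed; treated
  participants' slopes mix in the therapy effect.
- Subgroup clustering operates on participants using correlation distance
  (1 − Pearson r between baseline signatures) after per-probe centering,
  average linkage, cut into k groups. Because the participant-level
  correlation removes each participant's mean across probes, only
  expression *contrast* across probes — not overall level — drives the
  grouping.

## The synthetic-data generator

The generator emulates the study's statistical structure, not its biology:

- **Cross-sectional cohorts** (ROT1D 47, LRS 42, HRS 30, uHC 44; 5000
  probes): 100 inflammatory signal probes elevated in ROT1D (full effect,
  0.6 log2) and LRS (0.8 × effect), 250 regulatory probes elevated in HRS
  (full) and uHC (0.8 ×), i.i.d. Gaussian probe noise (SD 0.5 log2), and a
  dim tail of probes (15 % of the non-signal set, means 1–2.2 log2) for the
  intensity filter to remove. The mild grading makes the cohort mean-index
  ordering ROT1D > LRS > uHC > HRS an identifiable planted feature (the
  gap is an order of magnitude above the cohort-mean standard error) while
  keeping every per-contrast effect near the stated 0.6.
- **Trial** (54 treated, 20 placebo; visits 0/3/6/12/18/24 months): each
  participant carries a latent index (subgroup means −0.3/0/0.5/0.9, within
  SD 0.25) expressed as ±index/2 on the signature probes, and three module
  factors with subgroup-patterned centers driving 80-probe blocks
  (loading 0.7). The factor centers sum to zero across the three modules —
  patterns with a common level are invisible to correlation-distance
  clustering — and factor 2's pattern is proportional to the centered
  index-mean pattern, making module 2 the index-linked module. Placebo
  percent-change outcomes have conditional mean −0.85 × index + trend
  (trend −2.2 %/month; participant shift SD 0.25 %, visit noise SD
  0.35 %), giving per-timepoint r² ≈ 0.45 at the planted coupling, in line
  with the association strength the pipeline is meant to detect; treated
  outcomes are decoupled (slope 0) with a small subgroup benefit, largest
  in the inflammatory-biased subgroups. Remission times follow a Weibull
  AFT model (shape 1.5, log scale = log 20 − 0.8 × index + 0.25 for the
  treated arm), censored at 24 months; the IDAA1c series crosses 9 at
  0.6 × that time (lognormal jitter), so IDAA1c-rule durations
  systematically underestimate C-peptide-rule durations, and the baseline
  AUC couples weakly to the remission time so the two rules correlate
  positively. Planted responders (15 % of treated) have outcomes displaced
  +3 residual SD at every timepoint plus a 3 %/month time-growing boost
  (≈ +3.8 SD on the decline-slope line). A 2 SD displacement cannot
  satisfy a ≥ 0.9 sensitivity bound under the 1.5 SD/≥3-timepoint and 1 SD
  slope rules (the per-timepoint exceedance probability is only ~0.69), so
  the planted magnitude is set where the rules have real power.
- **Paired signatures**: two signed log2-ratio vectors with an exact count
  of sign-concordant positions, for the spike-in concordance emulation
  (880/1509 = 58.3 %).

What the generator does **not** emulate: array batch effects and
normalisation artefacts, probe-level hybridisation physics, longitudinal
induced-expression timecourses (trial expression is baseline-only; the
baseline-normalisation stage is exercised on constructed matrices),
annotation-based curation of the gene sets, correlated probe noise within
pathways, and missing-visit patterns. Passing recovery tests therefore
demonstrates that the pipeline's inference is correct under its own
assumptions at the study's sample sizes — not that those assumptions hold
on real cohort data.

## Problem sizes and numerical choices

- Recovery analyses run at the default study sizes (163 cross-sectional
  samples × 5000 probes; 74 trial participants). The network stage keeps
  the top 1500 probes by MAD after the intensity filter — the planted
  module and signature probes all survive, and the correlation/TOM matrices
  stay small enough for quick, repeated analysis; on larger matrices the
  7000-probe default applies unchanged.
- Replicate counts: Weibull CI coverage 100 replicates at n = 500;
  responder operating characteristics 50–100 clinical-only replicates;
  null-calibration suites 200–400 replicates.
- MAD is unscaled (no 1.4826 factor); scaling would not change the
  ranking. Ties in the MAD and importance rankings break by probe ID.
- Degenerate inputs fail loudly: zero residual SD on a reference line,
  constant index in a survival fit, all-censored durations, empty
  partition sets, and probes with non-finite values are errors, not
  warnings.
- Durations of exactly 0 are nudged to 10⁻⁶ months before likelihood
  fits (lifelines requires positive durations).

## Known limitations

- The Gini threshold 3.49 from the original tool is not portable to
  scikit-learn's normalised importances; the per-contrast top-k mode is
  the supported equivalent, and the absolute-cut mode only makes sense
  with comparably scaled importances.
- The cohort-peak partition rule approximates, but cannot reproduce, the
  original manual ontology curation.
- The static 0.99 height cut with eigengene merging is simpler than
  dynamic tree-cut; on data with nested module structure it will be more
  conservative (more grey probes).
- Weibull fits hold the shape constant across participants;
  covariate-dependent shape is out of scope.
- IDAA1c-rule remission durations inherit the quarterly visit grid, so
  survival coefficients estimated from them are attenuated relative to the
  continuous-time process; the planted-process coefficients are recovered
  without bias when fit on the continuous times.
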