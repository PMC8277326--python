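# Methods

`phenoscreen` re-implements, as a tested pipeline, a screening-algorithm
construction for obstructive sleep apnea: odds-ratio-weighted categorical
distance → Ward clustering → three severity phenotypes → phenotype-augmented
Bayesian classifier → rule-out evaluation. This note records the model
assumptions, the tunable parameters and their defaults, the numerical
choices, and the limits of what the test suite demonstrates.

## Synthetic cohort generator

The reference cohort (318 referred patients; 207 OSA, 111 healthy) was never
deposited, so the generator is the package's data source. It emulates the
cohort at the categorical level the analysis consumes:

- **Latent phenotype.** Each patient carries a hidden phenotype
  (low / medium / high) drawn from status-specific weights — 74/104/29
  among OSA patients, 25/79/7 among healthy ones.
- **Predictors.** Given (phenotype, OSA status), each categorical predictor
  is drawn independently from the per-group frequency encoded from the
  published per-phenotype tables (14 cluster-candidate variables: gender,
  age band, BMI band, nonrepairing sleep, nocturia, stroke, arterial and
  pulmonary hypertension, congestive heart failure, arrhythmias, pacemaker,
  respiratory changes, diabetes, dyslipidemia). Four screening-only symptom
  variables (witnessed apneas, daytime sleepiness, snoring, gasping/choking)
  and bariatric surgery are described only at the whole-cohort level in the
  source tables; their OSA-arm prevalences come from those totals, and their
  healthy-arm prevalences are fixed package choices (0.40, 0.50, 0.85, 0.40,
  0.03) — plausibly lower than the OSA arm, configurable in
  `GeneratorSpec.category_probs`.
- **Outcome.** OSA patients draw a severity band from their phenotype's
  mixture (e.g. 68.9 / 24.3 / 6.8 % mild/moderate/severe in the low
  phenotype); healthy patients are always in the normal band. The integer
  AHI is then drawn inside the band from a truncated geometric law,
  `P(AHI = lo + k) ∝ r^k`, with decay r = 0.85 (normal, mild) and 0.9
  (moderate, severe) and the severe band truncated at 120 events/hour.
  AHI is right-skewed within bands in clinical data; a uniform law (r = 1,
  available) cannot reproduce the reference per-phenotype medians and
  spreads, while the geometric defaults give pooled medians 10 / 14 / ~31.
- **Missingness.** Each predictor entry is masked independently at the
  variable's reported rate (0% for gender and age up to 97% for bariatric
  surgery); that is the MCAR mechanism. The MAR option multiplies a
  variable's rate by 1.3 (configurable) for healthy patients, reflecting
  under-recording of comorbidities in healthier charts. Outcome columns are
  never masked; pre-masking values are retained for imputation scoring.

What the generator does **not** emulate: continuous raw measurements before
discretization; any dependence among predictors beyond the shared
(phenotype, status) — conditional independence is assumed, which is exactly
the structure the augmented classifier can exploit and is *not* claimed to
be the truth of the original registry; calibration drift, site effects, or
informative referral. Consequently, passing tests show the pipeline behaves
correctly on data with latent-class structure at realistic sizes — not that
the published real-cohort validity numbers are reproduced.

## Preprocessing

- **Discretization cutoffs**: age 20–44 / 45–64 / 65–90; BMI <25 / 25–30 /
  ≥30; Epworth 0–10 normal, 11–24 excessive; neck and abdominal
  circumference use gender-specific bounds — "increased" means strictly
  above 37/41 cm (neck, female/male) or 80/94 cm (abdominal). The published
  bands are gapped ("≤37 normal, >38 increased"); using the normal bound as
  the threshold covers the gap. AHI severity uses ≥30 for severe, which
  partitions the integers.
- **High-missingness removal**: variables with missing proportion strictly
  above 0.80 are dropped. Note that a variable with a nominal rate near the
  threshold (stroke, 78.7%) crosses it on some seeds — a faithful property
  of the replica, and the reason downstream code treats the variable list
  as data-dependent.
- **Univariate screening** (default α = 0.20): by default the 3-level
  severity contrast among OSA patients; the binary OSA contrast is an
  option. Chi-square without continuity correction, switching to the Fisher
  exact test when any expected cell count is below 5. The r×c Fisher test
  (Freeman–Halton) is an exact enumeration over margin-fixed tables summing
  probabilities ≤ the observed one (within 1e-7 relative tolerance);
  when the enumeration bound exceeds 200 000 tables, a seeded Monte Carlo
  over Patefield-sampled tables (20 000 draws) is used instead, so results
  are deterministic. Variables with a single observed category are flagged
  untestable and non-significant.
- **Cluster-variable selection**: significant in *both* the original and
  the imputed screens, minus exclusion-flagged variables (witnessed apneas,
  which depend on third-party reporting). If fewer than 3 survive, the
  pipeline falls back to all non-excluded candidates with a warning.
- **Imputation** (k = 10): stepwise. Incomplete variables are ranked
  ascending by missingness; pass 1 imputes the outcome-associated ones
  using distances over the complete, outcome-associated variables (each
  imputed variable immediately joins the distance set); pass 2 imputes the
  rest using all currently complete/imputed variables. When no variable is
  complete (heavily masked synthetic data), pass-1 distances fall back to
  the observed entries of all outcome-associated variables. The neighbour
  metric is the unweighted simple-matching proportion over shared observed
  entries of the distance set (the target variable excluded); rows sharing
  nothing are pushed to the maximal distance. Each missing cell takes the
  modal category of its 10 nearest donors; vote ties break toward the
  globally more frequent category, then the first in category order;
  distance ties break by donor index. Observed cells are never altered and
  imputed cells are flagged.

  *Known limitation.* A majority vote among k = 10 neighbours is a
  probability-matching estimator: for a binary variable whose conditional
  mode probability is below ≈0.75 it is strictly worse than always
  predicting the mode. On synthetic cohorts with every predictor masked at
  20%, the gains on phenotype-structured variables (nocturia, stroke:
  ≈ +4 points over the mode baseline) are offset by this penalty on
  weak-signal variables, leaving the pooled masked-cell accuracy at the
  baseline. An oracle that knows the latent phenotype reaches +4 points
  pooled, so the margin exists but is not accessible to this vote. The unit
  suite asserts the structured-variable gain; the pooled-accuracy
  acceptance check documents the shortfall.

## Phenotyping

- **Weights**: the crude odds ratio of each selected variable for the
  severe level, from the 2×2 cross-product on OSA patients with the
  Haldane–Anscombe +0.5 correction on zero cells. Multi-category variables
  are binarized for the OR at their top-severity category (age 65–90,
  obese; configurable per schema) but keep all categories in the mismatch
  indicator. ORs below 1 enter as-is: protective variables get small
  weight. Constant variables are excluded with a warning.
- **Distance**: weighted mismatch sum; the normalized variant (divide by
  total weight) is behind a flag. Scaling all weights by c > 0 scales all
  distances by c and provably changes nothing downstream.
- **Ward linkage**: hand-written Lance–Williams recursion applied to the
  raw dissimilarities (`ward.D`, the convention of the classic hclust
  generation), O(n³) vectorized, first-minimum tie-break in row-major
  order, heights made non-decreasing. `ward.D2` (recursion on squares,
  square-root heights) is available and is oracle-tested against the
  standard scientific-stack implementation on Euclidean data.
- **Fine cut and aggregation**: the dendrogram is cut into k = 10 fine
  clusters. Default aggregation follows the same dendrogram's 3-cluster cut
  (the hierarchical aggregation the fine cut is nested in), naming the
  groups low/medium/high by ascending pooled median AHI. The alternative
  `aggregation="medians"` groups the fine-cluster median AHIs by exact 1-D
  k-means on the log scale; it reproduces the reference grouping
  {8, 10}, {12, 13, 14}, {31, 34}. The tree cut is the default because the
  median of a 10–20 patient cluster is a noisy statistic under overlapping
  severity mixtures: in recovery experiments at fold sizes the tree cut
  roughly doubles the adjusted Rand index with the latent truth. If the
  tree cut fails to strictly order median AHI across phenotypes (a
  degenerate severity phenotype), the median grouping is used instead; if
  fewer than 3 distinct medians exist, a tertile split applies. Each
  constraint violation warns.
- **Assignment**: affinity of a patient to a phenotype is the mean weighted
  distance to its reference patients (medoid distance optional); the
  minimal affinity wins, ties breaking toward the lower-severity phenotype
  (conservative for a rule-out screen).
- **Description**: per-phenotype counts, proportions, and 95% CIs (Wilson
  score with continuity correction by default; Clopper–Pearson exact
  optional — the Wilson-cc convention is the one that reproduces the
  reference tables' printed intervals, including the zero-count cells).

## Bayesian classifiers

- **Model A** (naive Bayes): `P(OSA)` is the unsmoothed outcome frequency;
  `P(x_j = v | OSA = s)` is Laplace-smoothed with α = 1 (α configurable;
  with α → 0 CPTs equal empirical frequencies). **Model B** adds a 3-state
  phenotype node as a parent of every predictor; each of the 6 parent
  configurations gets its own smoothed column, and sparse configurations
  (e.g. healthy × high) degrade gracefully toward uniform with a warning.
  α = 1 is the default because those columns can rest on a handful of
  patients.
- **Phenotype node**: a root with a free marginal estimated from the
  assigned phenotypes of all patients — the phenotype influences the
  outcome only through the predictors' tables, mirroring a
  parent-of-all-predictors topology. An explicit outcome → phenotype arc
  (`phenotype_arc=True`) is available.
- **Inference**: exact enumeration over the outcome and, when unobserved,
  the phenotype. Predictors are leaves, so absent evidence marginalizes out
  for free; computations run in log space.
- **Prediction-time phenotype treatment**: by default the phenotype is
  *marginalized* — model B then acts as a phenotype-stratified mixture over
  the predictors. Entering the affinity-assigned phenotype as evidence
  (`phenotype_as_evidence=True`) is supported but not the default: the
  assignment is a deterministic function of the same predictors already in
  evidence, so conditioning on it double-counts them; in large-sample
  experiments on the generator this mode scores *below* the naive model
  (AUC 0.70 vs 0.73) while marginalization scores above it (0.76), and an
  oracle given the true latent phenotype reaches 0.90.

## Evaluation

- **Cutoff**: integer percent posterior threshold, comparison strict (>);
  the largest threshold whose derivation-sample sensitivity meets the
  target (default 0.95). If no threshold qualifies, the floor is returned
  with a warning.
- **Schemes**: `derivation` (apparent), `loo` (n refits, pooled posteriors,
  count-based CIs), `10x2cv` (10 seeded repetitions of stratified half/half
  splits; per-fold metric panels at the derivation cutoff; point estimate =
  mean over the 20 folds; CI = mean ± 1.96·SE across folds). For model B
  the weights, dendrogram, aggregation, and assignments are refit inside
  every training fold — no test information reaches the cluster structure.
  Imputation, as in the original procedure, is performed once upfront.
  Single-class training folds are skipped with a warning.
- **Intervals**: proportions via Wilson-cc (Clopper–Pearson optional),
  likelihood ratios and DOR via the log method, AUC via DeLong. The DOR
  uses the Haldane +0.5 correction on all four counts when any count is
  zero (the identity DOR = LR+/LR− then no longer applies, and holds to
  1e-9 otherwise).
- **Comparator rule**: the guideline step-2 symptom rule — excessive
  daytime sleepiness AND at least two of {snoring, witnessed apnea or
  gasping/choking, hypertension} — with missing values counted as absent.
  Its cohort-dependent performance is reported, not asserted.

## Determinism and problem sizes

Every stochastic step takes an explicit seed (`numpy` Generator); pipelines
record config hashes and seeds in a manifest sufficient for byte-identical
re-runs. The test and acceptance suites use cohorts of n = 318 (the study
size) for classifier comparisons, 400 OSA patients for phenotype recovery
(20 seeds against a 200-draw label-permutation null), n = 500 for
imputation scoring (10 seeds), and 1000-trial oracle-equivalence sweeps for
Ward linkage, posterior inference, and AUC; the whole suite completes in
about a minute on one core.

## Known limitations

- The augmented model's cross-validated advantage on synthetic cohorts at
  n = 318 is positive in the mean (≈ +0.01 AUC) but modest: phenotype
  labels recovered from ~100-patient training folds are noisy (ARI ≈
  0.2–0.5 against the latent truth), eroding most of the oracle-label gain
  (≈ +0.07). The per-seed win rate is about 75%.
- Pooled imputation accuracy under uniform 20% MCAR sits at the
  marginal-mode baseline (see the imputation note above); with the actual
  reported missingness pattern — concentrated on comorbidities that carry
  phenotype signal — the structured gains dominate.
- Proportion CIs reproduce the reference tables to the printed integer for
  38 of 42 cells; the remainder are off by one percentage point,
  consistent with rounding noise in the source.
- No multiple imputation, no bootstrap cluster stability, no automatic
  choice of the fine cut, no external-cohort validation.
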