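# Methods

This note documents the models, algorithms and design choices behind
`phosphosig`, in the order the pipeline applies them, together with the
numerical conventions and the limitations a user should know.

## Data model

The measured object is a sites × samples matrix of positive ratios: each
cell is the MS intensity of a phosphopeptide in a patient sample divided by
the intensity of the same peptide in a heavy-labeled spike-in standard
common to all runs. Ratios are analyzed on the log2 scale. Cells are
missing when the peptide was not quantified in that run — in this kind of
experiment roughly 10% of cells, and not at random: low-abundance peptides
drop out more often.

Supervision is a per-sample manifest assigning a cohort (training or
validation) and a binary response label (responder / non-responder, with
responder the positive class throughout).

## Preprocessing

Order: class-I filter → log2 → quantification filter → median centering.

* **Class-I filter.** Keep sites with residue-localization probability
  ≥ 0.75 (boundary inclusive) — the conventional definition of a
  confidently localized site. The threshold is configurable
  (`classI_threshold`).
* **Quantification (two-thirds) filter.** Keep a site iff it is observed in
  at least ⌈f·n⌉ of the n samples being analyzed, default f = 2/3: 8 of 12,
  6 of 9. Ceiling is the strict reading of "at least two thirds". The rule
  is applied per cohort under analysis. An empty result is an error, not an
  empty matrix.
* **Normalization.** Each sample column is centered to observed median 0.
  Median centering is self-contained per sample — validation samples never
  borrow training statistics — and robust to abundance-dependent
  missingness. It can be switched off.

Filters are idempotent, record themselves in the matrix's provenance, and
commute when every site is fully localized.

## Mean-rank differential test

For one site, let the m observed log2 ratios carry ascending mid-ranks and
let T be the mean rank of the n_r responder observations; E[T] = (m+1)/2
under exchangeability. The two-sided p-value is the proportion of the
C(m, n_r) responder/non-responder reassignments over the *observed* entries
with |T − E[T]| ≥ |T_obs − E[T]|.

Numerical conventions:

* Computation is on the rank-sum scale (sums of mid-ranks are exact
  half-integers in floating point); comparisons use a 1e-9 slack.
* Exact enumeration whenever C(m, n_r) ≤ 20,000 (always at 12 samples,
  where C(12,6) = 924); otherwise Monte-Carlo with the configured
  permutation budget and the (b+1)/(B+1) convention, which includes the
  observed assignment and guarantees p > 0 and valid type-I control.
* Sites where all observed values are identical get p = 1 by convention.
* Sites with fewer than two observations in either group are skipped with a
  reason code rather than tested: a one-observation group makes the
  two-sided permutation null degenerate.
* Sites sharing a missingness pattern share one enumerated null; on
  complete matrices the whole test is a single vectorized block, which is
  what keeps nested cross-validation (below) fast.

On complete tie-free data T is a monotone transform of the Wilcoxon
rank-sum statistic and the exact-mode p equals the exact two-sided Wilcoxon
p; the test suite verifies this bit-for-bit against an independent
integer-enumeration oracle.

Multiplicity is controlled by Benjamini–Hochberg at q ≤ 0.10 (delegated to
statsmodels). An important discreteness consequence: at 6 vs 6 the smallest
achievable two-sided p is 2/924 ≈ 0.00216, so with thousands of tested
sites BH at q = 0.10 essentially cannot reject — the differential stage is
calibrated but deliberately conservative at this sample size.

## Signature learning

* **Importance ranking.** Testable sites are ordered by the absolute
  difference of responder and non-responder mean log2 ratios (descending),
  with the mean-rank-test p-value as tiebreak (ascending), then site_id.
  The continuous effect size must lead the ordering precisely because of
  the discreteness noted above: among thousands of candidates, many strong
  sites saturate the permutation p floor and several null sites are
  expected at it by chance, so p alone cannot order the top of the list.
  In simulations with five sites planted at four times the observation
  noise among 500 null sites, effect-size-led ranking recovers the exact
  planted set in ≈99% of runs versus ≈73% for p-led ranking. The ranking is
  deterministic and invariant under label flips.
* **Selection.** The signature is the top k sites, k = 5 by default. k is
  fixed rather than chosen by an inner cross-validation loop; with a dozen
  samples an inner model-selection loop would be noise.
* **Classifier.** A linear maximum-margin classifier (SVC, C = 1,
  convergence tolerance 1e-9) on the k-dimensional site vectors. Missing
  signature values are imputed with the constant 0 — the "no regulation"
  point of median-centered log2 ratios. The tight solver tolerance makes
  the margin negate exactly under a label flip, so calibrated probabilities
  satisfy p → 1 − p.
* **Calibration.** A two-parameter sigmoid P(responder | f) =
  1/(1 + exp(A·f + B)) fitted on the training decision values by
  unpenalized maximum likelihood with smoothed targets
  (N₊+1)/(N₊+2) and 1/(N₋+2), which keeps the fit finite on separable
  training sets. A sample is called a responder when its probability
  exceeds the 0.5 decision threshold.
* **Nested leave-one-out cross-validation.** For each sample, ranking,
  selection and training are re-run on the remaining n−1 samples and the
  held-out sample is scored by that fold's model; metrics are computed over
  the n held-out predictions and each fold's selected sites are logged. A
  deliberately *leaky* variant (selection once, before cross-validation) is
  provided solely to quantify selection bias; on pure-noise data it scores
  ≈0.9 mean accuracy where the nested estimate stays near chance.
  The nested estimate on noise sits slightly *below* 0.5 (≈0.41 in our
  simulations): with leave-one-out and in-fold selection the features are
  chosen to separate the n−1 training labels, which biases the held-out
  sample toward the wrong side. This anti-learning tendency of LOOCV with
  aggressive selection is expected behavior, not a defect.
* **Reported percentages** round half-up to integer percent
  (11/12 → 92%, 5/6 → 83%, 2/3 → 67%, 7/9 → 78%).

## Validation

The frozen signature (sites, weights, bias, calibration, imputation
constant — serialized to JSON with 17-significant-digit floats, so the
round trip is bit-exact) is applied unchanged to the validation cohort.
Sample-id overlap between training metadata and the validation matrix is a
hard error, and the report carries a disjointness attestation. Validation
samples are median-centered per sample, which requires no training
statistics. Metrics: confusion counts with responder positive, accuracy,
sensitivity, specificity, and AUROC by the rank method with mid-rank ties
(constant scores give 0.5; a single-class cohort reports AUROC as absent).

## Phospho–protein correlation

For a signature site and its protein, Pearson r is computed over
pairwise-complete samples only (observed in both vectors); the p-value is
the two-sided t test on t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom.
Fewer than 3 complete pairs yields an "insufficient data" flag instead of
an estimate.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

* per-site baseline b_i ~ N(0, base_ratio_sd²), default sd 1.0 log2 units —
  the biological spread of ratios to the standard;
* observation x_ij = b_i + Δ·[site planted]·[sample responder] +
  N(0, noise_sd²), defaults Δ = 2.0 and noise_sd = 0.5 (a planted effect of
  four noise sd, strong enough for a 12-sample study to see);
* default cohort shape 6 responders vs 6 non-responders in training and
  6 vs 3 in validation, 2000 sites;
* missingness: cell dropout log-odds = logit(mcar_rate) +
  mnar_strength·(−b_i). Default mcar_rate 0.106 reproduces the ~10.6%
  missingness typical of the tested matrix; mnar_strength > 0 makes
  low-abundance sites drop out preferentially (default 0 — tests that need
  MNAR switch it on explicitly);
* localization probabilities: class-I sites Uniform(0.75, 1), the rest
  Uniform(0, 0.75); `classI_fraction` defaults to 1 so the filter is
  exercised explicitly where wanted;
* a protein table coupled per cell as ρ·x + √(1−ρ²)·ε, ρ = 0.8 by default,
  for the correlation stage.

All draws come from a single seeded stream in a documented order, so one
config + seed is bit-reproducible; `generate_study` shares the site
universe (baselines, planted set, annotations) between cohorts and draws
sample-level noise independently.

What the generator does *not* emulate: peptide-level structure (one site =
one measurement), retention-time or channel effects, correlated site blocks
within pathways, heavy-tailed or sample-specific noise, batch effects
between cohorts. Passing tests on synthetic data therefore demonstrate the
correctness and internal honesty of the algorithms (calibration,
leak-freedom, recovery under the assumed model), not clinical performance
on real phosphoproteomes.

## Problem sizes used in tests

The test and acceptance suites run at desk scale by design: null
calibration uses ten 2000-site null datasets (~20,000 exact tests),
signature recovery thirty 505-site studies, and the selection-bias
comparison thirty to fifty 500-site noise datasets — sizes at which the
exact 6-vs-6 permutation null makes every stage deterministic and the full
suite completes in well under a minute.

## Known limitations

* The 6-vs-6 discreteness floor (p ≥ 2/924) makes FDR-controlled discovery
  very conservative at study scale; the signature stage compensates by
  ranking on the continuous effect size.
* The imputation constant 0 assumes median-centered inputs; applying a
  signature to un-normalized data shifts imputed cells.
* Labels are taken as given; ambiguous clinical response calls are out of
  scope.
* No batch correction, no peptide roll-up, no nonlinear kernels, no
  hyperparameter search.
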