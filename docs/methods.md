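# Methods

`tddkit` implements the quantitative machinery of a clinical study of
tactile direction discrimination (TDD) after first-time stroke: the adaptive
staircase test itself, the derivation of normative impairment thresholds,
single-case deficit tests, the exact association of lesion location with
impairment, and node-level lesion-symptom mapping on parcellation volumes.
This note documents the models, the parameters that matter, the synthetic
data the tests run on, and the design choices made where the published
description left the design open.

## The staircase test and its score

The test is a two-alternative forced choice: a probe moves across the skin
over one of seven path lengths (3, 6, 10, 18, 32, 56, 100 mm — an
approximately logarithmic series), in either a proximodistal or
distoproximal direction, and the participant reports the direction. The
protocol is a transformed up-down staircase: testing starts at 18 mm; an
incorrect answer moves the next trial one step up the series (longer,
easier); three correct answers in a row move it one step down (shorter,
harder). Both ends clamp. A test is 32 trials with 16 stimuli per direction
in seeded pseudo-random order. Probe speed (10 mm/s) and vertical load
(16 g) are stimulus metadata and play no computational role.

The score is the sum over trials of the 0-based index of each trial's
distance in the series — the "boxes to the left" of each response column on
the paper scoring sheet — and approximates the area under the staircase
trace. Higher scores mean poorer discrimination. Under the default protocol
the score is bounded by 18 (always correct: three trials each at 18, 10 and
6 mm, then 3 mm for the remaining 23) and 186 (always incorrect: 18, 32,
56 mm, then 100 mm for the remaining 29).

Two readings of "three correct responses" are possible; we reset the
correct-run counter on every error *and* on every level change, which is
the only reading consistent with both score extremes above, and score
correct and incorrect trials identically (position only), which is required
to reach 186.

`expected_score_dp` computes the exact expected score of a stochastic
observer by forward dynamic programming over (trial, level, correct-run
counter). It exists as an independent oracle for Monte-Carlo simulations:
the two never share code beyond the transition rule, and the test suite
holds them to agreement within three standard errors at 10,000 runs.

## Normative thresholds and relative scores

A raw score is classified against the 90th percentile of a healthy
normative sample. Quantiles use linear interpolation between order
statistics (the common default in scientific software; the original
description does not state a rule, so this choice is configurable).

* **Hand** — scores show a floor effect and no significant age trend, so a
  flat threshold is used, computed per decade age band (20–29 … 60–69); a
  band with fewer than two records inherits the pooled percentile with a
  warning.
* **Foot** — discrimination declines roughly linearly with age, so the
  threshold is a line `threshold(age) = a*age + b`. We reconstruct it as
  the OLS fit of score on age with the intercept shifted upward by the 90th
  percentile of the residuals, leaving ~90 % of normative points below the
  line while keeping the fitted slope. (Only the final coefficients of the
  original line are published; whether it came from a shifted OLS fit or a
  quantile regression is unknowable, so the form is reproduced and the
  published coefficients can be supplied as a fixture.) Thresholds
  extrapolate linearly beyond the normative age range, since stroke
  patients can be older than the oldest control and tactile function keeps
  declining linearly at those ages.

Performance is expressed as the relative score
`(raw − threshold) / threshold`; positive values are worse than the cutoff.
A site is abnormal when its relative score is **strictly** greater than
zero or when an examiner-supplied side-difference flag marks an abnormal
left/right asymmetry; a patient is abnormal when any tested site is. The
boundary case (exactly 0.00) is declared normal: the published patient
table leaves the case unobservable, so strictness is a declared convention,
not an inference. The numeric rule behind the side-difference footnote is
never published; flags are therefore accepted as input, not computed.

## Single-case tests

As an alternative classification strategy, the package implements the
classic small-sample single-case procedures: case-versus-sample
(`t = (case − mean) / (sd·sqrt((n+1)/n))`, df = n−1) and
case-versus-regression (the case's residual from the age-predicted value
over the prediction-interval standard error, df = n−2). "Worse than 90 % of
controls" is operationalized as an estimated percentile above 90 (point
estimate, one-tailed toward higher scores); interval-based criteria are out
of scope. `compare_classification_strategies` tabulates per-patient
agreement between this rule and the percentile-threshold rule.

## Cohort statistics

The lesion-impairment association uses a one-sided Fisher exact test
(hypergeometric upper tail conditional on the margins; the alternative is
that target-area lesions increase impairment incidence) with a matching
one-sided conditional exact confidence bound on the odds ratio: the lower
bound is the Fisher noncentral hypergeometric odds parameter at which the
conditional upper-tail probability of the observed count equals 0.05, found
by monotone root-solving on the log-odds scale. When the observed count
sits at its conditional maximum — as it does when every target-lesion
patient is impaired — the upper bound is infinite, giving intervals of the
form (L, ∞). Mid-p variants are deliberately off.

Time-point comparisons are classical paired t-tests on relative scores,
pooling left and right sides of one body site; differences are acute minus
follow-up so that a positive mean difference means improvement. On the
packaged patient table the recomputed hand comparison gives a mean
difference of 0.27 with t(55) = 2.195; the corresponding published t
differs in the third decimal because the table prints scores to two
decimals. The published foot t/p pair is internally inconsistent for
df = 55; the package reports its own recomputation (mean difference −0.01,
t(55) = −0.169) and does not attempt to match both printed numbers.

Multiple comparisons use the Holm step-down procedure (k-th smallest
p-value against α/(m−k+1); with two tests the critical alphas are 0.025 and
0.05), implemented directly because the critical alphas are part of the
reporting contract, and cross-checked against statsmodels in the tests.

## Node-level lesion-symptom mapping

Voxel-level mapping is not attempted: with highly variable lesion locations
the per-voxel patient counts cannot support statistics. Instead the
parcellation is split into contiguous nodes (connected components within
each parent label; 6-neighbourhood by default as the conservative
contiguity choice, 18/26 configurable) with stable ids ordered by parent
label, then size descending. Three gates follow:

1. only nodes with **more than** 100 voxels are considered (the strict
   boundary is a literal reading of the published criterion; a node of
   exactly 100 voxels is excluded);
2. a patient counts as lesioned in a node when the lesion covers at least
   `min(100, ceil(0.10 · node size))` of its voxels (the ceiling keeps the
   criterion integer-valued);
3. only nodes with at least four such patients are analysed.

For each analysable node, lesioned and non-lesioned patients are compared
on composite side scores (left = left-hand + left-foot relative score,
right likewise, same time point) with a one-tailed two-sample t-test
(lesioned worse), pooled variance by default (df = n−2, matching the
published degrees of freedom; Welch optional), Holm-corrected across all
node × side tests performed. Hemisphere is ignored when deciding "lesion in
node"; laterality enters only through which side's composite score is
tested. Inputs must already share one grid — no resampling is ever done
silently, and geometry mismatches are errors.

## Synthetic data

The generators produce every input the pipeline needs, with the structure
the analysis assumes — and only that structure.

**Observers.** P(correct | d) = 0.5 + (0.5 − lapse) · logistic((ln d −
ln α)/β), i.e. logistic in log-distance (the series is near-geometric), with
a 0.5 guessing floor and a lapse rate; a Weibull form is available. Age
degrades α multiplicatively, and the emergent score-vs-age slope is then
*measured*, not imposed.

**Normative cohorts.** Default sizes match the study's normative groups
(34 hand, 43 foot; ages 22–68). Site defaults — foot α₀ = 0.85 mm at age 22
growing 5.2 %/year with lognormal spread σ = 0.35, β = 0.55, lapse = 0.02;
hand α₀ = 0.60 mm with no age effect and σ = 0.40 — were fixed once so that
the emergent foot decline sits near 1.2 score points per year with foot
scores averaging ≈ 40 and hand scores near the floor of the range, the
regime the study reports. Raw scores always lie in [18, 186] because they
are produced by actually running the staircase.

**Phantoms and patient cohorts.** Phantom parcellations are deterministic
label volumes built from non-overlapping cuboids/spheres with known
component structure, including a 64-voxel fragment that exercises the
eligibility boundary. Simulated patient cohorts place a well-overlapping
lesion in a designated deficit component for a configurable subset of
patients (default 9 of 28, echoing the study's target-lesion group) and
small background lesions for the rest, so exactly one node is analysable —
the structural situation of the original analysis. The deficit is injected
by shifting the lesioned patients' contralateral relative scores up by 1.5
baseline SDs (fast mode, directly on scores; observer-degradation mode is
available through the observer specs). At these settings the node test
detects the deficit in ≥ 80 % of 500 replicates while the family-wise error
under a null cohort stays at α.

What the generators do **not** emulate: anatomically realistic lesion
shapes or atlas geometry, spatial correlation between nodes, non-Gaussian
relative-score distributions, dropout between time points, and any
dependence of scores on stimulation site within the tested skin area.
Passing tests therefore demonstrate correctness of the machinery and its
statistical calibration under the stated model, not clinical validity on
real lesion data.

## Problem sizes and numerical choices

The simulation-based tests use the study's own sizes where they matter
(28-patient cohorts, 34/43-control normative groups, 9 lesioned patients)
and compact phantoms (24³ voxel grids) for the volumetric loops; power and
calibration properties use 500 replicates, and null-calibration checks of
the scalar tests use 10,000. Root-solving for the odds-ratio bound runs on
the log-odds scale with expanding brackets and `brentq` at 1e-12 tolerance.
Ties in node ordering break by first voxel in array order; direction
scheduling and distance adaptation use independent seeded streams spawned
from one seed, which is stored in the scoring sheet.

## Known limitations

- The published coefficients of the foot threshold line, the normative
  means/SDs, inter-examiner correlations and the acute-phase count depend
  on unpublished raw data; the package reproduces the *procedures* and
  verifies them by parameter recovery and calibration on synthetic data.
- Node identity is structural, not anatomical: ids depend on the ordering
  rule, and a phantom stands in for the real functional parcellation, which
  users may supply as NIfTI.
- The side-difference criterion is an input flag, never computed.
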