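# Methods

## Scope and data model

`gaitpheno` analyses time-normalized gait cycles from instrumented 3D gait
analysis in children, with paediatric hereditary spastic paraplegia (HSP) as
the motivating cohort. A cycle is the interval between two successive
initial contacts of the same foot, resampled to a fixed grid of 201 epochs
(0.5% spacing, 0–100% of the cycle). Each cycle carries up to ten named
joint-angle channels in degrees — five sagittal (pelvic tilt, hip flexion,
knee flexion, ankle dorsiflexion, forefoot flexion; positive = flexion /
dorsiflexion / anterior tilt) and five non-sagittal (pelvic rotation and
obliquity, hip abduction and rotation, foot progression) — plus the three
within-cycle events (opposite toe-off, opposite initial contact, toe-off)
that bound the support phases, stride time and length, and subject height.
Left and right cycles are treated as independent classification units,
because limb asymmetry is itself a finding of interest.

Phase windows are half-open intervals `[a, b)` in % of cycle: first double
support `[0, OTO)`, single support `[OTO, OIC)`, second double support
`[OIC, TO)`, swing `[TO, 100)`. An epoch at exactly `b` belongs to the next
window; epoch 0 is initial contact. Terminal swing has no universal
definition; here it is the final third of the swing window, exposed as a
parameter (`terminal_swing_fraction`) rather than hard-coded.

Ingestion of non-normalized captures uses monotone piecewise-cubic (PCHIP)
interpolation: kinematic curves are smooth but must not overshoot at peaks,
which rules out unconstrained cubic splines.

## Interpretable parameters

Six spatio-temporal parameters (normalized walking speed, cadence, and the
four phase percentages) and 37 kinematic parameters are computed per cycle.
Every kinematic parameter is a `(channel, window, operator)` rule with
operators in {value_at, min, max, mean, range, time_of_max, time_of_min};
the full rule table is exported as JSON so the mapping is auditable.
Decisions embedded in the table:

* *Normalized walking speed* = (stride length / stride time) / subject
  height, in 1/s. Height normalization is the simplest convention
  consistent with reporting the speed decline in s⁻¹ per year; the rule
  table makes the normalizer swappable (leg length, Froude scaling).
* *Minimum hip flexion* and *maximum knee flexion* are taken over the whole
  cycle (they operationalize peak hip extension in stance and the swing
  knee peak); parameters naming a phase use exactly that phase window.
* *Time-to-peak* parameters report % of the whole cycle, not % of the
  window, and ties at the extremum resolve to the earliest epoch, making
  timing parameters deterministic.
* *Mean hip abduction in first double support and single support* uses the
  union window `[0, OIC)`.

## DTW dissimilarity and pattern definition

The dissimilarity between two cycles is multivariate dynamic time warping
over the five sagittal channels. The local cost between epoch *i* of one
cycle and epoch *j* of the other is the Euclidean norm of the difference of
their 5-channel vectors (all channels share the degree unit, so no
per-channel standardization is applied by default; optional z-scaling is
available). The cumulative cost is minimized over monotone warping paths
with steps (1,1), (1,0), (0,1); diagonal steps — and the starting cell —
carry weight 2, off-diagonal steps weight 1, and the total is normalized by
n + m. Under this convention a purely diagonal alignment of two
equal-length series equals the mean per-epoch cost, distances are
comparable across pairs, and the degenerate 1×1 case returns the raw local
cost. The step pattern and normalization are configuration options
(`symmetric1` and unnormalized variants) since different DTW toolchains
default differently. No warping-window band is imposed: all series have
identical length 201 and the unconstrained dynamic program is cheap (the
inner recursion is JIT-compiled).

Cycles are grouped by unweighted average linkage (UPGMA) on the DTW
dissimilarity matrix: the distance between clusters is the mean of all
cross-pair dissimilarities, which is monotone (no dendrogram inversions).
Patterns are the k flat clusters obtained by undoing the last k−1 merges.
The original analysis chose groups by visual inspection of the dendrogram;
this package replaces that subjective step with an explicit `k` (default 7
= six patterns + one singleton outlier). Labels are renumbered by
decreasing cluster size — pattern 1 is always the largest, mildest group —
with internal merge height breaking ties; singletons are flagged as
outliers and excluded from downstream model fitting (they are scored post
hoc by the pattern forest instead).

## Random forests and permutation importance

Three analyses share one machinery (scikit-learn forests, 1000 trees by
default, classic settings: bootstrap of size n with replacement, node size
1 for classification / 5 for regression):

1. **Pattern forest** — classification of the pattern label from the 43
   parameters, over the mtry grid {1, 3, 6, 12}; goodness of fit is the
   out-of-bag (OOB) misclassification rate, and the best mtry is the one
   minimizing it.
2. **Mild-vs-healthy forest** — regression forest coding healthy cycles 0
   and mildest-pattern HSP cycles 1, mtry grid {1, 14, 29}; goodness of fit
   is the AUC of OOB predictions. OOB (rather than resubstitution) scores
   are used because the training fit of a forest is trivially optimistic.
3. **Clinical forests** — regression forests predicting each clinical
   feature from the parameters, mtry grid {1, 7, 14, 28}; OOB AUC for
   binary targets (sex, GMFCS II–III vs I, polyneuropathy, abnormal VEP,
   thin corpus callosum), OOB Spearman ρ for age.

Variable importance is Breiman–Cutler permutation importance (VIMP): for
each tree, the increase in that tree's OOB error when one predictor is
randomly permuted among its OOB cases, averaged over trees (for
classification this is the mean decrease in accuracy). scikit-learn does
not expose per-tree OOB permutation importance, so the per-tree bootstrap
membership is reconstructed by replaying the forest's own sampling draw;
the reconstruction is verified in the tests against
`oob_decision_function_`. Note that sub-estimators of a classification
forest predict class *indices*, which are decoded through `classes_`
before comparing with labels.

Marginal-effect curves for the top mild-vs-healthy parameters are
*unadjusted*: the scatter of OOB predicted response against the raw
parameter value with a centered running-mean smoother (window = 10% of the
data). Partial-dependence-style adjustment is deliberately not substituted.

With highly redundant predictors (a cohort whose patterns differ in dozens
of parameters at once), classification VIMP is legitimately diffuse: a tree
rerouted past a broken split often recovers via correlated splits below.
Importances concentrate on the discriminating parameters as class overlap
increases.

## Classical statistics

* **Z-scores**: every parameter standardized against the healthy cohort's
  per-parameter mean and SD (cycle-level). Zero healthy SD is an error, not
  a silent NaN.
* **Linear mixed models**: one Gaussian model per spatio-temporal parameter
  with the pattern as fixed effect and a subject random intercept, fitted
  by full maximum likelihood (not REML, because the likelihood-ratio test
  compares fixed-effect structures). The LRT compares against the
  intercept-only mixed model; df = pattern levels − 1. Singular
  random-effect fits are flagged in the output, not dropped.
* **Clinical feature ~ pattern**: linear models with ANOVA F-tests for
  quantitative features; binomial (logistic) models giving per-pattern odds
  ratios for binary features. The dummy coding uses the most common pattern
  as reference. GMFCS III is pooled with II throughout. Perfect separation
  is reported with an `infinite_or` flag. Clinical features are attached to
  cycles (each cycle inherits its subject's record), matching cycle-level
  odds-ratio reporting; this double-counts subjects with many cycles and is
  therefore also the reason the mixed models exist for the quantitative
  outcomes.
* **Robust MM regression** (`parameter ~ age + condition + age×condition`):
  a high-breakdown S-estimate (elemental subsampling, best candidates
  refined by iteratively reweighted least squares at the 50%-breakdown
  bisquare constant c = 1.547) followed by an efficient bisquare M-step at
  c = 4.685 (95% Gaussian efficiency) with the robust scale held fixed.
  Standard errors use the standard MM asymptotic variance. No installed
  package provides MM-estimators, so this stage is implemented here and
  validated against least squares on clean data and under gross
  contamination.
* **BCa bootstrap contrasts**: two-group mean differences with 95%
  bias-corrected and accelerated intervals, resampling cycles within group
  (10,000 resamples by default, explicit seed), reported in raw units and
  in healthy-SD units. The bias correction ẑ₀ comes from the bootstrap CDF
  at the point estimate, the acceleration â from jackknife skewness;
  setting both to zero reproduces the percentile interval, which is used as
  a degenerate-case oracle in the tests, alongside a cross-check against
  `scipy.stats.bootstrap(method="BCa")`.
* **Multiple testing**: none applied, matching the reporting style of the
  source analyses; all p-values are unadjusted and should be read
  accordingly.

## Synthetic cohort generator

The generator exists so every statistical claim in the package can be
exercised against known ground truth. A healthy template per channel is
built from low-order harmonics and Gaussian landmark bumps with physiologic
landmarks (knee-flexion peak ≈ 60° at ≈ 70% of cycle, push-off
plantarflexion before toe-off at 60% stance, knee flexion at initial
contact in the 0–10° band); cadence and height-normalized walking speed
decline linearly with age (speed slope −0.05 s⁻¹ per year). Six pattern
operators perturb the template with the qualitative signatures of the HSP
gait phenotypes (close-to-normal; anterior-tilt/flexed; stiff-recurvatum
knee; crouch-like; recurvatum-equinus; jump-knee-like), applied in a fixed
order: constant offsets → second-harmonic "double hump" modulation → peak
time warps → event-locked Gaussian edits → spatio-temporal scaling.
Severity 0 is the identity and signature deviations grow monotonically with
severity.

Cohort structure: 26 subjects by default, pattern mixture weighted toward
the two mild patterns, 65.4% of subjects using a single pattern, 27% a
different pattern per limb, ~8% two patterns in one limb, 3–5 cycles per
limb per side, and one planted stretched-stance outlier cycle. Noise:
per-subject random channel intercepts (SD 2°), smooth within-cycle noise
(low-pass filtered white noise, SD 1.5°), event jitter (SD 0.8% of cycle),
and multiplicative stride-time/length jitter. Clinical features are drawn
per subject from a per-pattern coupling table (probabilities of GMFCS
II–III, polyneuropathy, abnormal VEP, thin corpus callosum, and per-pattern
age ranges), and severity is coupled to GMFCS (II–III subjects express
their pattern ≈ 20% more strongly), reflecting that GMFCS is itself a
severity scale. Effect magnitudes sit at 2–4 healthy SDs on each pattern's
signature parameters, anchored where published values exist (≈ +10–14°
knee flexion at initial contact and ≈ +6% knee-peak delay in the
severe-GMFCS patterns, equinus offsets well beyond the healthy
plantarflexion band).

What the generator does *not* emulate: marker placement and soft-tissue
artefact, kinetic coupling between joints, within-walk autocorrelation
beyond the subject intercept, missing channels, and genetically distinct
HSP subtypes. Passing the recovery tests therefore shows that the analysis
chain is correct and well-calibrated under the planted statistical
structure, not that real cohorts are this separable.

## Problem sizes and numerical choices

Default analysis sizes (one CPU, minutes): ≈ 210 HSP cycles → ≈ 22,000 DTW
pairs of 201×201 dynamic programs; forests of 1000 trees; 10,000 bootstrap
resamples per contrast. The test suite and the acceptance script scale some
simulations down (forests of 150–400 trees in unit tests, 2,000 resamples
per interval inside the coverage loops, 20 generator seeds for recovery
rates, 500 replicates for calibration checks) — sizes chosen so the whole
suite completes in a few minutes while keeping Monte-Carlo error well below
the asserted tolerances. Floating-point tie-breaks: extrema ties go to the
earliest epoch; linkage ties follow the deterministic SciPy ordering (merge
heights are tie-invariant, which is what the oracle checks); all stochastic
components take explicit seeds, and the pipeline derives per-stage seeds
from one master seed so stages are independently reproducible.

## Known limitations

* The dendrogram cut is a flat k-cut; if the real structure is a manual
  selection of subtrees at different heights, k must be chosen accordingly.
* Cycle-level models treat cycles of one subject as exchangeable beyond the
  random intercept (mixed models) or entirely (forests, odds ratios,
  bootstrap) — subject-level leakage into OOB estimates is possible, as in
  the original design; the per-subject sensitivity view is the usage
  classification, not a clustered bootstrap.
* The logistic "log-linear" models use Wald inference; with few cycles per
  pattern the separation flag should be heeded.
* The MM regression reports asymptotic normal CIs; no small-sample
  correction is applied.
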