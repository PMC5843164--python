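# gaitpheno

Phenotyping of paediatric gait from whole time-normalized gait cycles.

Children with hereditary spastic paraplegia (HSP) — and other motor
disorders — walk with heterogeneous, asymmetric gait abnormalities.
Clinical practice summarizes instrumented 3D gait analysis with isolated
parameters (an angle at one instant, a range over one phase), which loses
the structure of the whole cycle. `gaitpheno` implements the complementary
pipeline: classify *entire* multichannel gait cycles by similarity, then
translate the resulting patterns back into the interpretable parameters and
clinical features clinicians use. It is a library for movement-analysis and
clinical-biostatistics researchers, with a thin CLI for running the full
pipeline.

## What it computes

**Dissimilarity and patterns.** Each cycle is a matrix of 201 epochs × 5
sagittal joint angles (pelvis, hip, knee, ankle, forefoot; degrees). The
dissimilarity between cycles *a* and *b* is multivariate dynamic time
warping,

    D(a, b) = (1 / (n + m)) · min over warping paths π of
              Σ_(i,j)∈π  w_ij · ‖a_i − b_j‖₂ ,

with weight w = 2 on diagonal steps (and the start cell), 1 otherwise.
Cycles are grouped by unweighted average linkage (UPGMA),
d(A, B) = mean over a∈A, b∈B of D(a, b), and patterns are the k flat
clusters of the dendrogram (default k = 7: six patterns + a singleton
outlier). Per-subject usage is classified as one pattern, a different
pattern per limb, or two patterns in one limb.

**Interpretable parameters.** 43 per cycle: 6 spatio-temporal (normalized
walking speed (stride length/stride time)/height in 1/s, cadence = 2/stride
time, and the stance/double-support/single-support percentages) and 37
kinematic values defined by auditable (channel, window, operator) rules.

**Random forests.** Classification forests (1000 trees, mtry ∈ {1,3,6,12})
predict the pattern from the 43 parameters, scored by out-of-bag (OOB)
error; regression forests separate the mildest HSP pattern from healthy
cycles (mtry ∈ {1,14,29}, OOB AUC) and predict clinical features
(mtry ∈ {1,7,14,28}, OOB AUC or Spearman ρ). Importance is Breiman–Cutler
permutation VIMP: the mean increase in a tree's OOB error when one
predictor is shuffled.

**Clinical statistics.** Z-scores against the healthy cohort; per-parameter
linear mixed models `y ~ pattern + (1 | subject)` with likelihood-ratio
tests (ML fits, χ² with df = patterns − 1); linear/logistic models of
clinical features on dummy-coded pattern (largest pattern as reference,
odds ratios for binary features); robust MM regressions
`parameter ~ age × condition` (S-estimate + bisquare M-step); and two-group
mean contrasts with 95% BCa bootstrap intervals in raw and healthy-SD
units.

**Synthetic cohorts.** A generator with known ground truth plants six
pattern signatures (anterior pelvic tilt with "double hump", crouch,
recurvatum, equinus, jump-knee, …), subject random effects, limb asymmetry,
an outlier cycle, and clinical features coupled to pattern membership — so
every stage of the pipeline is testable end to end.

## Worked example

`examples/01_cluster_gait_patterns.py` generates a 12-subject cohort with
planted patterns, clusters it, and compares against the ground truth:

```
96 cycles from 12 subjects

Cluster sizes (pattern 1 = largest):
 pattern  n_cycles  fraction  outlier
       1        37  0.385417    False
       2        19  0.197917    False
       3        13  0.135417    False
       4        12  0.125000    False
       5         8  0.083333    False
       6         6  0.062500    False
       7         1  0.010417     True

Per-subject pattern usage:
               usage_class  n_subjects  fraction
            single pattern          10  0.833333
different pattern per limb           2  0.166667
  two patterns in one limb           0  0.000000

Adjusted Rand index vs planted labels: 1.000
```

The k = 7 cut recovers the six planted patterns exactly (ARI 1.0) and
isolates the planted stretched-stance cycle as the singleton outlier.
`examples/02–04` walk through parameter extraction (a crouch-pattern cycle
raises knee flexion at initial contact from 7.3° to 30.7° and delays the
knee peak from 70% to 77% of the cycle), forest importance (knee flexion at
initial contact tops the VIMP ranking on a noisy cohort, OOB error 2.6%),
and the clinical statistics (the MM regression recovers the planted
−0.05 s⁻¹/year decline of normalized walking speed as −0.0504 ± 0.0006).

Full pipeline from the shell:

```sh
gaitpheno run-all --out run1 --seed 7          # synthetic default cohort
gaitpheno report --run-dir run1
```

`run1/` then contains every artifact (parameter matrices, DTW distances,
Newick dendrogram, pattern assignment, VIMP tables, model tables, contrast
tables) plus `manifest.json` recording each stage, its outputs, hashes and
seeds.

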