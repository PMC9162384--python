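# Methods

This note documents the statistical model the package implements, the
defaults and why they were chosen, what the synthetic generator emulates, the
numerical implementation choices, and known limitations.  Problem sizes
(29/27 subjects, 116 regions, 170 time points, 5,000 permutations) are the
package's own default study conditions; every one of them is overridable.

## 1. Data model

A cohort consists of `n_patients + n_controls` subjects.  Per subject the
package handles:

- five regional metrics over an `R`-region atlas (default `R = 116` with
  regions 91–116 forming a cerebellar block): gray-matter volume (GMV),
  white-matter volume (WMV), fractional anisotropy (FA), mean diffusivity
  (MD) and tractography fiber count;
- an `R × R` functional-connectivity (FC) matrix, the Pearson correlation of
  region-averaged BOLD time series (`T = 170` time points by default);
- clinical covariates: age, gender, and for patients UMSARS-I/II (summing
  exactly to UMSARS-total), disease duration, MoCA, HAMA, HAMD.

The parcellation module maps voxel data to this representation: region means
of metric volumes (background label 0 ignored; empty regions yield NaN with a
warning), streamline incidence counts (a streamline counts at most once per
region; membership by `floor(point / voxel_size)` on a corner-origin grid),
and region-averaged time series.  NIfTI volumes are read with nibabel,
TCK/TRK streamlines with `nibabel.streamlines`; a JSON polyline dialect
exists for small text fixtures.

## 2. Group statistics

**Region-wise contrast.**  Two-sided pooled-variance (Student) t-test per
region, patients minus controls.  Pooled variance is the default because the
two groups are similar in size and the generator draws them with equal
variance; Welch's form is available (`welch=True`).  Zero-variance columns
give t = 0, p = 1 with a warning; regions with fewer than 2 values in a group
are excluded with a warning, never silently zeroed.

**Multiplicity.**  Benjamini–Hochberg step-up across the R regions,
separately per metric (each metric is its own family; pooling families would
couple unrelated hypotheses).  Significance is adjusted p strictly below
alpha: 0.001 for discovery (a deliberately strict gate given five metric
families), 0.05 for the classifier's feature gate (feature selection can
afford a conventional level because the classifier is validated by nested
cross-validation, not by the gate).  `bh_fdr` wraps
`statsmodels.multipletests(method="fdr_bh")`; the test suite checks it
against an independent step-up implementation.

**Demographics.**  Age: independent-samples t (p forced to 1 when the two
age samples are identical as multisets).  Gender: Pearson chi-square with
1 df on the 2×2 table **without** continuity correction — the worked example
(18 M/11 F vs 11 M/16 F → p = 0.110) pins this choice; Yates' correction
would give ≈ 0.184.

**Clinical correlation.**  Pearson r between each discovery-significant
feature and the patients' UMSARS-total, selected at raw p < 0.001 (strict).
Before correlating, subjects are screened on a normal Q-Q basis.  A visual
Q-Q call is not reproducible, so the screen is backed by a robust-z rule:
flag |x − median| > k · 1.4826 · MAD with `k = 3.5` (a conventional
far-outlier cut; at normality the expected false-flag rate for n ≈ 29 is
well below one subject).  A manual exclusion list overrides/augments the
automatic rule; when the MAD is zero the automatic rule is disabled with a
warning.

## 3. Extended network-based statistics

Edgewise pooled t-tests over the upper triangle of the FC stack give a
symmetric p-value "difference network".  Edges with raw p strictly below a
pre-defined threshold (default 0.001) form a binary network; its connected
components with at least one edge, sized by the number of member regions, are
the candidate effects.  Signs (increased/decreased in patients) annotate the
edges but do not split components.

Significance: group labels are permuted (group sizes preserved), the chain is
re-run, and the maximal component size per permutation forms the null.  The
default estimator is

    Emp_pval(s) = #{ permutations with max size > s } / n_perm

declared significant at Emp_pval < 0.05.  **This strict estimator is
anticonservative** when the observed component's size ties the null mode: a
size-2 component is "beaten" only by null maxima of 3+, so sparse nulls give
Emp_pval = 0 for effects that are pure noise.  Measured on null cohorts
(29/27, 30 regions, threshold 0.001, 200 permutations), the family-wise
false-positive rate is ≈ 0.34 rather than 0.05.  The estimator is kept as
the default because it is the procedure's literal definition; callers who
need calibration should pass `plus_one=True`, which switches to the standard
conservative form `(#{ ≥ s } + 1) / (n_perm + 1)` (measured type-I ≈ 0.01 in
the same setting and never returns 0).

The threshold sweep (0.0001 → 0.0010 in steps of 0.0001) reuses the identical
permutation label sequence for every threshold, so null distributions are
comparable across thresholds and per-permutation maxima are monotone in the
threshold.  `n_perm = 5000` gives empirical-p resolution 2 × 10⁻⁴; a warning
is emitted when `n_perm < 20 / alpha`.

Implementation: the permutation loop computes all edgewise |t| via a BLAS
formulation (group sums of x and x² against a 0/1 indicator) and compares
against the fixed t critical value per threshold instead of converting to
p-values; connected components come from `scipy.sparse.csgraph` on the
node-compressed subgraph.  The suite verifies the fast path against a literal
per-permutation re-run of the full `edgewise_stats → binarize → components`
chain, and the component finder against exhaustive subset enumeration and an
independent DFS.

## 4. Per-region classification

For each region, features are fused in a fixed order: the regional metrics
(GMV, WMV, FA, MD, fiber count) whose group contrast survives the FDR gate at
that region, then the FC edges incident to the region inside significant NBS
components (sorted by node pair).  Regions with no surviving feature are
"unclassifiable" and reported as such.

Evaluation is nested leave-one-out cross-validation on the default 56
subjects: the outer loop holds out one subject; an inner leave-one-out loop
over the remaining 55 scores each C in the grid
`(0.001, 0.01, 0.1, 1, 10, 100, 500, 1000, 5000, 10000)`; the best C (ties →
smallest C) is refit on all inner subjects and applied to the held-out
subject.  Standardization ((x − mean)/sd, sample sd) is estimated on the
training fold only, so neither the scaler nor the C choice ever sees the
held-out subject; `global_scaling=True` reproduces a single global
standardization pass for comparability, which is leaky by construction and
off by default.  Patients are the positive class; accuracy, sensitivity
(TP/(TP+FN)) and specificity (TN/(TN+FP)) come from the pooled outer-fold
confusion matrix, the ROC/AUC from the pooled decision values (trapezoid
rule).  Region ranking sorts by accuracy, then AUC, then region index, with a
strict `accuracy > 0.90` high-performer view.

**SVM solver.**  The model is the L2-regularized **squared-hinge** linear SVM
in the primal (the objective liblinear's `L2R_L2LOSS_SVC` solves, intercept
penalized).  The nested protocol needs ~3,100 fits per region × the C grid;
generic SMO-based solvers take ~90 ms per fit at large C, which is
infeasible.  The objective is convex, differentiable and piecewise quadratic,
so a damped Newton method with an active-set Hessian reaches the exact
minimizer in a handful of iterations at any C; warm-starting across the
ascending C grid reduces most fits to one Newton step (~1 ms for the whole
grid).  The solver is deterministic, and the suite enforces agreement with
`sklearn.svm.LinearSVC(dual=False)` to ~1e-5 and near-zero gradients at the
returned solution.  The plain hinge loss would weight margin violations
linearly instead of quadratically; at the separation levels relevant here the
selected models are practically identical, and the squared-hinge choice is
what liblinear-based software fits by default anyway.

## 5. Synthetic cohort generator

The generator emulates the default study conditions with known ground truth:

- **Sizes** 29 patients / 27 controls / 116 regions, T = 170.
- **Regional metrics** are i.i.d. normal per region with metric-specific
  baselines (GMV 0.45 ± 0.05, WMV 0.35 ± 0.05, FA 0.45 ± 0.06,
  MD 8·10⁻⁴ ± 8·10⁻⁵, fiber count 1200 ± 300 — plausible magnitudes for
  tissue-probability means, DTI scalars and streamline counts).  Group
  effects are Cohen's d shifts applied to patients: GMV d = −2 in all 26
  cerebellar regions (widespread atrophy), and focal d = ±1.5 effects for
  WMV, FA (decreases), MD (increase) and fiber count in small cerebellar
  subsets.  FA is clipped to [0, 1]; fiber counts are rounded to non-negative
  integers.
- **FC** is generated by sampling T × R multivariate-normal time series from
  an equicorrelation structure (base r = 0.1) whose Cholesky factor carries
  planted edge deltas (|Δr| = 0.4 on nine edges forming two cerebro-cerebellar
  components) for patients, then computing the Pearson matrix through the
  same `fc_matrix` code path real data would take.  Non-positive-definite
  planted structures are rejected with a clear error.
- **Clinical** scores reproduce study-style marginals (UMSARS-I 17.34 ± 5.65,
  UMSARS-II 17.07 ± 5.66, total sd 10.42, ages ≈ 57.6/57.4, 18/29 vs 11/27
  male — drawn as exact per-group counts).  UMSARS-total is a linear blend of
  standardized planted features plus independent noise, so each targeted
  feature carries its requested population correlation (defaults: FA at two
  cerebellar regions and one fiber count at ρ = −0.5); UMSARS-I + II equals
  the total exactly by construction.
- **Seeding**: one master seed spawns independent child streams (regional,
  FC, clinical, phantom) via `numpy.random.SeedSequence`, so changing, say,
  the clinical couplings never perturbs the imaging draws.
- A voxel-space **phantom** (ellipsoid mask, contiguous-slab parcellation,
  piecewise-constant metric volumes, straight polyline streamlines,
  region-constant BOLD) provides exact ground truth for the parcellation
  module.

## 6. Determinism and the pipeline

`run_pipeline` executes simulate → stats → nbs → classify → report from one
config.  Per-stage seeds derive from the master seed through
`SeedSequence.generate_state` (masked below 2³¹); every output is plain text
with `%.10g` floats; the manifest records the config hash, stage seeds and
SHA-256 checksums of all artifacts.  Reruns with identical config + seed are
byte-identical (verified in the suite at 5,000 permutations).  When the
configured atlas is smaller than 116 regions, planted structure referencing
out-of-range regions is dropped — never relocated — so shrunken runs remain
valid without inventing new ground truth.

## 7. Limitations

- The strict NBS empirical-p estimator is anticonservative (see §3); the
  calibrated `plus_one` variant is provided but not the default.
- Detecting a planted feature–severity correlation of |ρ| = 0.6 at raw
  p < 0.001 with n = 29 patients has power ≈ 0.57; analyses at that gate
  should expect to miss real couplings of that size half the time.
- Clinical scores are unbounded Gaussians: a sampled MoCA can exceed the
  instrument's ceiling of 30.  Clipping would bias the targeted marginal
  means/SDs, so values are left unclipped and the scores should be treated
  as continuous proxies.
- Regional metrics are independent across regions (no spatial covariance);
  FC uses a single equicorrelation background rather than a realistic
  modular connectome.
- The Q-Q outlier screen's robust-z rule is a reproducible stand-in for a
  visual call; `k = 3.5` is conventional, not adaptive.
- `global_scaling` exists only to reproduce globally standardized
  results and is knowingly optimistic; all defaults use fold-wise scaling.
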