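# Methods

## The analysis problem

A block-design trait-judgment task measures brain activity while
participants hold a known person in mind: romantic partner, parent (young
adults) or adult child (older adults), close friend, familiar acquaintance,
a famous person, the self, and a button-press motor control. Two cohorts
(young n = 29, older n = 27) complete 5 runs × 14 blocks × 5 trials
(350 trials), two blocks per condition per run, blocks separated by 10 s
fixation. The famous condition is excluded from analysis (participants
cannot reliably hold an unfamiliar other in mind within the trial window).

The package answers two questions with one multivariate machinery:

1. **Task activation** — which whole-brain activity patterns covary with
   the group × condition design (mean-centered task PLS)?
2. **Seed connectivity** — which whole-brain patterns of across-subject
   correlation with a medial-prefrontal seed vary with condition and
   group (seed PLS)?

## Activity reduction

Per subject, each block's voxel means are baseline-normalized against the
mean of the fixation period preceding the block, then averaged over that
condition's blocks, giving a voxel × condition matrix per subject.

* *Normalization convention.* "Relative to fixation" is implemented as
  subtraction (block − fixation), which is scale-preserving; percent
  signal change is available (`mode="percent"`). Subtraction is the
  default because the downstream decomposition is covariance-based and a
  shared multiplicative rescaling is absorbed by the saliences.
* *Baseline window.* The full inter-block fixation preceding the block;
  the first block of a run uses the run's initial fixation. The 1 s
  inter-trial fixations are too short to serve as baselines and are not
  used.
* Averaging and normalizing are both linear, so their order is
  irrelevant; this is asserted by a property test.

## Mean-centered task PLS

Stack the group × condition cell means (12 cells after exclusions) into a
cells × voxels matrix **M**, subtract the per-voxel grand mean over all
rows (single centering with groups stacked; per-group centering is an
option), and take the thin SVD, **M**ᶜ = **U S V**ᵀ:

* **U** — design saliences (cells × LV, orthonormal columns),
* **V** — voxel saliences (voxels × LV, orthonormal columns),
* **S** — singular values; LV k accounts for 100·s²ₖ/Σ s²ⱼ percent of the
  crossblock covariance.
* brain score of subject i, condition c on LV k: xᵢ꜀ᵀ **v**ₖ.

After grand-mean centering the matrix has rank ≤ cells − 1, so the last
LV is numerically null. Signs of an SVD are arbitrary; each LV is
oriented so its largest-magnitude design salience is positive. Because
the decomposition treats all voxels in a single step and inference is at
the LV level, no voxel-wise multiple-comparison correction is applied.

## Seed PLS

A seed ROI is a peak voxel plus its 26 face/edge/corner neighbors (the
3×3×3 cube is the unique shape with exactly 26 neighbors); out-of-mask
neighbors are dropped with a warning. Per group × condition cell, the
seed-neighborhood mean is Pearson-correlated with every voxel across that
cell's participants (≥ 3 required; a zero-variance seed or voxel maps to
r = 0 with a log notice rather than propagating non-finite values). The
stacked cells × voxels correlation matrix is decomposed by SVD
**uncentered** — correlations are already reference-free — with optional
column centering. The motor control condition is excluded by default
(connectivity is examined across the social conditions and self). Per
cell, the Pearson correlation between participants' LV brain scores and
their seed values (with bootstrap percentile CIs) summarizes how strongly
the cell expresses the pattern. Seed voxels are retained in the voxel
dimension; their trivially strong saliences are expected and reported.

Correlations are computed per group × condition cell, matching the
per-cell bars of the connectivity figures; pooling participants across
groups before stacking would conflate group differences with shared
structure.

## Resampling inference

* **Permutation test on singular values.** Each participant's condition
  labels are independently reordered (group labels untouched; the
  reordering acts on the condition-mean matrices, the analysis input) and
  the entire pipeline — averaging, centering/correlation, SVD — is
  recomputed. pₖ = #(permuted sₖ ≥ observed sₖ) / n_perm (raw proportion;
  the smallest nonzero value at the default 500 permutations is 0.002).
  An optional (count+1)/(n+1) correction is provided but not default.
* **Bootstrap reliability.** Participants are resampled with replacement
  *within group* (stratified — required to preserve the group × condition
  design) and the pipeline recomputed. Resampled saliences are aligned to
  the originals by orthogonal procrustes rotation computed on the design
  side and applied to both sides (sign-flip-only and no-alignment modes
  are available; a rank-deficient reference falls back to sign flips).
  The bootstrapped quantity is the **singular-value-scaled salience**
  (column of **V S**, i.e. the voxel's covariance with the design
  contrast): this is the canonical choice in this method family, and it
  is free of the unit-norm coupling across voxels that makes bootstrap
  SEs of the normalized singular vectors slightly too small. The
  bootstrap ratio BSR = scaled salience / bootstrap SE is treated as
  Z-like and thresholded at |BSR| ≥ 2.58 (two-tailed 1%). Exact-zero SEs
  (degenerate resamples) yield a ±∞ sentinel that thresholded maps
  exclude; SEs below 1e-12 of the salience scale are snapped to zero
  because floating-point summation leaves ~1e-16 residue even on
  bit-identical resamples.
* **Score intervals.** 95% intervals on cell-mean brain scores are
  bootstrap percentile intervals over the same stratified resamples —
  the published figures show 95% CIs without stating their construction,
  so this is an interpretation, flagged as such.
* 100 bootstrap iterations (the default, matching the study's procedure)
  yields coarse SEs; users wanting stable voxelwise maps should raise
  `n_boot`.

## Peak tables

Reliability maps are summarized as peak tables: local maxima of |BSR|
over the 26-connected neighborhood, above threshold, greedily pruned so
no two peaks of the same sign lie within `min_separation_mm` (default
10 mm), sorted by |BSR| within sign, reported in MNI mm through the mask
affine. The original peak-selection rules are unstated, so these
parameters are exposed as conventions. Voxel vectors are the in-mask
voxels in row-major order over the grid; this contract is enforced by
round-trip tests.

## Behavioral measures

* **WHOTO** (10 items, up to 4 figures listed per item in order): a
  target listed at rank r contributes 5 − r points, so the maximum over
  10 items is exactly 40 — the instrument's reported ceiling. The exact
  per-rank weights are not published; 5 − r is the unique linear scheme
  with that ceiling.
* **IOS**: consumed as a 1–7 integer.
* **Group tests**: pooled-variance two-sample t (df = n₁ + n₂ − 2), with
  F = t² also reported because the published "t(1, 54)" notation reads as
  an F with one numerator df; the pooled test reproduces the published
  values from the summary statistics (Welch is offered as an option).
  Zero pooled variance with equal means yields t = 0; with unequal means
  the statistic is undefined and refused.
* **Friedman test**: within-subject ranks (average ranks on ties),
  χ² = 12/(nk(k+1))·ΣRⱼ² − 3n(k+1), df = k − 1 — invariant to any
  strictly monotone per-subject transform; cross-checked against an
  independent implementation on tie-free data.

## The synthetic generator (study conditions)

No subject-level scan data are deposited, so the pipeline is validated
against a generator with known ground truth. Its defaults are the study
conditions and are not tuned per analysis:

| parameter | default | rationale |
|---|---|---|
| groups | young 29, older 27 | the study's cohort sizes |
| design | 5 × 14 × 5, 7 conditions | the study's block design |
| grid | 12×12×12 voxels (1728), 8 mm | smallest grid that keeps whole-brain-like voxel counts tractable; the shipped mm seeds fall inside |
| noise | i.i.d. Gaussian, sd 1, at the block-average level | the analyses consume block averages; no temporal model is needed at that granularity |
| planted effects | social-vs-control (both groups) and partner/self-vs-parent/friend (young only), 64 disjoint voxels each, amplitudes 1 and √60/4 | emulates the two reported task contrasts; disjoint supports make the patterns orthogonal and the amplitude ratio fixes the planted crossblock split at exactly 80/20 |
| behavioral targets | the published instrument summaries (means, sds) per group × condition | the generator's emulation targets |

Behavioral draws are clipped Gaussians; the latent mean is calibrated
(closed-form clipped-normal expectation + root finding) so the clipped
expectation equals the target — plain clipping would bias a mean ~1 sd
from a bound by about half a point. IOS values are rounded to the 1–7
grid. Within-subject block-to-block variance is not published; the
block-level expander exposes it as a parameter (`within_block_sd`)
rather than fixing it.

Seed couplings are planted by rebuilding target voxels as
r·z + √(1−r²)·residual against the standardized seed mean, where the
residual mixes a region-level component shared across the target voxels
(50% of residual variance by default) with voxel-specific noise: a
genuinely coupled region fluctuates coherently, and the shared component
keeps the region-aggregate correlation near the planted per-voxel r
instead of inflating toward 1 by averaging.

**What the generator does not emulate:** hemodynamics, temporal
autocorrelation, motion or physiological artifacts, spatial smoothness,
and anatomical structure. Passing recovery tests therefore shows the
*estimator machinery* is correct and calibrated under the assumed noise
model — not that the pipeline is robust to preprocessing failures or
spatially correlated noise in real data.

## Validation studies and problem sizes

`socialpls.calibration` packages four studies, used by the test suite and
the acceptance script:

* **Null calibration** — no planted effects; LV1 permutation p-values over
  200 replicates at 100 permutations each are compared to uniform by KS
  test. Run on a 200-voxel grid: the null p-value distribution does not
  depend on grid size, and the small grid keeps the study cheap.
* **Task-LV recovery** — 50 replicates at the study ns; both planted LVs
  must show |salience correlation| > 0.9 with their patterns and
  permutation p ≤ 0.05 (100 permutations per replicate — a 0.05 decision
  needs far fewer than 500).
* **BSR calibration** — a single ±1 contrast planted at amplitude/noise
  = 1.5; over 50 replicates at 100 bootstrap iterations, null voxels
  exceed |BSR| 2.58 at ≈ 1–1.6% (nominal 1%; the excess reflects the
  ~100-df SE estimate and the bootstrap's small-sample downward SE bias)
  and planted voxels are flagged essentially always.
* **Seed-coupling recovery** — r = 0.6 planted in the (young, partner)
  cell, 64 target voxels, n = 100 per group; recovery means the planted
  cell carries the largest |brain-score × seed| correlation on the LV
  whose saliences best match the planted pattern.

## Numerical choices and degenerate inputs

* SVD via LAPACK thin SVD; oracle-checked against eigendecomposition of
  **M Mᵀ** on random matrices (reconstruction < 1e-8).
* LV sign: largest-magnitude design salience positive.
* Ties in WHOTO ranks cannot occur (an item lists distinct figures);
  ties in Friedman ranks get average ranks.
* Empty cells, non-finite activity, out-of-mask peaks, unknown condition
  labels, and invalid configurations raise errors naming the offender.
* All randomness flows through explicitly passed numpy Generators; every
  workflow is deterministic given its seed.

## Known limitations

* The dmPFC seed default follows the methods coordinate (−6, 54, 30),
  which differs from the reported dmPFC activation peak (−8, 54, 32); the
  discrepancy is documented, not resolved — pass your own coordinate to
  override.
* Whether the original analysis procrustes-aligned bootstrap resamples,
  or stratified its permutations by group, is unstated; both are exposed
  as flags (`align`, and permutations always preserve group labels).
* The omnibus MANOVA (Wilks' Λ) tests are not recomputable from published
  summaries and are out of scope; the recomputable post hoc tests are
  implemented.
* No anatomical labeling, spatial smoothing, GLM/HRF modeling, or
  resting-state analysis.
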