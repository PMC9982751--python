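# Methods

This note documents the models, estimators, parameters, and numerical
conventions behind `uwfvm`, and what the synthetic validation does and
does not establish about real ultra-widefield (UWF) images.

## Conventions

Pixel coordinates are 0-based `(row, col)`; angles are reported in
degrees; binary masks and skeletons are boolean arrays aligned with
their source frame. The default frame is 975 × 768 px, a quarter-scale
UWF frame chosen so the test suite runs in minutes; the full
3,900 × 3,072 frame is available via `SyntheticSpec.at_full_scale()` or
`--full-scale`, and all geometry (disc/macula position, field-of-view
radius, step lengths, calibers) scales linearly with the frame, so the
two are geometrically similar. Pixels outside the circular field of
view (FOV) — the dark corners of a UWF frame — are zero in images and
excluded from every measurement.

## Synthetic UWF generator

### Vessel growth

Vascular trees are grown as a stochastic branching walk, one step ≈ 2 px
(quarter scale):

* **Roots.** `n_root_vessels` (default 6) trunks start on the optic-disc
  rim, fanned ±2.1 rad around the temporal direction, in disjoint
  angular sectors with small jitter.
* **Steering.** Each step perturbs the heading by N(0, `tortuosity`)
  and pulls it toward an outward spiral around the macula
  (tangential-plus-radial blend, pitch 0.55 rad, gain 0.10 fading by
  0.55 per branching generation). This reproduces the temporal-arcade
  geometry that the vessel-angle metric presumes. An optional
  `axis_alignment` gain additionally pulls headings toward the
  macula–disc axis, emulating the arcade straightening that accompanies
  globe elongation.
* **Branching.** While the tree holds fewer than `target_branch_count`
  segments, a tip bifurcates with probability `branch_prob` per step
  into two children deflected by ±10–25° each; child caliber is the
  parent's × `width_decay` (0.92). The budget cap is what makes the
  emitted segment count track the target (within ±10% in expectation),
  while `branch_prob` controls where along the tree branching happens.
  Bifurcation is disallowed within ~6 steps of a segment's birth, near
  the FOV rim, and inside the disc neighborhood, so every segment is
  long enough to survive skeletonization and junction removal.
* **Termination and avoidance.** Tips stop at the FOV boundary, below
  the 0.8 px drawable caliber (calibers also taper by 0.9975 per step
  along a vessel, so unbranched trunks cannot run forever), or when
  approaching another vessel's centerline within ~`root_width + 2` px.
  The avoidance rule reflects the near-planar, essentially
  non-anastomosing retinal arterial/venous trees, and it is what makes
  skeleton junctions correspond one-to-one with true bifurcations — the
  property the branch-count recovery tests rely on. Avoidance is
  suspended near the disc, where real vessel trunks do overlap; the
  rare vessel crossings there are the main residual source of
  branch-count error (measured/true ratios on clean eyes are ≈
  0.94–1.03).

### Rendering

Segment centerlines (calibers quantized to 0.25 px) are rasterized, and
the binary mask is the exact union of caliber disks swept along them
(computed per caliber with a Euclidean distance transform), clipped to
the FOV, **before** any noise — so the ground truth is pixel-exact. The
image draws that stencil dark-on-light with a ~0.5 px anti-aliased edge
(default vessel contrast 60 intensity units) over a background of
radial vignette, gentle horizontal gradient, grade-scaled blotchy
choroidal "tessellation" texture (Gaussian blobs of ~24 px scale), and
additive Gaussian noise (`noise_sigma`, default 6 on the 8-bit scale).
No published acquisition-noise model exists for this hardware; these
are assumption-labeled defaults, not device physics.

### Grades and covariates

Severity grades (healthy controls HC plus maculopathy grades C0–C4)
parameterize the generator only — measurement code never sees the
grade — so severity-recovery tests are not circular. The default grade
map encodes the clinically reported direction of every effect:

| grade | branch budget | branch prob | tortuosity | tessellation | root caliber (px) | axis alignment |
|-------|--------------|-------------|------------|--------------|-------------------|----------------|
| HC | 271 | 0.095 | 0.082 | 4 | 3.5 | 0 |
| C0 | 290 | 0.100 | 0.085 | 4 | 3.4 | 0 |
| C1 | 251 | 0.090 | 0.078 | 10 | 3.2 | 0.002 |
| C2 | 189 | 0.080 | 0.071 | 14 | 3.0 | 0.004 |
| C3 | 164 | 0.070 | 0.062 | 18 | 2.8 | 0.006 |
| C4 | 125 | 0.060 | 0.052 | 22 | 2.6 | 0.008 |

Branch budgets are the reported per-grade means of vascular branch
counts in graded highly myopic cohorts; caliber narrowing and arcade
axis-alignment with severity encode the reported vessel-caliber decline
and arcade-angle narrowing of elongated eyes, and together they make
expected density, branch count, complexity (Df), and vessel angle all
decline with severity. Covariates (age in years, axial length in mm,
visual acuity in logMAR) are drawn per grade from independent truncated
normals with the published per-grade means ± SD; cross-correlations
between covariates and morphometry therefore arise through grade alone,
which is exactly what per-grade mean ± SD tables constrain.

The paired neovascular simulation (`simulate_paired_morphometry`)
models matched case/control eyes in which the case arm has vessel
density higher by 0.62 percentage points (pair SD 0.8) and ≈ 24 more
branches — the reported between-arm gaps — at the morphometry level,
since neovascular membranes are not rendered.

## Segmentation

**Tiling.** Frames are zero-padded right/bottom to multiples of the
tile size (default 576) and cut into non-overlapping row-major tiles;
recombination concatenates and crops, an exact inverse (property-tested
over frame dims 1…1152). No blending is used, matching a plain
crop-and-combine protocol.

**Vesselness baseline.** The Sato tubularity response (dark ridges,
scales 1.0/1.6/2.6 px) is maximized over scales inside an FOV eroded by
4 px (the rim is a strong artificial ridge), then hysteresis-thresholded
at the 0.966/0.972 response quantiles computed within the FOV. Quantile
thresholds make the output invariant to positive intensity rescaling.
The quantile pair was calibrated once against the clean reference eye
(F1 ≈ 0.92; across clean eyes ≈ 0.85–0.92): a fixed quantile is
implicitly a prevalence assumption, which is the known limitation of
non-learned baselines.

**Trainable segmenter.** A compact pixel classifier: per-pixel features
are the z-scored intensity plus, at scales 1/2/4 px, the Gaussian-smoothed
intensity, gradient magnitude, and both Hessian eigenvalues (13
features), fed to a 13→16→1 MLP (ReLU/sigmoid, 241 parameters) written
in numpy with explicit epoch control, deterministic seeding, and
lossless checkpoints. Training follows the two-stage transfer recipe:
pretrain on tiles from a regular-fundus-like (45°-field) synthetic
corpus, then fine-tune the same weights on UWF tiles; a scratch control
trains on the UWF tiles alone for the same number of epochs. Pixels are
sampled class-balanced per tile (default 400/tile), optimized with Adam
(lr 3 × 10⁻³, batch 512, binary cross-entropy). Prediction computes
per-tile probability maps, recombines them by exact untiling, and
thresholds at 0.5 (configurable). The transfer benefit is asserted in
the scarce-annotation regime (1 epoch) where the pretrained features
matter; with generous epochs both arms saturate on this easy synthetic
task and the gap closes — which is itself the expected behavior of
transfer learning.

**Evaluation.** Confusion counts are accumulated inside the FOV only
(the dark corners would inflate true negatives). Accuracy, sensitivity,
specificity, precision are fractions in [0, 1]; F1 is also reported
× 100 following the vessel-segmentation literature. Precision and F1
are defined as 0 (and flagged) when no positives are predicted. Both
micro- (pooled counts) and macro- (per-image mean) averages are
reported, because the two differ on heterogeneous sets and published
summaries rarely say which was used.

## Morphometry

All four metrics derive from one skeletonization (Zhang thinning via
scikit-image, plus a cleanup pass that deletes simple pixels of
residual 2 × 2 blocks; blocks where no pixel is simple — thick diagonal
crossings — are left intact because thinning them would change
topology).

* **Vessel angle.** Local orientation at each skeleton pixel is the
  principal axis of skeleton-pixel coordinates in a (2r+1)² window
  (r = 5 px default), computed in closed form from windowed first and
  second moments (uniform filters), i.e. a length-weighted orientation
  field. The acute angle to the macula→disc axis lies in [0°, 90°]
  (sign of the axis is irrelevant under the acute convention); the
  skeleton-pixel mean is returned; windows holding < 3 skeleton pixels
  are skipped. Exactness: straight lines parallel/perpendicular/at
  known angles reproduce 0°/90°/analytic means within 1°.
* **Df.** Box counts N(ε) on grids anchored at the skeleton's
  bounding-box origin, ε = powers of 2 from 2 px up to a quarter of the
  shorter bbox side (falling back to 2/4/8 for thin objects so a line
  is measurable); Df is the OLS slope of log N vs log 1/ε. Df is
  computed on the skeleton by default — caliber would otherwise
  confound complexity — with a mask-mode flag for sensitivity analysis.
  Box counts are verified against a brute-force double-loop scan, and
  the estimator reproduces the analytic dimensions of a line (1), a
  filled square (2), and the Sierpinski triangle (log 3/log 2).
* **Vessel density.** 100 × vessel pixels / area of the convex hull of
  vessel pixels. "Removing the avascular surround" has no unique
  definition; the hull is reproducible and parameter-free, and FOV-disc
  and bounding-box denominators are available via `region_method`.
  Because the denominator convention moves absolute densities,
  cross-study comparison of magnitudes requires the same convention; a
  degenerate (collinear) hull yields 100% with a warning.
* **Branch count.** Junction pixels are skeleton pixels with ≥ 3
  skeleton neighbors (8-connectivity); removing them splits the
  skeleton into segments, and 8-connected components with ≥
  `min_branch_len` (5 px) pixels are counted, suppressing thinning
  spurs.

Invariances (tested): exact translation invariance; joint 90°-rotation
invariance (angle within 1°, branch count within a small rasterization
tolerance since thinning is not exactly equivariant); integer-upscaling
stability of density, Df, and branch count.

## Statistics

Eyes are the analysis unit; correlation between fellow eyes of one
subject is deliberately not modeled (an acknowledged limitation of
eye-level cohort analyses, matched here for fidelity). Tests are thin,
contract-checked wrappers over scipy.stats: one-way ANOVA, Pearson
chi-square without continuity correction, pairwise grade comparisons
(default: uncorrected two-sided Welch t for all 10 grade pairs, with
Bonferroni and Tukey HSD selectable, since the multiplicity handling
behind published pairwise tables is rarely stated), Pearson
correlations, and paired t-tests. Degenerate inputs have explicit
conventions: all-identical ANOVA groups → (F 0, p 1); zero within-group
variance with unequal means → (∞, 0) with a warning; identical pairs →
(t 0, p 1); constant nonzero paired differences → (±∞, 0) with a
warning; zero-variance correlations raise. Type-I error of every test
is calibrated at 0.05 ± 0.01 under 2,000-replicate null simulations in
the acceptance suite. Visual acuity is handled as logMAR throughout.

## Pipeline and reproducibility

A single global seed fans out to per-stage seeds by a fixed affine rule
(`stage_seed = (48271·seed + 1009·stage_id) mod 2³¹−1`); every run
writes a manifest with the config hash, per-file SHA-256 checksums, and
stage seeds, and on the deterministic (baseline or ground-truth) path
the manifest reproduces every output byte-for-byte. Identical spec +
seed give bit-identical trees, images, and masks.

## Problem sizes

Chosen as the package's standard validation scale: quarter-scale
frames; 20 eyes/grade for cohort-structure checks; 25 pretraining
frames (100 tiles of 192 px at validation scale), 20 fine-tuning and ≥ 4
held-out UWF eyes over 3 seeds for the transfer comparison; 2,000
replicates for test calibration; 1,000 for paired-design power.
`scripts/acceptance.py` uses 12 eyes/grade.

## What the synthetic validation does not show

The generator produces arcade-shaped, non-anastomosing trees with
smooth backgrounds and additive Gaussian noise. It does not model
arteriole/venule distinction, central reflexes, laser artifacts,
peripheral projection distortion of the UWF optics, lesions
(neovascular membranes, atrophy borders), media opacity, or real
device noise. Passing tests therefore establish the correctness and
calibration of the measurement chain and the direction of the designed
severity effects — not clinical-grade segmentation accuracy, nor the
absolute magnitudes of density/Df on patient images, which depend on
acquisition and on the avascular-region convention.
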