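# uwfvm — ultra-widefield fundus vessel morphometry

`uwfvm` is a reproducible pipeline for quantifying retinal vascular
morphology on ultra-widefield (UWF, ~200°) scanning-laser fundus images,
the imaging setting used to study how the retinal vasculature changes
across grades of myopic maculopathy (META-PM C0–C4) in highly myopic
eyes. It is aimed at researchers who want the full measurement chain —
vessel segmentation, skeleton morphometry, cohort statistics — as tested,
scriptable code, exercised end-to-end on a synthetic UWF generator with
pixel-exact ground truth, so every stage is verifiable without any
clinical data.

The pipeline has four stages:

1. **simulate** — grow stochastic branching vascular arcades from the
   optic-disc rim around the macula, rasterize them into a green-laser-like
   frame (975 × 768 by default; 3,900 × 3,072 full scale) with exact
   binary vessel masks, landmarks, and grade-conditional covariates.
2. **segment** — produce binary vessel masks either with a deterministic
   multiscale Hessian-ridge (vesselness) baseline, or with a small
   trainable pixel classifier trained by the two-stage transfer-learning
   recipe: pretrain on a regular-fundus-like (45° field) corpus, then
   fine-tune on UWF frames, processing frames as non-overlapping
   576 × 576 tiles that are recombined by exact cropping. Segmentations
   are scored inside the circular field of view with accuracy,
   sensitivity, specificity, precision, and F1.
3. **measure** — from a mask and the macula/disc landmarks, compute the
   four morphometry metrics:
   * **vessel angle** (°): mean acute angle between the local vessel
     orientation (windowed coordinate PCA on the skeleton) and the
     macula–disc reference axis;
   * **Df**: box-counting fractal dimension of the skeleton,
     `Df = slope of log N(ε) vs log(1/ε)`;
   * **vessel density** (%): vessel pixels over the convex hull of the
     vasculature (the avascular surround is removed);
   * **branch count**: skeleton segments delimited by junction pixels
     (≥ 3 neighbors) and endpoints, spur-pruned.
4. **stats** — grade summaries (mean ± SD), one-way ANOVA, chi-square,
   pairwise grade comparisons (Welch/Bonferroni/Tukey), Pearson
   correlations with axial length, visual acuity and age, and paired
   t-tests for matched case/control (choroidal neovascularization)
   designs.

## Worked example

```bash
uwfvm simulate --n-per-grade 2 --out sim --seed 5
uwfvm measure --mask sim/C0_000_mask.png --landmarks sim/C0_000.json
```

prints

```json
{
 "eye_id": "C0_000_mask",
 "vessel_angle_deg": 49.23363290600738,
 "df": 1.2763793028591495,
 "vessel_density_pct": 4.0902802443040835,
 "branch_count": 266
}
```

i.e. this simulated healthy-end (C0) eye has vessels at a mean 49.2° to
the macula–disc axis, a skeleton fractal dimension of 1.28, vessels
covering 4.1% of the vascular region, and 266 resolvable vessel
segments — within 10% of the 290 segments the generator actually grew
for this eye, the guaranteed recovery band of the branch counter on
clean synthetic eyes. Running the same two commands again reproduces
these numbers bit-for-bit.

The same measurements over a full synthetic cohort (20 eyes per grade)
show the designed severity trend: mean density falls from ≈ 4.0%
(C0) to ≈ 2.6% (C4), branch count from ≈ 274 to ≈ 126, and Df from
≈ 1.28 to ≈ 1.22, each with ANOVA p < 0.001, and all twelve
correlations of the four metrics with axial length, visual acuity, and
age are negative.

The end-to-end pipeline (simulate → segment → measure → stats) is one
command, driven by a YAML config and emitting a manifest with config
hash and file checksums for exact re-runs:

```bash
uwfvm run --out results_dir --seed 4 --n-per-grade 5
```

Python API: `uwfvm.synth.generate_cohort`, `uwfvm.segment.train_segmenter`
/ `predict_mask` / `evaluate_segmentation`, `uwfvm.morpho.compute_morphometry`,
and `uwfvm.stats` mirror the CLI one-to-one; see the docstrings and
`docs/methods.md`.

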