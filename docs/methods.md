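# Methods

This note records the modeling assumptions, parameter choices and known
limitations behind the package, in the order the pipeline runs.

## Phantom model

Real cone-beam CT cohorts for sinus work are access-restricted, so the
pipeline is developed and validated on synthetic phantoms that reproduce the
*structure* of the problem rather than its radiological appearance:

- **Geometry.** A spherical bone shell (`shell_radius`, `shell_thickness`,
  in voxels) encloses soft tissue; a two-lobed air cavity — the frontal
  sinus stand-in — sits superior of center, its lobes split left/right by
  `lobe_separation`. Each lobe is an ellipsoid with independently sampled
  minor/major semi-axis ratios (`axis_ratio_range`, default 0.55–0.85),
  emulating the strong left/right asymmetry of real sinuses. The mask is
  the exact discretized union of the two ellipsoids.
- **Dimorphism.** The per-subject cavity volume is drawn from a normal
  distribution (CV 12 %, truncated at ±2 σ so extreme draws cannot breach
  the shell) whose mean is `cavity_base_volume` for the female class and
  `dimorphism_factor × cavity_base_volume` for the male class. The factor
  multiplies the *volume*; axis lengths then scale as its cube root. (A
  factor applied literally to both volume and axes would be internally
  inconsistent.) Published morphometry reports male/female sinus volume
  ratios of roughly 1.2–1.6; the default factor of 1.5 sits in that range,
  and the scaled study profile uses 1.6. Setting the factor to 1.0 gives a
  null world in which no classifier should beat chance.
- **Intensity.** CBCT intensities are not calibrated Hounsfield units, so
  values are a normalized [0, 1] surrogate: air 0.05, soft tissue 0.55,
  bone 0.95, plus additive Gaussian noise (`noise_sd`, default 0.02) and
  optional Gaussian blur (`blur_sigma`) as a mucosal-thickening surrogate.
- **Confounders.** `confounder_count` small air blobs are placed
  inferior-adjacent to the cavity, imitating ethmoid air cells — the main
  source of segmentation false positives in practice. They appear in the
  image only, never in the mask.
- **Seeding.** All randomness flows from integer seeds
  (`SeedSequence([spec.seed, sex, instance_seed])`); identical inputs give
  bit-identical volumes, masks and manifests. Cohorts are split
  train/val/test with equal sex composition per split.

What the phantoms deliberately do **not** model: skull anatomy beyond a
shell, CT physics (beam hardening, scatter), age effects, and truly
irregular (scalloped) sinus borders. Passing tests on phantoms therefore
demonstrates that the pipeline machinery — losses, attention, metrics,
orchestration — behaves as specified and can recover a known generative
signal; it does not certify clinical performance.

## Segmentation stage (FSNet)

A U-shaped encoder–decoder over single axial slices. Each block is a 3×3
convolution + batch normalization + ReLU; downsampling is 2×2 max pooling,
upsampling a 2×2 stride-2 transposed convolution with skip concatenation;
the head is a 1×1 convolution + sigmoid. Named backbones (`tiny`,
`vgg16-like`, …) select depth/width profiles of this same plain design —
they are channel-count analogues, not faithful reimplementations, and no
pretrained weights are bundled. The `tiny` profile (3 levels, 8 base
channels, ≈60 k parameters) is the test vehicle.

**Dice loss.** The training loss is
`1 − 2(Σyŷ + ε)/((Σy + Σŷ) + ε)` with ε = 10⁻³. The stabilizer makes the
loss slightly negative at perfect overlap (−5·10⁻⁶ for a 100-pixel mask)
and exactly −1 when both arguments are empty; both values are asserted in
the tests. When used as a *metric* the empty/empty case is reported as 0
with a warning, because rewarding all-empty predictions is pathological.

**Batch aggregation.** For sinus-free slices the per-image loss is
maximally flat: ∂L/∂ŷ ∝ ε/(Σŷ+ε)², which is numerically zero once any
mass is predicted, so a model that floods empty slices with false positives
receives no corrective gradient from them — and most axial slices contain
no sinus. Training therefore pools the Dice sums over the whole minibatch
(the common framework idiom for tensor-level custom losses), which restores
a genuine gradient on every slice. The per-image form remains available
(`dice_aggregation="per_slice"`), and the public `dice_loss` op is exactly
the printed per-image formula.

**Output-prior initialization.** The output bias starts at the background
prior logit (log(p/(1−p)), p = 0.02), the standard rare-class
initialization; without it, early training marks large dark regions as
sinus before supervision catches up. On the 32³ profile these two choices
move held-out volume F1 from ≈0.03 to ≈0.95.

**Augmentation.** Rotation of ±10° applied identically to image and mask
(linear/nearest interpolation respectively); Gaussian blur with σ sampled
uniformly in [0, 0.1·σ_max] (σ_max = 2 voxels) and multiplicative
brightness ±10 %, both image-only. All augmentation parameters are sampled
uniformly from their ranges.

**Schedule.** Adam at 10⁻³, halved when the validation loss fails to
improve for 20 consecutive epochs (never below 10⁻⁶); reference schedule
200 epochs, batch 16. The scaled profile uses 35 epochs and patience 8,
which suffices for the phantoms' much simpler appearance.

**Binarization.** Probability ≥ 0.5 → sinus. The ≥ convention (ties go to
foreground) matches the sigmoid midpoint and the classification threshold.

## ROI assembly

The stage-2 input is a fixed-size crop — (122, 128, 128) at clinical
resolution, 24³ in the scaled profile — centered at the integer-rounded
centroid of the predicted 3D mask. The window is **never shifted** to fit
the volume: out-of-volume voxels are constant-padded (image: the volume
minimum; mask: 0) and the padded fraction is recorded, preserving
"centered at the centroid" exactly. An empty prediction falls back to the
volume center and sets a flag rather than failing, so a degenerate
segmentation still produces a classifiable sample. The mask channel is
binarized by default (probability passthrough is a switch), and an optional
largest-connected-component filter (default off) is available for cohorts
with heavy ethmoid false positives. Channel subsets {image}, {mask},
{image, mask} reproduce the ablation configurations.

## Classification stage (SDNet + AGAM)

Per level: 3×3×3 conv + BN + ReLU, optional attention, 2× max pooling;
after the last level, global average pooling feeds a single sigmoid unit
giving P(male); female = 0 is the negative class and a probability ≥ 0.5 is
called male. Reference channels are (16, 32, 64, 128); the scaled profile
uses (4, 8, 16).

The attention module receives the ROI mask S and the level features F. S is
first resampled (trilinear, endpoint-aligned) onto F's spatial grid; then
A = Conv₁(S) and B = Conv₁(F) (1×1×1 convolutions to C channels),
F_dis = ψ(ReLU(A+B)) with ψ a 1×1×1 convolution to one channel,
F_att = σ(F_dis), and the output is F_att·F broadcast over channels.
Because the mask is brought to the feature grid *before* the 1×1×1
convolutions, the final grid-resampling step is the identity — the reading
that keeps every map on a consistent lattice. Resampling on matching grids
returns the input untouched (exact identity). The attention convolutions
carry biases by default; a switch removes them so the zero-weight contract
(gate ≡ σ(0) = 0.5) is exactly testable. Attention sits after the
convolution block and before pooling at each level. Since σ ∈ (0, 1), the
module can only attenuate: |F_n| ≤ |F| elementwise, verified over random
draws.

**Loss.** Standard mean binary cross-entropy with probabilities clipped at
10⁻⁷ for numerical safety. (A cross-entropy variant that keeps only the
positive-class term −Σ p log p̂ is sometimes written down for this task; it
is not a proper loss — it ignores every female-labeled sample — so the full
two-term form is used.)

**Schedule.** Adam (β₁ = 0.9, β₂ = 0.999) at 10⁻⁴, batch 1, halving on a
25-epoch validation plateau down to 10⁻⁷; reference 100 epochs. The scaled
profile uses 24 epochs, patience 8, learning rate 10⁻³.

## Metrics

Segmentation: per-volume voxel counts give precision, recall, JI and F1,
aggregated as mean ± SD across volumes (per-slice aggregation is a switch).
Empty ground truth with empty prediction scores 1 with a degenerate flag.
Classification: ACC/SEN/SPE from the confusion counts at threshold 0.5
(male positive, ≥ convention), Brier score, trapezoidal ROC AUC (midrank
tie handling; equal to the normalized pairwise-comparison statistic, which
the tests verify against an O(n²) oracle to 10⁻¹²), and PAM. PAM places
(ACC, SEN, SPE, AUC, JI, FM) — JI and FM computed from the classification
confusion counts — as radii on a regular hexagon in that fixed order and
normalizes the polygon area by 2.59807 (the unit hexagon, 3√3/2). The area
depends on vertex order, so the order is pinned and documented; PAM is
monotone in each argument and PAM(r,…,r) = r².

## Scaled study profile

The desk-scale profile (`PipelineConfig.tiny()`) runs the full design on
one CPU in about 90 s: 32³ phantoms, segmentation cohort 8/2/2,
classification cohort 60/12/40 with balanced sexes, tiny backbones, ROI
24³, dimorphism 1.6. Under these conditions the pipeline reaches mean
held-out segmentation F1 ≈ 0.95 and test AUC ≈ 0.99; with dimorphism 1.0
test accuracy sits at chance; and the image+mask+attention preset matches
or beats the image-only preset. The ablation harness trains the
segmentation stage once per seed and retrains only the classifier per
preset, since stage 1 is identical across presets.

## Numerical and engineering choices

- The layer library computes in float32 with float64 loss accumulation;
  gradients are verified against central finite differences in the tests.
- Max pooling uses floor behavior on odd spatial sizes (trailing voxels are
  dropped, as in the usual framework default); ties in a pooling window
  split the gradient equally.
- Batch normalization uses momentum 0.9 running statistics; with batch
  size 1 (the classifier's reference setting) training-mode statistics are
  per-sample, which acts like instance normalization, and evaluation uses
  the running averages.
- The plateau scheduler halves once the monitored loss has failed to
  strictly improve for `patience` consecutive epochs, then resets its
  counter; the floor clamps the rate exactly.
- One global seed derives all stage seeds through `SeedSequence`; reruns of
  a pipeline config are bit-reproducible on the same platform.
- Checkpoints are `.npz` weight archives with a JSON sidecar holding the
  config and training history.

## Limitations

- Phantom realism is intentionally minimal (see above); absolute metric
  values on phantoms say nothing about clinical accuracy.
- The numpy backend is single-threaded and CPU-bound; the full-resolution
  clinical configuration (640×670×670 scans, 122×128×128 ROIs, five-level
  pretrained encoders) is expressible but not practical to train here.
- Backbone "likeness" is a width/depth profile only; transfer learning
  from pretrained encoders is not supported.
- A single centroid is used even when the predicted sinus is disconnected;
  multi-ROI handling is out of scope.
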