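# Methods

## Problem and approach

Automatic delineation of head-and-neck gross tumor volumes (GTV) on
co-registered CT/PET fails most often at the tumor's axial edges: the
superior- and inferior-most slices have small cross-sections, weak PET
uptake, and low soft-tissue contrast, so a slice-local model has little to
work with. This package implements a family of U-Nets built around the
idea of contouring the way a clinician does — starting at the most salient
center slice and working outward — so that information from the salient
middle of the tumor is *pushed* to the ambiguous edges:

* **2D U-Net** — slice-independent baseline; no inter-slice pathway.
* **3D U-Net** — volumetric baseline; 3×3×3 convolutions see neighboring
  slices, but weight all positions uniformly.
* **RC U-Net** — the 2D U-Net decoder augmented with a convolutional
  recurrent (CRNN) cell at every decoder level. Slices are fed as two
  *half-sequences* starting at the tumor-center slice and running
  superiorly and inferiorly; each level's hidden state carries context
  from earlier (more central) slices.
* **SARC U-Net** — the RC U-Net plus a spatial-transformer step: before
  each recurrent update, a localization network regresses a 6-parameter
  affine from the current slice's pre-upsampling features together with a
  pooled view of the hidden state, and the hidden state is warped by that
  affine. This re-aligns anatomy that drifts in-plane from slice to
  slice (≈1.5 px per slice on average in the motivating cohort) before
  the recurrence mixes it with the current slice.

## Architecture details

All four models share one filter plan: per-level widths (32, 64, 128,
256) with a 512-wide bottleneck, **one** 3×3 convolution + ReLU per level,
2×2 max-pool downsampling, learned 2×2 transposed-convolution upsampling,
one 3×3 convolution after each skip concatenation, and a 1×1 sigmoid
head. The 3D U-Net uses 3×3×3 convolutions but pools and upsamples
in-plane only (kernel (1,2,2)), so the axial extent is preserved and every
input slice produces an output slice. This plan gives the four
architectures 3,832,321 / 10,100,353 / 5,399,521 / 7,841,465 trainable
parameters (2D / 3D / RC / SARC); the SARC U-Net is ~22% smaller than
the 3D U-Net.

The CRNN update is `h' = ReLU(Conv3x3(concat(h, x)))` with the hidden
state initialized to zeros — concatenation followed by a single
convolution is the minimal way to make both the previous hidden state and
the current slice "the input".

The localization network at a decoder level of width C consumes the
pre-upsampling feature map (2C channels, half resolution) concatenated
with the 2×2-average-pooled hidden state (C channels): a 3×3 convolution
to C maps, an instance-norm-style per-channel affine normalization, then
a per-pixel two-layer perceptron C→C→6, reduced across pixels by an
element-wise max. The final layer starts at zero weights with an
identity bias, so an untrained SARC U-Net is numerically identical to the
RC U-Net — the warp is a learned refinement, never an initial distortion.
The normalization makes the per-pixel regression insensitive to feature
scale drift across recurrence steps; its two per-channel parameters are
part of the parameter budget above.

The affine acts on coordinates normalized to [−1, 1] with corners
aligned; sampling is bilinear with zeros outside the feature map. These
conventions are stated because they differ across frameworks and the
identity-at-initialization property depends on them.

## Numerical backbone

The networks run on a small reverse-mode autodiff engine over numpy
arrays written for this package (`sarc_unet.nn`): stride-1 convolutions
(2D/3D) evaluated by shift-and-matmul, non-overlapping transposed
convolutions and pooling, the differentiable affine warp, and Adam.
Every operation's gradient is validated against central finite
differences in the test suite; the warp's gradient with respect to both
the features and the affine parameters is exercised explicitly (bilinear
interpolation has subgradient kinks at integer sample positions, so the
checks keep test points off the pixel lattice). Parameters are float32;
initialization is He-normal from an explicit `numpy.random.Generator`, so
construction, training, and evaluation are bit-reproducible given a seed.

## Data conventions and preprocessing

Volumes are (Z, H, W), z increasing superiorly, channels ordered
(CT, PET). CT is clipped to [−200, 200] HU and min–max mapped to [0, 1];
PET is min–max normalized per patient (a constant PET volume is an
error). In-plane resampling uses linear interpolation with
origin-aligned grids; the output extent is `round(extent·src/dst)` per
axis. The region-of-interest crop is a fixed 64³ window centered on the
centroid of the union bounding box of all cohort GTVs, shifted inside
bounds when necessary.

Half-sequences are padded (zeros) or truncated to 32 steps; a validity
mask excludes padded steps from loss and metrics. The center slice opens
*both* halves; at prediction time the two center predictions are averaged
(symmetric and order-free — the reconciliation rule at the shared slice
is this package's choice). When no mask is available at inference the
center defaults to the middle slice of the crop, overridable explicitly.
Volumes with more than 2·32−1 slices are not fully covered by the two
halves; uncovered slices predict background.

## Training objective and protocol

All models minimize one minus the mean *per-slice* soft Dice
(ε = 10⁻⁶), so every axial slice carries equal weight. A volumetric Dice
loss would weight slices by area and thereby downweight exactly the edge
slices this architecture targets; the per-slice loss is the point, and a
constructed test demonstrates the masking effect (volume Dice exceeds
slice-mean Dice when only small edge slices fail). Defaults follow the
training protocol the architectures were designed under: Adam, learning
rate 3×10⁻⁴, batch 10, 100 epochs, 7-fold cross-validation, no data
augmentation, no learning-rate schedule. A "batch" is 10 of the
architecture's natural unit (slices / volumes / half-sequences).
Evaluation reports slice-mean Dice, volume Dice, sensitivity and
specificity (patient-level and fold-level means), per-offset curves, and
paired t-tests on per-patient scores.

Metric conventions: predictions binarized at 0.5; a slice empty in both
prediction and truth scores Dice 1.0; sensitivity/specificity with empty
denominators and Hausdorff distances involving an empty mask are
undefined and excluded from averages; Hausdorff is computed on foreground
pixel sets (deterministic and directly checkable against a brute-force
all-pairs oracle). Offset-stratified averages are restricted to slices
within each patient's true GTV span by default; the full tables retain
all slices so both variants can be reported.

## Synthetic phantoms

Real cohort data is large and access-controlled, so the package ships a
seeded phantom generator producing the statistical structure the
architectures are designed to exploit, on any grid size:

* per-slice tumor cross-sections are filled axis-aligned ellipses whose
  radii shrink by a factor (1 − taper) per slice away from a center
  slice — a unimodal, center-peaked area profile;
* the per-slice centroid performs a Gaussian random walk outward from the
  center in both axial directions (default mean step (1.53, 1.5) px,
  matching the reported average in-plane GTV drift of the motivating
  head-and-neck cohort, without claiming clinical realism; sd 0.5 px);
* PET is a Gaussian blob co-located with the ellipse whose amplitude
  decays by (1 − pet_edge_decay) per slice from the center, so edge
  slices carry little slice-local evidence;
* CT is smoothed background noise plus a constant in-tumor offset.

Cohort sampling draws per-patient parameters uniformly from stated
ranges; drift can be sampled as a magnitude with a random per-patient
direction. Generation is byte-deterministic in (config, seed). Tumors
that walk off-grid are truncated at the boundary with a logged warning;
slices whose tapered radii fall below half a pixel are empty.

What the phantoms do *not* model: anatomy (bone/air structures, organs at
risk), scanner physics (partial-volume effects, dental-amalgam scatter),
inter-observer contour variability, and non-elliptical or non-convex
tumor shapes. Passing tests on phantoms therefore demonstrates that the
mechanisms work where the assumed statistical structure holds, not
clinical-grade performance.

## Scaled-down capability experiments

Reproducing the motivating study's absolute accuracy would require the
clinical cohort and GPU-scale training; instead the test suite checks the
*mechanism* at desk scale:

* **Edge-accuracy comparison.** Forty phantoms on a 32³ grid with strong
  drift (magnitude 1.4–1.7 px/slice, random per-patient direction),
  strong PET edge decay (0.25/slice), and CT contrast at the noise floor
  (0.05 vs. noise 0.04), so edge slices are locally ambiguous and only a
  model that carries context from the center can place them. A small
  SARC U-Net (filters 4/8/16) and a 2D U-Net with a *larger* parameter
  budget (filters 6/12/24) train on 30 phantoms (16-step halves, 30
  epochs, Adam 3×10⁻³, sequence batch 5) and are compared on 10 held-out
  phantoms by mean slice Dice at |offset| ≥ 8. The learning rate and
  batch are raised relative to the full protocol because the scaled-down
  models see far fewer updates per epoch; both arms are trained with the
  same budget. The expectation is directional — SARC above 2D in at
  least 4 of 5 seeds — not a reproduction of absolute values.
* **Capacity check.** Each architecture, at reduced width (6/12), must
  drive the slice-wise Dice loss below 0.05 within 200 epochs when
  overfitting a single 16³ phantom.
* **Determinism.** Identical seed and config reproduce identical fold
  splits, loss histories, and metric tables.

Problem sizes in these experiments (grid 32³ or 16³, reduced filter
widths, tens of epochs) are the package's chosen desk-scale test
conditions; the full-size architectures and protocol remain available
through the same interfaces.

## Known limitations

* Training is CPU-bound numpy; the full 64³ protocol at canonical widths
  is functional but slow — the package is a faithful, testable
  implementation, not a performance-tuned trainer.
* The localization head's hidden width and normalization are fixed by the
  parameter accounting above; alternative localization designs (deeper
  perceptrons, per-pixel attention) are not explored.
* Half-sequence length is fixed (default 32) rather than adaptive to
  tumor extent.
* The phantom's drift is a random walk with constant mean step; real
  anatomical drift is smoother and structured.
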