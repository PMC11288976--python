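# Methods

## Problem and model

Stargardt disease produces progressive atrophy of the photoreceptors and
retinal pigment epithelium (RPE).  Given a baseline SD-OCT volume with
segmented retinal boundary surfaces (ELM, EZ, inner RPE, outer RPE,
choroid–sclera junction), the package predicts the *future* extent of
atrophy — the binary mask a grader would draw on fundus autofluorescence
(FAF) 6 or 12 months later, registered to the baseline en-face frame.

The predictor works on 2D en-face feature maps rather than the raw volume.
For a region bounded by two surfaces, each A-scan column contributes one
pixel per statistic: mean, median, maximum, minimum, standard deviation,
skewness, kurtosis, gray-level entropy, and slab thickness.  Regions are
ELM–EZ, EZ–IRPE, IRPE–ORPE, ORPE–CS, ELM–IRPE, and EZ±5 depth pixels;
thickness is excluded for ORPE–CS (large natural variation) and EZ±5
(constant by construction), giving 9-channel stacks for four regions and
8-channel stacks for the other two.

Each feature map feeds exactly one **component U-Net** (encoder blocks:
5×5 conv → batch norm → ReLU → 2×2 max pool with retained indices; decoder
blocks: max unpool → concatenation with the matching encoder features →
conv → batch norm → ReLU; 1×1 conv head to two class channels; no
per-component softmax).  The ensemble output is the per-pixel, per-channel
maximum of the component activations,

    g(E(Y)) = max(f1(x1), …, fn(xn)),

followed by a softmax over the two channels (atrophy / background).  The
max makes the ensemble interpretable: each component's activations can be
graded separately (through a sigmoid) to measure that feature's
contribution.

Training minimizes

    L = L_logloss + L_Dice + λ‖W‖²_F

with a weighted two-class logistic loss (pixel weight 6 inside the atrophy
region and background, 15 on the boundary band where a 3×3 neighborhood
contains both classes), a soft Dice loss on the atrophy probability, and
L2 decay λ = 1e-4 on convolution kernels.  Optimization is stochastic
mini-batch gradient descent (batch 8, momentum 0.95) at learning rate 1e-2
for 40 epochs then 1e-3 for 20.  Gradients flow through the max only to
the per-pixel arg-max component; exact ties split the gradient equally.

## Conventions chosen where the method leaves them open

- **Statistics.**  Population (biased) central moments; kurtosis is
  non-excess m4/m2²; skewness and kurtosis are defined as 0 for
  zero-variance columns so maps stay finite.  Gray-level entropy is
  Shannon entropy in bits over the 256 native 8-bit gray levels (bin count
  configurable).  Column sampling is inclusive over integer depths between
  the rounded boundary positions; a column whose rounded outer bound lies
  above the rounded inner bound collapses to the rounded midpoint voxel.
  The EZ±5 band is ±5 native depth pixels about the rounded EZ position,
  clamped to the volume, applied before any resizing.
- **Map preparation.**  Right-eye (OD) maps are mirrored along the A-scan
  axis; native 49×N maps are resized to square frames without preserving
  aspect (bilinear for continuous maps, nearest neighbor for masks); each
  channel is min–max normalized to [0, 1] after resizing (constant maps
  map to 0).  Normalization is our own addition: thickness (depth pixels)
  and intensities (0–255) otherwise enter the loss on incommensurate
  scales.
- **Loss normalization.**  The logistic loss is written as a sum over
  pixels; we optimize its per-pixel mean (the summed form is also
  reported) because the published learning-rate schedule is only stable
  under a normalized loss in this implementation.  The decay term is
  applied as the exact gradient 2λW of λ‖W‖²_F, on convolution kernels
  only.  Stabilization constants: log clamp 1e-7, Dice smoothing 1e-7.
- **Architecture.**  Encoder depth 4 with widths (16, 32, 64, 128) at
  128×128 input is the full-scale default; both are configurable and the
  desk-scale experiments use depth 3, widths (8, 16, 32) at 64×64.
  Weights are He-uniform (fan-in) initialized from an explicit seeded
  generator; batch norm uses batch statistics in training and running
  averages (momentum 0.1) at inference.
- **Registration.**  The transform family is affine (2×3, least squares on
  ≥3 non-collinear landmark pairs; exact for 3), with a similarity fit as
  an option; the residual error modes observed in practice (shear,
  rotation, translation) motivate a linear family.  Landmark detection is
  out of scope: the module consumes corresponding vessel points.  Warping
  is inverse-mapping resampling, bilinear for images and nearest for
  masks, zero-filled outside the frame.
- **Evaluation.**  Dice on both-empty masks is defined as 1.0 (agreement
  on absence), one-empty as 0.0.  The ensemble row is graded on the
  binarized (argmax) map by default, soft grading by flag; component rows
  use the soft Dice of the sigmoid map and the pixel accuracy of its
  0.5-threshold.  The Wilcoxon signed-rank test is two-sided, drops zero
  differences, uses average ranks on ties, and enumerates the exact null
  (dynamic programming over doubled ranks) for n ≤ 25, switching to the
  tie-corrected normal approximation above.

## The synthetic cohort

Clinical OCT volumes with graded follow-up masks are not distributable, so
the package ships a simulator that produces the structures the method
relies on: an 8-bit volume (default 128×256×49, any size by parameter)
with ordered, smoothly undulating boundary surfaces; retinal vessels as
smooth en-face curves casting multiplicative axial shadows (their points
double as registration landmarks); and a central, contiguous, roughly
elliptical lesion with smooth outline jitter that grows radially between
baseline, 6-month, and 12-month visits (masks are nested by construction).
Optional variants add an interior hole or satellite lesions — the shapes
that atrophy networks notoriously miss.

Inside the lesion the simulator applies the characteristic outer-retinal
signature: EZ–ORPE attenuation (fraction 0.5), sub-RPE hypertransmission
(gain 1.7), EZ–IRPE thinning (fraction 0.5), and raised speckle variance
(gain 2.2) over a base noise sd of 12.  The rings the lesion will grow
into receive the same effects at reduced strength (0.55 for the 6-month
ring, 0.3 for the 12-month ring): baseline scans therefore carry a weak
precursor signal about future extent, which is the premise that makes
progression prediction learnable at all.  Vessel shadows deliberately
confound mean intensity (both lesions and vessels darken the slab mean),
while thickness and distribution-shape features are unaffected — so
ensembles with several features hold a genuine advantage over
mean-intensity-only models, the direction the method is designed to
demonstrate.  Effect sizes are free parameters of the simulator, chosen
once as plausible for advanced atrophy; they are not calibrated to any
clinical cohort.

What the simulator does **not** emulate: physical speckle statistics,
real vessel topology (branching trees, crossovers), segmentation errors in
the input surfaces, FAF image formation, or non-atrophic pathology.
Passing the synthetic end-to-end test shows the pipeline is implemented
coherently and can learn a lesion-growth signal; it says nothing about
accuracy on clinical data.

## Problem sizes used in tests and the acceptance script

The shipped experiments run the pipeline at desk scale: synthetic grids of
96×128×48, network inputs 64×64, component U-Nets of depth 3 with widths
(8, 16, 32), cohorts of 80 eyes split 3:1 (60 train / 20 test), and a
16-epoch schedule (11 at 1e-2, 5 at 1e-3) — sizes chosen so a single CPU
reproduces every result in minutes.  Full-scale settings (128×128 inputs,
depth 4, 60 epochs) remain the defaults of `ComponentUNetConfig` and
`TrainConfig`.

## Known limitations

- The numpy engine is CPU-only and single-threaded apart from BLAS; it is
  meant for correctness and desk-scale experiments, not clinical-scale
  training.
- The exact published layer dimensions are not recoverable from the
  source figure; our defaults approximate the stated parameter budget but
  are not a bit-level reconstruction.
- Median/min/max/entropy are computed over rounded 8-bit levels on the
  fast (histogram) path; float-valued volumes fall back to the per-column
  path, which is slower.
- The synthetic lesion model is radial-growth only; it cannot produce
  merging foci or regression, and its penumbra model is an idealization.
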