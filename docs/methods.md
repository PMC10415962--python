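# Methods

## Problem and model

Routine head-and-neck CT stops at the neck, so the L3-level muscle area that
defines imaging-assessed sarcopenia cannot be measured directly. `c3morph`
measures muscle at the mid-C3 level instead and converts it to an L3
equivalent. The pipeline has three parts with distinct error sources, which
the package deliberately keeps separable:

1. **Slice selection.** A densely-connected convolutional regressor maps each
   preprocessed axial slice to its signed physical distance from the mid-C3
   level, in millimetres. Regressing millimetres (not slice counts) makes the
   target invariant to slice thickness, which varies across scanners. At
   inference the per-slice offsets are median-smoothed with a window of 3 and
   the slice with the smallest absolute smoothed offset is chosen; exact ties
   resolve to the inferior slice. Localization error is summarized as
   Δh = (predicted − truth) × dz in mm (mean and SD, n−1 denominator),
   with the sign following the axial axis (z increases toward the head).
2. **Segmentation.** A two-level U-Net (additive skip connections, 1×1 output
   head) produces a per-pixel muscle probability on the selected slice;
   pixels with probability ≥ 0.5 are muscle. No connected-component or
   HU-range post-filter is applied by default.
3. **Morphometry.** CSA (cm²) is the foreground pixel count × pixel area.
   The C3→L3 conversion is the published regression of Swartz et al. (2016):
   CSA_L3 = 27.304 + 1.363·CSA_C3 − 0.671·age + 0.640·weight + 26.442·sex,
   sex coded female = 1 / male = 2. SMI = CSA_L3/height². Sarcopenia iff SMI
   is strictly below 52.4 (male) / 38.5 (female) cm²/m²; BMI strata use
   strict < 18.5 for underweight (boundary value is not underweight) and a
   < 25 / ≥ 25 sensitivity split. The coefficient block, including the sex
   coding, is an explicit versioned config entry; the conversion refuses to
   run when any piece is missing, because a silent default would corrupt
   every downstream number. The strict-< threshold convention is
   config-exposed (`strict_threshold`) since cut-point sources differ on
   boundary handling.

## Preprocessing

Volumes are clipped to a HU window (default −1024..1024, retaining bone for
slice selection and soft-tissue contrast for segmentation in one channel),
mapped affinely to [0, 1], resampled in-plane (linear for images, nearest for
masks so they stay binary), and center-cropped/zero-padded about the body
center of mass (voxels > −500 HU). Defaults are 1.0×1.0 mm and 256×256; the
reduced experiments use 2.0×2.0 mm and 96×96. The crop offset is recorded on
the preprocessed volume so ground-truth masks can be conformed through the
identical geometry. The chain is idempotent on already-conformed volumes up
to interpolation tolerance, and mask area is conserved under resampling to
within 2% for masks ≥ 1 cm².

## Networks and training

No GPU framework is assumed: both models run on a small numpy layer library
(stride-1 same-padded convolutions via im2col, instance normalization, max
pooling, nearest upsampling, dense heads) with exact hand-derived backward
passes — each verified against finite differences in the test suite — and an
Adam optimizer. Everything is float32 and seeded; two runs with the same
configuration are bit-identical.

Normalization is per-sample *instance* normalization rather than batch
normalization. The muscle/soft-tissue contrast is only ~10 HU (0.5% of the
intensity window), so the segmentation decision boundary is finer than the
batch-to-batch fluctuation of feature statistics; batch-norm running averages
can then land outside the distribution the model was trained against and
shift the boundary across an entire tissue class at inference. Instance
normalization applies the identical transform in training and inference,
making single-image prediction deterministic and batch-size independent —
the same reason instance norm is the conventional choice in medical image
segmentation frameworks.

* Slice regressor: conv stem then three dense blocks (growth rate 8) with
  1×1 transitions and pooling, global average pooling, two-layer head.
  Offsets are scaled by 1/50 for regression; slices farther than 45 mm from
  the landmark are excluded from training. Loss: mean squared error (a
  Gaussian Δh summary is the natural fit for a smooth offset target).
* Segmenter: 16 base filters by default, doubling per level. Loss: equally
  weighted soft-Dice + binary cross-entropy on the logits, the standard
  choice for class-imbalanced single-slice segmentation.

The default `TrainingConfig` mirrors the full-scale development protocol
(100 epochs, initial learning rate 0.005, 5-fold cross-validation seeded and
stratified by mid-C3 tercile, small random translations/rotations as
augmentation). The reduced phantom experiments use 8–11 epochs, Adam at
3e-3 with cosine decay to a tenth, batch size 8, and no augmentation — the
phantom sampler already randomizes geometry, spacing, area and noise, which
is the variation augmentation would otherwise have to synthesize.

## Phantom generator

The phantom emulates the features the pipeline actually consumes, not CT
physics. Each axial slice holds an elliptical body (soft tissue 40 HU) with
a 6 mm subcutaneous fat rim (−80 HU), an anterior airway (air, −1000 HU), a
posterior vertebral column (700 HU bodies, 150 HU discs, 19 mm period), and
three bilateral muscle compartments (50 HU) — paraspinal, scalene and
sternocleidomastoid analogues — whose combined area at the target slice
equals `muscle_area_target` exactly by construction (rasterization is checked
to 5%). Additive Gaussian noise (default SD 15 HU) is applied and values are
clipped to [−1024, 3000].

Two cues make the mid-C3 level identifiable to a per-slice regressor, playing
the role anatomy plays on real scans: the body cross-section tapers linearly
toward the head (0.2 mm radius per mm), giving every slice a monotone global
size cue, and the vertebral segment containing the target level is the widest
in the column (×1.35), with slightly asymmetric superior/inferior widths so
the two directions are distinguishable. Muscle area decays smoothly away from
the target level. The default sampling ranges for phantom sets are
25–55 cm² total muscle area, 2–3 mm slice thickness, 1.0–1.4 mm in-plane
pixels, and 10–18 HU noise, with the target slice at least 5 slices from the
stack ends.

What the phantom does *not* emulate: realistic vertebral shape, contrast
agents, metal/dental artifacts, pathology inside muscle, patient positioning
variation, or inter-muscle HU heterogeneity. Passing the phantom experiments
therefore demonstrates that the architecture, training loop, geometry
handling and morphometric chain are correct and well-wired — not that the
shipped configuration would reach clinical-grade accuracy on patient scans,
which requires training on expert-contoured data.

Synthetic cohorts draw exponential survival times (constant baseline hazard,
default 0.004/month) with a configurable sarcopenia log-hazard and
independent Bernoulli covariates matching the standard head-and-neck
prognostic factors; administrative censoring at a configurable horizon
(default 72 months). The exponential choice gives closed-form ground truth
for parameter-recovery tests. PEG-tube duration uses removal as the event
(sarcopenia log-HR −0.4, so hazard ratios < 1 mean longer tube dependency);
toxicity is a logistic outcome (default log-OR log 2.25, base rate 25%). A
`bmi_class` column is sarcopenia with 16.5% label noise, yielding a ≈0.67
phi correlation — a binary proxy with the coupling strength BMI shows to SMI
— used by the AIC/BIC model-comparison analyses.

## Evaluation statistics

* Dice = 2TP/(2TP+FP+FN), precision, recall; the empty-vs-empty convention
  is fixed to 1.0 (and empty-vs-nonempty to 0.0) so batch evaluation is
  total. The evaluator reports both mean and median Dice.
* ICC(2,1): two-way random effects, absolute agreement, single measure, from
  the ANOVA mean squares — the stricter, conventional variant for method
  comparison (it penalizes constant offsets, unlike consistency ICCs).
* Gwet's AC1 = (pa − pe)/(1 − pe) with pe = (1/(K−1))·Σ π̂ₖ(1−π̂ₖ); reported
  on both the native 0–3 acceptability scale and the binarized
  acceptable (≥2) / unacceptable scale, since both conventions are defensible.
* Survival: Kaplan–Meier product-limit; Cox proportional hazards with Efron
  tie handling and Wald 95% CIs (via lifelines); logistic regression with
  Wald CIs (via statsmodels). Cox fits with fewer than two events are
  rejected rather than returning degenerate Wald statistics.
* AIC = −2ℓ + 2k; BIC = −2ℓ + k·log m with m = events for Cox partial
  likelihood and m = rows for logistic fits; m is pinned so deltas are
  reproducible (an all-n Cox variant can be obtained by recomputing from the
  exposed log-likelihood). Multivariable term lists are explicit
  configuration, never automatic selection.

## Reference experiments and problem sizes

The package's reference experiments, shared by the test suite and
`scripts/acceptance.py`, use 500 training / 100 held-out phantoms (seed 42):

* Segmentation: reduced U-Net, 96×96 at 2 mm, 11 epochs. Reported: mean and
  median held-out Dice and the Pearson correlation of predicted vs truth
  CSAs. Representative run (seed 42): mean Dice 0.91, r 0.97.
* Slice selection: reduced regressor, 4 sampled slices per training volume,
  8 epochs. Reported: fraction of held-out phantoms localized within one
  slice and the Δh mean/SD.

Phantoms stream through generation → preprocessing → feature extraction one
at a time, so memory stays flat in the number of phantoms.

## Numerical and design notes

* Probability threshold 0.5 is inclusive (≥); a model emitting exactly 0.5
  everywhere segments everything, not nothing.
* argmin tie-breaks (slice selection, crop origin) always resolve toward the
  smaller index / image center, making runs reproducible bit-for-bit.
* Empty segmentations and non-positive or out-of-range SMI values do not
  abort the pipeline; reports complete with `qa_flags` so batch runs can
  triage failures, mirroring how unusable scans are flagged rather than
  silently dropped. Rows with sex recorded as anything but male/female are
  excluded from classification with a logged count.
* All geometric metadata and per-stage choices flow through one YAML config
  whose SHA-256 hash is embedded in every report.

## Known limitations

* The numpy trainer is CPU-bound and sized for phantom-scale experiments;
  full-resolution clinical training would need a GPU framework behind the
  same module interfaces.
* The C3→L3 regression is a population-level anthropometric conversion;
  individual L3 predictions carry its residual error even with perfect C3
  segmentation.
* Phantom realism limits are listed above; no claim about robustness to
  artifacts or anatomy outside the phantom family is made or tested.
* DICOM support covers single-series axial stacks (classic, not
  enhanced/multi-frame).
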