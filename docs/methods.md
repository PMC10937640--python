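# Methods

`pericfat` re-creates, end to end and without any clinical data, an
automated pipeline for quantifying epicardial adipose tissue (EAT) on
non-ECG-gated low-dose chest CT, together with the survival-analysis
framework used to relate EAT volume and density to mortality in a
lung-screening population. This note records the models, the numerical
choices, and what the synthetic substrate does and does not demonstrate.

## The imaging pipeline

EAT is fat inside the pericardial sac. The pipeline finds it in three
stages:

1. **Heart localization** (`locnet`). The volume is resampled to a coarse
   isotropic grid, center-cropped/padded to a fixed cube, intensity-
   clipped to [-1000, 1000] HU and scaled to [0, 1], and a 3D U-Net
   predicts a coarse heart mask. At full scale the grid is 3 mm /
   112x112x112; the desk-scale profile uses 4 mm / 32x32x32.
2. **Crop derivation and pericardium segmentation** (`segnet`). The
   coarse mask is resampled back to the native spacing; its bounding box
   is expanded by a safety margin on every face (11 voxels at full
   scale, 3 in the desk profile — the margin guards against coarse-stage
   under-segmentation), and a fixed-size high-resolution crop is taken
   around the expanded-box center (384x384x80 at full scale, 48x48x32 at
   desk scale). A second U-Net segments the pericardial sac on this crop
   (2.0x2.0x2.5 mm at full scale; the desk profile stays at the phantom's
   native 2 mm so restoration is lossless). The predicted mask is mapped
   back to the original geometry by inverting the pad, resampling
   nearest-neighbour, and pasting the crop at its recorded offset.
3. **EAT rendering and measures** (`eatq`). Inside the restored sac mask,
   voxels with attenuation in the inclusive window [-190, -30] HU are
   EAT. Volume is voxel count x voxel volume (cm^3); density is the
   arithmetic mean HU over EAT voxels (undefined, not NaN, when the mask
   is empty); volume is indexed by body surface area (Du Bois
   0.007184 h^0.725 w^0.425 by default, Mosteller sqrt(hw/3600)
   selectable). No connected-component or partial-volume correction is
   applied to the rendered fat.

Voxel conventions: 0-based indices, inclusive bounding boxes, box
midpoints round down, image padding uses -1000 HU (air), masks pad with
zero. Images are interpolated trilinearly, masks nearest-neighbour;
resampling maps voxel centers exactly (an affine-transform lattice, not a
zoom factor), which keeps mask volumes conserved to within the discretization.

## The network and its training recipe

Both stages use the same 3D U-Net family: four down-sampling steps at
full scale (three in the desk profile), two 3x3x3 convolutions + ReLU per
encoder level, 2x max pooling, a bottleneck with a 1x1x1
channel-halving "feature reduction" convolution and dropout 0.5, and a
decoder of nearest-neighbour upsampling, a 1x1x1 channel-halving
up-convolution, skip concatenation and two 3x3x3 convolutions, ending in
a 1x1x1 convolution and sigmoid.

Training minimizes soft Dice loss with Adam. The learning rate starts at
1e-4 at full scale and is multiplied by 0.5 (localization) or 0.3
(segmentation) every 100 epochs over 1200 epochs; batch sizes are 3 and
4. Augmentation is random axial-plane translation (+/-10 voxels
localization, +/-20 segmentation) and rotation about a random axis
(+/-4 and +/-35 degrees). Localization holds a single 70/30 train/tune
split; segmentation redraws the 70/30 split every 100 epochs from the
full pool (a rotation-style use of all data). The desk profile
compresses this recipe in time: lr0 1e-3 held constant over 20
(localization) and 64 (segmentation) epochs, resplit every 25, smaller
augmentation amplitudes (+/-3, +/-4 voxels; +/-4, +/-10 degrees).

Two stabilizers are part of the trainer, not part of the standard recipe above, and
were added after reproducible failures: the output-head bias is
initialized to -2 so training starts from sparse foreground predictions,
and gradients are clipped to a global L2 norm of 1. Soft-Dice training
started from near-0.5 predictions otherwise collapsed into the
empty-prediction attractor (all logits driven negative, sigmoid
saturation, vanishing gradients) on small training pools.

There is no deep-learning framework in this package's dependency set:
the network, Adam, and backpropagation are implemented directly on
numpy, with numba-compiled direct-convolution kernels (channels-first,
innermost loop contiguous along the last axis, output channels blocked
by 8) for large feature maps and im2col+BLAS for small ones. Gradients
are verified against finite differences and the two kernel paths against
each other in the test suite.

## The phantom substrate

`phantom` generates torso-like volumes with exact ground truth: air
background, an elliptic-cylinder soft-tissue torso with a subcutaneous
fat ring, two lung fields near -800 HU, a heart ellipsoid (~+40 HU)
enclosed by a pericardial sac whose inner shell holds fat drawn from
N(-100, 20) clipped to the EAT window, with a configurable fraction of
shell voxels actually fat (default 0.9). Truth masks are frozen before
additive acquisition noise (SD 10 HU); after noise, fat-voxel HUs are
re-clipped to the window so the recorded EAT truth remains exactly the
set of voxels the rendering stage should find. Heart center and radii
are jittered per seed (+/-4% of extent, +/-10% of radii); default radii
(30, 26, 18) mm are chosen so the sac plus jitter plus localization
error fits the desk-scale crop. Height and weight are drawn from
truncated normals (170/10 cm, 80/15 kg) and matter only through BSA.

What the phantoms do **not** emulate: partial-volume effects at the sac
boundary, gating/motion artifacts, beam hardening, contrast variation,
anatomical variability of the mediastinum, or the manual four-reader
segmentation reference. Passing the desk-scale Dice check therefore
demonstrates that the pipeline's stages, geometry bookkeeping and
training recipe are implemented correctly — not that this network would
reach the same accuracy on clinical CT.

## The cohort simulator

`simcohort` generates participant-level tables with the joint structure
the survival analyses assume:

* **EAT biomarkers.** BSA-indexed volume is lognormal with mean 70.3 and
  SD 24.6 cm^3/m^2 (the lognormal's implied quartile boundaries
  ~52.8/66.4/83.5 match the target quartile cut-points of
  <53 / 53-67 / 67-85 / >85 far better than a normal would, whose
  symmetric 54/70/87 cannot); density is N(-77.7, 5.2)
  HU. They are joined by a Gaussian copula whose latent Pearson
  correlation is 2 sin(pi rho_s/6) applied to the Spearman target -0.72
  — derived, never set directly.
* **Covariates** are independent draws from the target marginals (age
  N(61,5), 59% male, BMI N(27.9,5), 48% current smokers, etc.); race,
  ethnicity and education are categorical draws with zero true hazard.
  Pack-years are lognormal around a median of 48.
* **Coronary calcium** is zero-inflated (24% exact zeros); among scored
  positives, ln(CAC+1) is linear in EAT volume with slope 0.04 per
  10 cm^3/m^2 plus N(0, 1.6) noise.
* **Survival.** Event times are exponential with rate
  lambda0 exp(eta), eta the per-10-unit centered linear predictor with
  true mutually-adjusted hazard ratios {volume 1.19, density 1.66}
  (all-cause) or {1.27, 2.14} (cardiovascular). Administrative censoring
  is Uniform(11.4, 13.2) years, reproducing a median follow-up of 12.3
  (IQR ~11.9-12.8) years with no loss to follow-up. The baseline rate is
  calibrated by root-finding on the exact censor-integrated death
  probability, averaged over a fixed-seed Monte-Carlo covariate sample,
  to hit 19.5% cumulative mortality. Composite mode runs two independent
  cause-specific hazards; the non-CV log-HRs are moment-matched
  (s b_cv + (1-s) b_ncv = b_allcause with s = 0.232) and the two baseline
  rates are solved jointly so total mortality and the 23.2% CV share of
  deaths both hit their targets.

The univariable volume hazard ratio (~1.10) is emergent: it arises from
the -0.72 volume-density correlation attenuating the mutually-adjusted
1.19, and is checked against omitted-variable algebra in the tests.

## The statistics layer

Cox models are partial-likelihood fits with Efron tie handling (ties are
measure-zero in the simulator anyway); EAT terms are rescaled so hazard
ratios are per 10 cm^3/m^2 or 10 HU. Cardiovascular analyses are
cause-specific: non-CV deaths are censored at their death time. The
three nested prognostic models (EAT only; + clinical covariates; + ln
CAC) are declared as strict covariate supersets so the likelihood-ratio
test's nesting is structural. ln-CAC uses a +1 offset because the cohort
contains true zeros. CAC categories are the clinical 0 / 1-100 /
101-300 / >300 bins, implemented as half-open intervals so fractional
scores fall upward. Quartiles are type-7 sample percentiles.

Harrell's C counts concordant over comparable pairs (earlier subject an
event; score ties 1/2). The continuous net reclassification improvement
is P(up|event) - P(down|event) + P(down|non-event) - P(up|non-event)
with ties contributing zero, computed on end-of-follow-up event status —
well-defined here because censoring is administrative. Inputs should be
each model's predicted event probability at a common horizon
(`predicted_risk`, Breslow baseline); raw linear predictors from
different models are not comparable (their arbitrary centering dominates
the up/down signs).

## Problem sizes and determinism

The shipped evaluation trains the desk-scale cascade on 40 phantoms
(64^3 at 2 mm) and evaluates 20 held-out phantoms; generator
calibration uses 10^6 biomarker draws; parameter-recovery fits use
cohorts of 10^5. All randomness flows from explicit integer seeds
(numpy Generator streams; split, augmentation and batch-order streams
are separate so the split schedule does not depend on augmentation
settings), and training is bit-reproducible for a fixed seed on a given
BLAS build.

## Known limitations

* The desk-scale Dice result (median ~0.95-0.97) sits near the 0.95
  bar it is held to; a different seed can move individual-case Dice by
  ~0.01.
  The full-scale configuration (112^3/1200 epochs) is declared but not
  exercised here.
* Surface distance is defined on boundary-voxel centers, so its desk
  value collapses to 0 mm when predictions are voxel-exact; it is
  reported against a resolution bound (<= 2x voxel size), not the
  clinical 1.6 mm, which is resolution- and cohort-dependent.
* The simulator's covariates are independent of the EAT biomarkers by
  default, so adjusted (Model 2/3) hazard ratios equal Model 1 in
  expectation; realistic confounding structure cannot be recovered from
  summary statistics alone. A hook for covariate effects exists
  (`extra_log_hrs`) but carries no calibrated defaults.
* Real-data quantities — the 0.95 Dice / 1.6 mm surface distance on
  clinical scans, absolute C-statistics 0.700-0.776 and cNRI 0.12-0.49 —
  require the original cohorts and are out of scope; the package covers
  them with scaled-down and property-based analogues.
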