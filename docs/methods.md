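# Methods

## Problem and scope

Sonomyography infers a user's intended hand grasp from B-mode ultrasound of
the residual forearm: voluntary contraction deforms muscle, the deformation
is visible in the image, and a per-frame classifier maps the image to one of
three grasps (*rest*, *tripod* ← wrist flexion, *point* ← wrist extension).
The analysis implemented here asks three questions. (1) How well does a
linear classifier decode grasps from raw downscaled pixels, and how does
that degrade when the arm position at test time differs from training —
and how far does pooling training positions, or training during continuous
arm movement, repair it? (2) How similar are the underlying images, within
and across grasps, relative to what two speckle fields share by chance?
(3) At stream level, how cleanly do per-frame predictions drive a discrete
three-grasp hand (transient bouts, percent-point)?

No public residual-limb ultrasound dataset accompanies this analysis, so
the pipeline runs end-to-end on a synthetic generator whose job is to
reproduce the *statistical structure* the method depends on — not tissue
acoustics. Everything downstream of the generator (frame handling, LDA,
SSIM, stream metrics) operates identically on real 100 × 140, 8-bit frame
sequences.

## Frame representation

Frames are 100 rows (depth) × 140 columns (lateral) of 8-bit gray,
produced by exact area (block-mean) resampling of any larger raw image
followed by quantization. Every integer gray level is produced by rounding
half away from zero; this convention is fixed so that tests can assert
pixel-exact values. Classifier features are the row-major flattening
scaled to [0, 1] (feature *k* is pixel (*k* // 140, *k* mod 140) / 255),
which keeps covariance conditioning independent of bit depth. Upscaling is
deliberately unsupported: the canonical grid is a downscale target.

## Synthetic generator

The forward model is phenomenological:

* **Templates.** A shared layout of six horizontal echogenic Gaussian bands
  (muscle bellies / fascial planes in a transverse view) on a 0.15
  background, with a gentle lateral undulation. Each non-rest grasp
  displaces band centers (±6 px range) and perturbs band amplitudes
  (±0.12); both deviations scale linearly with `grasp_separation`
  (default 1.0), so separation 0 collapses the three classes to one
  template and class distance grows monotonically.
* **Arm position.** A scalar `arm_state` ∈ [0, 1] parameterizes position
  along the workspace path: the seven static positions sit at 0, 1/6, …, 1;
  each of the four movement patterns sweeps one quarter of the path; the
  20-s continuous-dynamic sweep concatenates the four patterns with the
  first and third traversed in reverse so the combined path is continuous.
  Position acts as an affine warp (translation up to `position_effect`
  pixels, default 3.0, plus a small shear), smooth in `arm_state` — the
  transducer-shift/tilt analog.
* **Load.** Load A (full distal hardware) multiplies all motion-coupled
  perturbations by 1.5, load B (light surrogate) by 1.0. Three noise
  sources are load-scaled: the position warp itself, a per-acquisition
  placement jitter (sd 0.35 px × scale — imperfect repositioning between
  repeats), and a per-frame micro-jitter (sd 0.2 px × scale — arm motion
  coupling into the socket). The last is what makes load-A SSIM traces
  visibly more variable, most strongly in dynamic mode.
* **Speckle.** Multiplicative Rayleigh speckle, normalized to unit mean and
  smoothed to a ~1-px grain (speckle cell size is set by the imaging PSF,
  so raw i.i.d. noise would be unrealistically harsh). The *chance-baseline*
  images are different by design: pure i.i.d. Rayleigh(σ = 0.101) intensity
  fields on [0, 1], quantized — the stated construction of the similarity
  floor, with no imaging structure at all.
* **Dynamic contrast.** Grasp deformation is multiplied by
  `dynamic_contrast` = 1.25 whenever the arm is in motion (dynamic,
  continuous-dynamic, and scripted functional tasks). This models the
  observation that actively moving users produce stronger, more distinct
  contractions; it is the single mechanism from which both dynamic-mode
  advantages (higher classification accuracy, wider same/different SSIM
  gap) follow, rather than per-metric switches.
* **Frame counts.** An acquisition holds
  ⌊duration × rate + U[0, 1)⌋ frames: at the default 11.5 Hz this gives 57
  or 58 frames per 5-s recording and 230–231 per 20-s sweep, reproducing
  the observed count jitter without modeling the grabber clock.

Every operation is a pure function of (inputs, seed); sessions randomize
presentation order from their seed.

What the generator does **not** emulate: anatomy-specific echotexture,
out-of-plane probe rotation, contraction dynamics within a hold, fatigue,
skin-coupling changes, or inter-subject variability. Passing tests
therefore show that the *analysis* recovers the structure the generator
encodes at realistic noise levels — not that a particular accuracy will be
attained on any real limb.

## Classifier

LDA on 14,000 raw pixel features with a few hundred training frames
requires a covariance model: the pooled within-class covariance is shrunk
toward its scaled identity,
Σ<sub>λ</sub> = (1 − λ) Σ<sub>pooled</sub> + λ (tr Σ<sub>pooled</sub>/p) I,
with λ ∈ [0, 1]. `auto` (the default) uses the Ledoit–Wolf analytic rule,
computed from the Gram matrix of the class-centered data so no p × p matrix
is ever formed; a fixed λ is accepted everywhere. For p > max(n, 512) the
discriminant solve uses the Woodbury identity on the low-rank scatter —
algebraically exact, O(n²p) instead of O(p³) — and λ = 0 is rejected in
that regime because the covariance is genuinely singular. Degenerate
zero-scatter input falls back to a unit isotropic target (the nearest-mean
rule is scale-free). Priors come from training proportions; ties in the
linear scores break by fixed class order (REST < TRIPOD < POINT). Per-frame
decisions are never smoothed — stream-level behavior is measured on the raw
prediction sequence.

Train/test splitting assigns, per (grasp × condition × load) cell, one of
the two repeats to training by a seeded fair coin. Accuracy is
100 · n<sub>correct</sub>/n<sub>total</sub> over frames. The
cross-condition matrix trains one classifier per condition plus a pooled
ALL row (8 × 7 static, 5 × 4 dynamic); its diagonal is intra-condition
accuracy, off-diagonal inter-condition generalization.

## SSIM

SSIM is computed from the luminance/contrast/structure decomposition with
C1 = (K1·L)², C2 = (K2·L)², C3 = C2/2 and exponents α = β = γ = 1. The
constants K1 = 0.01, K2 = 0.03 and the Gaussian 11 × 11 (sd 1.5) local
window are the canonical defaults; both are configurable, and a global
(whole-image-moment) window is provided because either reading of "local
statistics" is defensible. Local maps are cropped to the interior where
the window fits before averaging. L defaults to the frame's dynamic range
(255) and is overridable to 1.0 for [0, 1]-scaled data, since the
intensity scale on which the chance images' σ was fitted is ambiguous.
The chance baseline enumerates all n(n−1)/2 unordered pairs (4,950 at
n = 100), caching per-image window statistics so each pair costs one
cross-term filter. Same-grasp comparisons pair frame *k* of repeat 1 with
frame *k* of repeat 2 (same grasp/condition, first min(n₁, n₂) frames);
different-grasp comparisons pair frame *k* across grasps within the same
condition and repeat. The two samples are compared with a Welch
(unequal-variance) two-sided t-test; the degenerate all-constant case
returns p = 1 by convention.

The printed-literature chance value for this construction (≈ 0.23) is not
an exact target: it depends on unstated constants, windowing and intensity
scaling. At this package's defaults the chance mean lands near 0.10, and
what the analysis relies on — a floor several tenths below same-grasp
similarity — is asserted instead.

## Stream metrics and the virtual hand

A prediction stream is the per-frame classifier output in time order.
Transient bouts are maximal runs of identical predictions strictly shorter
than 5 frames (a run of exactly 5 is not transient — strict reading of the
definition); boundary runs count like interior runs. Percent-point is the
percentage of frames classified POINT. Latency is modeled as a constant
delay (default 0.532 s) between prediction and hand command; it shifts the
hand trajectory only and provably leaves both metrics unchanged. The
virtual hand starts in the rest configuration and changes configuration
exactly when the delayed prediction changes; transition kinematics are
preset and outside the classifier's control.

The three functional tests are represented as scripted grasp-demand
sequences over arm-state paths — a repetitive midline pick-and-place
script (8 targets), a 16-target grid script, and a 14-target
wide-workspace arch script — each target a TRIPOD hold followed by a REST
return, every segment ≥ 10 frames so a clean classifier should produce
zero transient bouts. The physical block-and-box scores themselves
(completion counts/times with a human in the loop) cannot be reproduced;
the demand structure they impose on the classifier can.

Repeatability protocols train one classifier (continuous-dynamic strategy,
load B) and reuse it: 3 consecutive rounds (short-term), 7 rounds at
30-minute marks (three-hour), or before/after a transducer-replacement
perturbation (don/doff; default 2-px lateral shift + 1° shear applied to
test-time rendering).

## Numerical and design choices

* Rounding half away from zero for every gray level; area resampling uses
  exact interval-overlap weights, so constant fields are preserved bit-exactly.
* The Gaussian SSIM window is truncated at radius 5 (matching the 11-px
  window), making the implementation directly comparable to the standard
  reference implementation to < 1e-6.
* Sub-seeds are derived by hashing (SHA-256) the named seed with fixed
  salts, keeping all seeds below 2³¹ and independent across uses.
* Problem sizes in tests and the acceptance script are the study's own:
  full 42-record static and 24-record dynamic sessions per load, 100
  chance images, 1,000 random sequences for the stream oracle. One full
  offline experiment runs in about a minute on one CPU.
* Accuracy matrices and SSIM summaries are written as RFC-4180 CSV bodies
  under a one-line `# config_hash=…` provenance header; identical
  configurations reproduce byte-identical bodies.

## Limitations

The generator's class structure is linear in its separation parameter and
its position effect is a global affine warp; real position effects include
out-of-plane motion that no 2-D warp captures, and real load effects
change tissue compression, not just jitter. LDA accuracies near 100% on
defaults reflect the generator's separability at those settings, matching
the upper range of what pooled training achieves in practice, and should
be read as a regime, not a forecast. SSIM absolute levels depend strongly
on speckle grain and window choice; only contrasts between conditions are
meaningful.
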