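# Methods

`fetalscan` automates the retrospective analysis of large fetal ultrasound
(US) DICOM repositories: it routes every stored object to the B-mode
stream, recognises which fetal structure each B-mode image shows,
identifies transcerebellar (TC) head planes, and measures the thalamus
diameter on them. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic phantoms do and do
not establish.

## 1. B-mode triage cascade

Four cheap filters run in sequence; the first positive filter labels the
file and stops, and whatever survives all four is a 2D B-mode still.

1. **Video** — the DICOM `NumberOfFrames` header (0028,0008) present and
   > 1. Header-only: at repository scale no pixel data is decoded for
   cine loops. 4D rendered-surface snapshots are stored as multi-frame
   clips and are removed here too.
2. **Dual display** — the column-sum intensity profile is smoothed with
   an 11-sample moving average; within a central window of 20% of the
   width, a minimum below 0.2x the profile median marks the near-black
   gutter between side-by-side panels. The two fractions quantify
   "a trough near the middle" and are configurable; `split_x` is reported
   at the center of the minimal plateau.
3. **Color Doppler** — RGB is converted to HSV (channels scaled to
   [0,1]); a pixel is colored when saturation **and** value are both
   >= t = 0.1. Saturation is what separates a velocity color map from
   grayscale tissue stored as RGB (where S = 0 identically); the joint
   value test discards black pixels whose hue is meaningless. The frame
   is Doppler when colored pixels exceed 0.1% of the frame
   (`min_colored_frac = 0.001`; setting 0 restores a literal "any
   non-zero" rule, at the cost of sensitivity to chroma compression
   noise).
4. **M-mode / pulsed Doppler** — these displays put a bright B-mode
   reference strip above a dark spectral/temporal trace. On the row-sum
   profile split at mid-height, the frame is flagged when the highest
   first-half peak has topological prominence > 50000 **and** the
   first/second-half peak ratio exceeds 2.5. A missing or zero
   second-half peak makes the ratio +inf. Both constants assume 8-bit
   intensities summed across a ~800 px row; `normalize_profile=True`
   divides by the width for size-independent thresholds. Peaks are
   strict local maxima; plateaus count once at their leftmost sample.

Monotonicity holds by construction: raising `half_ratio_min` can only
move files from the M-mode/pulsed label to B-mode, never the reverse.
Dual displays are removed from the B-mode stream; `split_dual` can emit
the two halves as derived records for downstream use.

## 2. Hierarchical plane recognition

B-mode images are classified in two stages: a 14-class organ stage
(Abdomen, Arm, BloodVessels, CordInsertion, Face, FemurHumerus, Foot,
Genitals, Head, Heart, Kidney, Leg, Spine, Hand) and, only for Head
images, a binary TC vs non-TC stage. Non-head images never touch the
intra-plane model.

Both stages are linear-kernel SVMs (one-vs-rest for the organ stage,
C = 1.0) over image features, with per-feature standardisation fitted on
the training split; a linear kernel avoids regularisation tuning, and
standardisation is required because the descriptor mixes
gradient-histogram mass with intensity statistics on different scales.
Training uses a stratified 90/10 train/validation split with an explicit
seed. Ties in decision values break toward the lowest class index, so
prediction is deterministic.

The **feature extractor is a pluggable contract** (same image -> same
fixed-length vector). Two implementations:

- `lite` (default): a deterministic multiscale descriptor — at three
  dyadic scales the image is divided into a 4x4 grid, each cell
  contributing an 8-bin magnitude-weighted gradient-orientation histogram
  plus its intensity mean and standard deviation; 480 dimensions, no
  learned weights, bit-reproducible. A black image maps to the zero
  vector.
- `alexnet-ft`: the fine-tuned-CNN contract — an AlexNet-topology network
  whose 1000-way final layer is replaced by a 14-way fetal-organ layer,
  fine-tuned by SGD with cross-entropy and layer-specific learning rates
  (1e-3 for the new layer, 1e-4 elsewhere), with the penultimate
  4096-dimensional activations as features. It needs a deep-learning
  backend and pretrained weights, so it is constructed lazily and is not
  used by the tests.

Training-time augmentation produces exactly six variants per image: the
central square crop `c` (side 0.9 x the shorter image side) plus the four
corner crops and the center crop of `c` (side 0.9 x side(c)), each
resized to 227x227. Resizing always preserves aspect ratio: scale until
the longer side fits, then zero-pad the shorter side symmetrically. At
SVM time one feature per image (the central variant) is used.

## 3. Thalamus biometry

The thalamus lacks crisp US boundaries, so it is never segmented
directly. Instead the pipeline segments the "guitar" — the dark
negative space surrounding the thalami — and reads the diameter from an
intensity profile through the guitar's waist, which pinches exactly at
the thalamic extremities.

**Denoising.** Perona–Malik nonlinear diffusion, explicit 4-neighbour
scheme: 15 iterations, time step 0.2 (stability requires <= 0.25),
exponential edge-stopping flux with conductance 20 on the 0-255 scale
(a `rational` flux is available). The output range never exceeds the
input range; with very large conductance the scheme reduces to linear
heat diffusion, which the tests verify against a Gaussian convolution on
smooth inputs (on broadband noise the explicit scheme and the continuous
kernel legitimately differ at high frequencies).

**Skull localization.** The fetal skull is the registration landmark for
everything that follows. Edge map: Otsu-thresholded Sobel gradient
magnitude, morphologically closed (disk radius 2). An iterative
randomized Hough transform samples 5-point subsets, fits exact conics
(null space of the 5x6 design matrix, batched SVD), keeps candidates that
are real ellipses with plausible axes, and votes by inlier count
(point-to-ellipse distance < 2 px, first-order along-ray approximation).
After each of up to 3 rounds of 2000 draws the winner's inliers are
removed and the search repeats; the overall best candidate is refined by
a least-squares ellipse fit to all edge points within a 6 px band,
iterated three times. The wide refinement band is deliberate: a skull
ring has two gradient edges a few pixels apart, and a 2 px band lets the
fit lock asymmetrically onto the inner edge on one side and the outer on
the other, displacing the center by ~2 px along the major axis; a band
covering both edges makes the ring centerline the only fixed point.
Detection is bit-reproducible given the seed. The fraction of occupied
10-degree arc bins among inliers is the arc coverage; below 0.70 the
result is flagged `skull_incomplete` (an incompletely imaged skull is a
known failure mode of zoomed or motion-corrupted acquisitions).

**Orientation.** A heuristic stands in for a trained classifier (the
contract allows either): within the outer 25% elliptical annulus of the
eroded intracranial area, the half (split at the skull's minor axis) with
the brighter band — posterior fossa and cerebellum — is the occiput.
Margins under 2% resolve to LEFT_OCCIPUT with `low_confidence` set.
Mirroring the image flips the label.

**Shape model.** The guitar outline is parameterised by L = 32 landmarks
ordered clockwise (in image view) from the point directly superior to the
centroid; indices 0 and 16 are the superior and inferior waist points.
Generalized Procrustes alignment (similarity transforms, no reflection,
convergence 1e-6) followed by PCA of the aligned coordinates yields the
point-distribution model; the smallest k with cumulative variance >= 95%
is kept. A population identical up to similarity transforms yields k = 0.
Full-mode reconstruction reproduces every aligned training shape to
machine precision, and the eigenvalue sum equals the total aligned
variance — both asserted in tests.

**Segmentation.** The guitar is fitted by model-based curve evolution:
the zero level set is the polygon of the posed model shape, and the
evolving curve is restricted to the SSM's pose + mode-coefficient
subspace (parameters: translation, log-scale, rotation, k mode
coefficients). The energy is

    E = l1 * sum_in (I - c_in)^2  +  l2 * sum_out (I - c_out)^2
      + mu * length + beta * || shape - clamped-projection ||^2

with I normalised to [0,1], c_in/c_out the optimal region means,
l1 = l2 = 1, mu = 0.2, beta = 0.5 and mode coefficients clamped at
`b_limit = 3` standard deviations. Two numerical choices matter:

- *Local region statistics.* The two-phase term is evaluated over a
  central sub-ellipse of the skull (55% of the major, 92% of the minor
  axis) rather than the whole intracranial area. The intracranial image
  is tri-modal (dark guitar, mid-gray parenchyma, bright
  butterfly/falx/skull band), and globally the best two-phase partition
  is "bright vs non-bright": an unconstrained fit can reach *lower*
  energy than the true configuration by swallowing parenchyma.
  Restricting the statistics to the neighbourhood that actually contains
  the guitar and thalamus makes the guitar the two-phase optimum.
- *Bounded accept-if-better coordinate descent.* Starting from the mean
  shape at the skull center, scaled so its largest centroid-to-landmark
  distance is 0.35x the skull semi-minor axis, the optimizer walks one
  parameter at a time with adaptive steps and accepts only energy
  decreases — so the recorded energy sequence is non-increasing by
  construction, which a plain explicit gradient scheme does not
  guarantee. The search is a box around the anatomically registered
  initialization (translation +-0.12 x semi-minor axis, log-scale
  +-0.35, rotation +-0.35 rad) with six starts: both midline polarities
  (0 and pi — the anatomy may face either way) crossed with three
  initial values of the dominant bulb-asymmetry mode, whose landscape is
  two-basined. A fresh-step restart after first convergence escapes
  premature step collapse in coupled scale/mode valleys.

**Measurement.** The measurement line passes through the two fitted
waist landmarks, perpendicular to the midline. From each waist landmark
the intensity profile (sampled at 0.5 px, smoothed with sigma = 2 px) is
followed outward across the intracranial span; the endpoint is the
outermost crossing of half the local intensity envelope (the maximum
seen on that side), with sub-sample interpolation at the crossing. The
half-max fraction is configurable. If a side has no usable envelope the
waist landmark itself is the fallback endpoint and `low_confidence` is
set. The diameter is the endpoint distance; millimetres are reported as
diameter x the mean of row/column pixel spacing, and a missing spacing
header yields a px-only result flagged `no_spacing` (header completeness
varies across vendors).

## 4. Synthetic phantoms

No public fetal-US repository accompanies the pipeline's target use, so
every stage is exercised on seeded schematic phantoms with exact ground
truth; (type, seed, parameters) fixes each output byte-for-byte.

- **Speckle** is multiplicative unit-mean gamma noise (shape 4), the
  standard US speckle surrogate; for anatomy phantoms it is lightly
  smoothed (correlated speckle) before multiplication.
- **Modality suite** (7 kinds x n): sector B-mode; dual display (two
  panels, >=30 px near-black gutter); color Doppler (saturated patch
  >= 1% of the frame on an RGB B-mode); pulsed Doppler and M-mode
  (bright reference strip over a dark trace, margins sized so prominence
  and ratio clear their thresholds by >= 25%); multi-frame video and a
  4D-snapshot look-alike (both multi-frame, NumberOfFrames in 10..60).
  The >= 25% margin on every deciding criterion makes 100% routing a
  soundness check, not a threshold-tuning exercise.
- **Plane suite** (14 classes x n): one parametric motif per organ
  (long bright bar for FemurHumerus, rib ladder for Spine, four-chamber
  blobs for Heart, ...) with rotation/scale jitter and speckle; border
  fill uses edge values so jitter does not introduce black frames absent
  from deployment images. The Head class is rendered at full TC-phantom
  geometry (half TC-like, half TT/TV-like) so the classifier trains on
  exactly the anatomy the biometry stage receives.
- **TC phantom**: bright elliptical skull ring (a in [160,200] px,
  b/a in [0.72,0.85]), interrupted midline falx along the major axis, a
  vertical butterfly thalamus whose outer lobe edges are exactly the
  requested diameter apart (60-200 px), the dark guitar drawn over the
  butterfly center, and a cerebellum blob marking the occiput.
  `truncate_skull` removes 35% of the ring arc (driving arc coverage
  below the 0.70 flag bound); `mirror` reflects the image, the truth
  landmarks and the orientation.
- **Guitar population** (default n = 100): the canonical outline
  deformed along three fixed radial harmonics (cos, cos 2, sin 3 of the
  landmark angle) with zero-mean coefficients of sigma 6, 3 and 1.5 px
  at the reference scale, plus similarity jitter. The drawn coefficient
  sample is whitened so the population realises the nominal variances
  exactly and without cross-correlation; without this, finite-sample
  coefficient covariance rotates the PCA modes measurably away from the
  generating fields, blunting the population's role as a mode oracle.

**What the phantoms do and do not show.** They verify algorithmic
correctness: that each filter keys on the statistic it claims, that the
SSM recovers a known deformation basis, that segmentation and
measurement recover known geometry through the full pipeline, and that
flags fire on the failure modes they name. They are schematic — no
acoustic simulation, no shadowing, no probe-angle or gestational-age
variation, no vendor annotation overlays — so passing them does not
certify clinical accuracy on hospital data; published clinical
performance of this pipeline family rests on expert-read hospital
evaluations that no desk reproduction can replace.

## 5. Evaluation module

Accuracy, precision and recall follow the standard confusion-count
formulas; a zero denominator reports the metric as undefined rather
than 0, which would silently inflate averages. Inter-reader agreement is
percentage agreement plus Cohen's kappa, kappa = (p_o - p_e)/(1 - p_e)
with p_e from the raters' marginal frequencies (multi-category form; two
constant, identical raters define kappa = 1). kappa <= p_o whenever
p_e > 0, asserted as a property test.

The clinician review gallery is deliberately offline: two static HTML
pages (image-quality assessment with thalamus / cisterna-magna
visibility fields, and measurement confirmation with the measurement
line overlaid at the result's exact pixel coordinates), with form
controls exporting to CSV — the two-assessment workflow with zero
deployment burden.

## 6. Problem sizes and reproducibility

Test and acceptance runs use the suite sizes the generators default to:
7x40 modality phantoms, 14x40 plane phantoms, 100 training guitars, 20
skull-ring phantoms, 25 end-to-end TC phantoms, and 3,109 synthetic
images for the augmentation-count check. Every stochastic stage takes an
explicit integer seed: phantom generation derives per-file child seeds,
the RHT consumes its own generator, SVM training seeds both the split
and the solver, and the segmentation descent is deterministic (its seed
parameter is reserved). Rerunning any stage with the same seed
reproduces its outputs bit for bit.

## 7. Known limitations

- The `lite` descriptor is designed for the schematic phantom domain; on
  clinical images the CNN contract (pretrained + fine-tuned weights) is
  the intended extractor.
- The orientation heuristic assumes the posterior fossa is the brightest
  outer-annulus structure; strong acoustic shadowing would break it —
  hence the pluggable-classifier contract.
- The segmentation's localized region statistics assume the skull fit is
  approximately correct; a grossly wrong skull ellipse propagates.
- Only the head/TC branch of the per-organ intra-plane ensemble is
  implemented; the other 13 organ branches are out of scope and the
  hierarchy treats their organ label as terminal.
- Dual-display halves are removed from the B-mode stream by default
  rather than re-entering the pipeline as two images.
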