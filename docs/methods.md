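# Methods

This note documents the models and procedures implemented in `dermpipe`,
the defaults and why they were chosen, what the synthetic fixtures do and
do not emulate, and the numerical conventions that keep results
reproducible.

## Field-of-view detection and cropping

Dermoscopic images acquired without pre-cropping show the illuminated
circular field of view (FOV) surrounded by a near-black border.  Detection
proceeds in four steps:

1. **Binarization** at a low mean-channel threshold (default 20/255).  The
   method only requires the threshold to sit above sensor noise and below
   any illuminated skin tone; 20 satisfies both with a wide margin.
2. **Equivalent ellipse.**  The foreground's center of mass and second
   central moments are computed over pixel centers (x + 0.5, y + 0.5); the
   ellipse with the same moments has semi-axes 2·√λ for the eigenvalues λ
   of the moment matrix, and its orientation is the principal eigenvector
   (θ ∈ (−π/2, π/2]).  Under this convention a filled disk of radius r maps
   back to semi-axes r, and a full w×h frame to w/√3 × h/√3.  A mask with
   no foreground or with collinear foreground raises an error, which the
   crop stage converts into a logged no-crop.
3. **Bounding box** of the rotated ellipse: half-extents
   hx = √(a²cos²θ + b²sin²θ), hy = √(a²sin²θ + b²cos²θ), floored/ceiled to
   half-open pixel coordinates and clipped to the frame.
4. **Crop-necessity heuristic.**  Cropping fires only when at least 5% of
   the pixels lie outside the box **and** mean_inside ≥ 2.0 ·
   (mean_outside + 1).  The "+1" guards against division-free comparison
   with a pitch-black exterior; the ratio 2.0 and area fraction 0.05 are
   config-exposed since the underlying criterion ("substantially
   different") is qualitative.  A box covering the whole frame trivially
   returns false.

Coordinates are 0-based with x = column; boxes are half-open.  One stated
convention avoids off-by-one drift between the generator's ground truth
and the detector.

## Shades-of-Gray color constancy

The per-channel illuminant is estimated as the Minkowski mean
e_c = (mean(I_c^p))^(1/p) with p = 6.  Channels are rescaled to a common
gray g, for which the arithmetic mean of (e_r, e_g, e_b) is used: this
preserves overall brightness and makes achromatic uniform images exact
fixed points.  An identically zero channel is left unchanged with a
warning.  Integer inputs are clipped to [0, 255] and rounded back; float
inputs stay float so the equalization property (post-correction p-norm
means equal to better than 1e-4 relative) can be verified without
quantization noise.

## Resizing

Images whose longer side exceeds 600 px are downscaled to 600 with the
aspect ratio preserved (bilinear, antialiased); smaller images pass through
untouched, which makes the operation idempotent.  600 px matches the
curated reference resolution of the largest public dermoscopy corpus.

## Metadata encoding

The 11-vector is site one-hot (8, alphabetical over the ISIC site names) +
sex one-hot (female, male) + age in years.  Age is fed raw — the −5
missing sentinel is only meaningful on the raw scale, where 0 is a
legitimate age and all observed values are non-negative multiples of 5.
Metadata dropout operates on the *record* before encoding, so a dropped
property always yields a consistent all-zero block or sentinel, never a
partially zeroed one.  The category orders are fixed here because the
source tables carry no canonical order; any fixed order works as long as
it is stable across training and prediction.

## Network and training

`dermpipe.nn` implements the needed layers (conv via im2col, batch norm,
ReLU, inverted dropout, linear, global average pooling), Adam, and
backpropagation in numpy, with gradients validated against central finite
differences in the test suite.  The backbone contract is minimal: map a
(N, 3, H, W) batch to pooled features of a declared width.  `TinyConvNet`
(three stride-2 conv blocks, widths 16/32/64, global average pool) is the
desk-scale default; GPU-scale pretrained backbones can be attached behind
the same contract.

Stage 1 trains the image-only model: weighted cross-entropy with
n_i = (N/N_i)^k (k = 1), Adam, learning rate halved every 25 epochs, 100
epochs by default, held-out mean sensitivity evaluated every 10 epochs,
best and last snapshots kept.  The weighted loss is the plain mean of
per-sample weighted terms (no renormalization by the batch weight sum).
Checkpoint ties keep the earlier epoch (less overfit).  Classes absent
from a training fold receive weight 0 — they cannot occur in a batch, so
the value is inert; the public `class_weights` helper still rejects
zero-count classes because a weight for an absent class is undefined.

Stage 2 freezes the CNN (verified by hashing all backbone arrays before
and after; a mismatch aborts), attaches the metadata branch
(11 → 256 → 256, each with batch-norm/ReLU/dropout 0.4), concatenates with
the pooled features, and trains one fusion layer (1024 units baseline,
width configurable) plus the classifier.  Image augmentation stays active
during this stage — the CNN performs fresh forward passes, so its features
are not fixed per image — and metadata dropout (p = 0.1) is applied.
Defaults are 50 epochs, lr 1e-5, batch 20; the desk-scale tests shrink
epochs and raise the learning rate through the same config, exactly as
they shrink the 100-epoch stage-1 schedule.

Cross-validation is lesion-grouped: lesions are shuffled by seed and dealt
round-robin into folds (balanced to within one lesion), and train-only
records (external data) join every training set.  The constraint is the
contract; round-robin dealing is simply a deterministic algorithm that
satisfies it.

All randomness flows from explicit `numpy.random.Generator` objects seeded
from the config, so identical seeds reproduce runs bit-for-bit
(single-threaded numpy arithmetic is deterministic).

## Augmentation

Train-time: brightness ±0.3 (additive, fraction of 255), contrast ×(1±0.3),
horizontal/vertical flips (p = 0.5), rotation ±180°, scale 0.8–1.2, shear
±10°, and CutOut with one 16-px square hole filled with 0 (holes clip at
borders).  The transform *families* and the CutOut geometry are part of
the method; the magnitude ranges are defaults exposed in the config.  An
all-zero parameter draw is an exact no-op (the warp is skipped), which
pins down the identity contract.  Two input strategies: same-sized random
crops (zero-padded when the image is smaller than the window) and the
ImageNet-style random-resize crop (area fraction 0.08–1.0, log-uniform
aspect 3/4–4/3, center-crop fallback after 10 infeasible draws).

## Test-time augmentation

Same-sized: 36 crops on a 6×6 grid with top-left corners evenly spaced
over the valid offsets — the simplest deterministic layout producing 36
ordered crops and covering corners and center.  Random-resize: center
crops at fractions {1.0, 0.875, 0.75, 0.625} of the shorter side × flips
{identity, h, v, hv} = 16 views, the only 4×4 factorization consistent
with "four scaled center crops and flipped versions".  The metadata vector
is repeated unchanged for every view, and softmax outputs are averaged
arithmetically.  Nothing at prediction time is random.

## Metric and ensembling

Mean sensitivity S is the unweighted mean of per-class recalls; argmax
ties resolve to the lowest class index, and classes absent from the truth
are excluded with a warning.  Per-class reporting adds one-vs-rest AUC,
partial AUC restricted to sensitivity > 0.8 (area under specificity over
that sensitivity range, normalized by 0.2), and argmax
sensitivity/specificity.

The subset search evaluates every nonempty subset of configurations
(capped at 16 by default — 2^16 subsets is the practical exhaustive
limit; the cap is an explicit override).  The objective is S on the
held-out predictions pooled across folds; per-fold S is logged alongside.
Pooling was chosen over averaging per-fold S because it yields a single
well-defined objective even when folds differ in class composition; both
numbers are reported.  Ties prefer smaller subsets, then lexicographic
order, making the search deterministic.  The final ensemble averages the
best *and* last checkpoints of the selected configurations.  By
construction S(optimal) ≥ S(average-of-all) and ≥ every singleton.

## Synthetic fixtures

The generators emulate exactly the properties the pipeline consumes:

* **Images** — a skin-toned disk (uniform tone + Gaussian noise, σ = 6)
  inside a border of uniform noise in [0, 10] of 255, mimicking sensor
  noise in the "black" area and exercising the low-threshold binarization;
  a lesion blob (filled ellipse) whose hue and size depend
  deterministically on the class index, making the 9-class task separable
  by a tiny CNN.  Ground-truth boxes are the analytic circumscribing boxes
  of the disks.
* **Datasets** — lesions with 1+ images each (all sharing the lesion's
  class), lesion-level metadata with independent per-property missingness,
  ages on the five-year grid {0, …, 85}.  A `class_signal` switch decouples
  appearance from the label and plants the class in the metadata instead
  (age = 10·class, site/sex congruent to the class), providing a
  constructed-signal oracle for the metadata stage.
* **Prediction tensors** — rows interpolate between a symmetric Dirichlet
  draw (chance) and the one-hot truth with a per-configuration `skill`,
  giving known-strength ensemble members.

Not emulated: hair, rulers, vignettes, histogram-corrected subsets,
multi-site acquisition shifts, or photorealistic lesion morphology.
Passing tests therefore demonstrate that the *mechanics* of every stage
are correct (geometry recovered, contracts held, signals recoverable),
not that the tiny backbone would classify real dermoscopy images.

## Desk-scale problem sizes

The shipped experiments use 72×72 fixtures with 64×64 crops, 120–450
images, 3–5 folds, 4–10 stage-1 epochs and up to 12 stage-2 epochs —
sizes chosen so the whole suite exercises every code path in about a
minute of compute while leaving the class structure learnable.  The
training smoke bar (held-out S ≥ 0.60 on 450 separable images after 10
epochs, versus chance 1/9) and the metadata-gain check are calibrated to
these sizes.

## Known limitations

* The numpy backbone is for correctness and desk-scale experiments, not
  throughput; there is no GPU path.
* `same_size_crop` on images much larger than the crop sees only a small
  window per draw; at desk scale fixtures are sized near the crop.
* The exhaustive search is exponential by design; beyond the cap a
  different (out-of-scope) strategy would be needed.
* AUC for classes absent from the truth is reported as missing rather
  than imputed.
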