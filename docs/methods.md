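# Methods

## Problem and approach

Breast masses on B-mode ultrasound are usually segmented by seeded methods:
an operator marks a region and an active contour or level set grows it to the
mass boundary. Seeding is trivial retrospectively but incompatible with live
imaging. `busseg` implements the alternative: an ensemble of ten U-nets, each
trained with a different validation tenth of the patients, whose binarized
per-pixel predictions are fused by majority voting into a single mask with no
seed at all — plus the seeded distance-regularized level-set (DRLSE) baseline
it is compared against, and the Dice / TPF / FPF evaluation protocol.

Because clinical breast-ultrasound images cannot be redistributed, the package
carries a phantom generator producing B-mode-like images with known masks;
all tests and the end-to-end comparison run on those phantoms.

## The ensemble member ("multi" variant)

Encoder of five levels (depth configurable), each two 3x3 zero-padded
convolutions with leaky-ReLU (slope 0.01) and 2^(b + level) filters with
b = 5 at full scale (64, 128, 256, 512, 1024); 2x2 max pooling between
levels; channel dropout (rate 0.6) at the deepest level; decoder of 2x
nearest-neighbor upsampling, concatenation with the matching encoder skip,
and two convolutions; a final 1x1 single-filter convolution with a sigmoid
gives a per-pixel lesion probability. At 208x208 input the deepest grid is
13x13 and the output grid equals the input grid. Training minimizes the
negative soft Dice loss

    L = -(2 * sum(p*g) + s) / (sum(p) + sum(g) + s),   s = 1 by default,

with RMSprop (full-scale learning rate 5e-6), LeCun-uniform initialization.
The smoothing term s keeps the loss finite and informative on empty masks.

The "original" comparator variant differs exactly where the classic
architecture differs: unpadded convolutions (so skip tensors are
center-cropped — at 572 input the crops are 88, 40, 16, 4 pixels per edge and
the output is 388x388), two-channel softmax output trained with categorical
cross-entropy, Xavier-normal initialization, SGD with momentum 0.99, dropout
0.5. Crop sizes are recomputed from shape propagation and validated against
the configured values, which lets the variant run at scaled-down inputs.

There is no deep-learning framework in the supported environment, so both
variants run on a small NumPy engine (`busseg.nn`) with explicit
backpropagation; gradients were verified against central finite differences.
Convolution uses the stacked-shifted-views (im2col) formulation so the inner
loop is one BLAS matmul.

### Design choices where the design was open

- *Upsampling*: nearest-neighbor resize followed by convolution
  (resize-then-convolve); transposed convolution is not offered.
- *Skip merge*: concatenation (the U-net convention), not addition.
- *Leaky slope* 0.01, *Dice smoothing* 1.0, *original-variant SGD learning
  rate* 0.01 — all unstated upstream, all configurable.
- *Dropout* acts on whole feature maps (filters), matching "drop out
  filters"; inverted scaling keeps inference the identity.
- *Epochs/batch/patience* default to 50/8/10 at full scale.

## Scale profile

Full-scale training is a GPU workload. The CPU **scale profile**
(`NetworkConfig.scale_profile()`) is 64x64 input, depth 4, b = 2 (8..64
filters), RMSprop at 5e-4, 12 epochs with patience 4 and batch 8. The rate
is half the common framework default (1e-3): 5e-6 is tuned to long training
on a large clinical corpus and barely moves a phantom-scale model, while at
1e-3 a noticeable fraction of initializations collapse into the degenerate
all-background minimum of the soft Dice loss (validation Dice pinned at 0
with a saturated sigmoid and no recoverable gradient). As a second guard,
`train_member` detects that collapse signature — best validation Dice still
exactly zero after two epochs — and reinitializes the member (at most
twice) from a deterministically derived seed. On phantoms, members converge
within ~5 epochs, so the 12-epoch budget is a CPU-time choice, not a
performance tune; a ten-member ensemble trains in minutes on one core.

## Grouped folds and majority voting

Patients are shuffled once (seeded) and dealt into k folds whose sizes differ
by at most one; every image of a patient stays in one fold, so no member ever
validates on a patient it trained on. Member k trains on folds != k.

Fusion: each member map is binarized at 0.5, the binary maps are averaged
with equal weights, and a pixel is lesion iff the average meets the vote
threshold (default 0.5). The tie — average exactly at the threshold, e.g.
5 votes of 10 — counts as **positive** (inclusive >=); this convention is
fixed and tested. Averaging raw probabilities instead of binary votes is
available (`average_probabilities=True`) but is not the reference method.
The member-count sweep uses deterministic fold-order prefixes, optionally
averaged over seeded random subsets.

## DRLSE baseline

Level-set field phi (negative inside), evolved by explicit Euler steps of

    dphi/dt = mu * div(d_p(|grad phi|) grad phi)
            + lambda * delta_eps(phi) * div(g grad phi / |grad phi|)
            + alpha * g * delta_eps(phi)

with the double-well distance regularizer, smoothed Dirac delta of width
eps, and edge indicator g = 1/(1 + |grad(G_sigma * I)|^2). Weights:
lambda = 0.5, alpha = -0.75 (negative: balloon expansion), eps = 0.5. The
seed is the truth mask eroded by a disk of radius 4 (lesions under 500 px)
or 8 (500 px and larger; the boundary case is treated as large), falling
back to a centroid pixel if erosion empties the mask — deliberately
favourable seeding emulating an expert operator.

Numerical choices: mu = 0.04 and timestep 5 (mu*dt = 0.2 < 0.25 satisfies
the double-well stability bound), sigma = 1.5 px, binary-step initialization
at +/-2, Neumann boundary conditions. Two choices came from measurement
rather than convention:

- the image is internally rescaled to the 0-255 range before the edge
  indicator: on a standard-scored image |grad|^2 is O(1), g never falls
  much below ~0.6, and the balloon force pushes straight through the lesion
  boundary (measured Dice collapses from ~0.98 at the boundary crossing to
  ~0.29 at saturation);
- 1000 iterations rather than ~300: with the small published weights the
  boundary-ward speed on speckled phantoms is ~0.15 px/iteration and decays
  as the contour enters the smoothed edge, so convergence creeps (disk
  benchmark Dice 0.934 at 300, 0.949 at 500, 0.953 at 800 iterations);
  iterations cost ~2 ms each at 128x128. Both remain configurable.

## Metrics

Dice = 2|P∩T|/(|P|+|T|) (defined as 1 when both masks are empty, logged);
TPF = |P∩T|/|T|; FPF = |P\T|/|grid\T|. The FPF denominator is the whole
true-background; this is the normalization under which per-image FPF values
of order 0.01 are plausible when a lesion covers a few percent of the frame.
FP/|T| is available behind a flag. The paired method comparison defaults to
the two-tailed Wilcoxon signed-rank test on per-image Dice (no normality
assumption; all-zero differences return p = 1 by convention), with the
paired t-test behind a flag.

## Phantom generator: what it emulates and what it does not

Each phantom is a piecewise-smooth echogenicity field — background 0.55,
hypoechoic lesion interior at `contrast` x background, optional hyperechoic
rim of `halo_width` px, optional posterior shadow band attenuated
multiplicatively and deepening with depth — multiplied by unit-mean
gamma-distributed speckle (variance speckle_scale^2, shape 1/scale^2;
exponential envelope is the scale = 1 case) blurred by a sigma = 0.7 px
point-spread kernel to correlate the grains. Lesion boundaries are ellipses
optionally perturbed in polar coordinates by band-limited harmonics
(m = 2..6) of peak amplitude `margin_irregularity`, the malignancy analog.
A dataset draws one geometry per patient and jitters center (±2 px) and
radii (±10%) across that patient's views, emulating multiple orientations
of one mass; patients with above-median irregularity are labelled
"malignant" for stratified reporting.

Defaults (the stated world of the tests): 64x64 frames, radii 9-16 px,
contrast 0.30-0.45, irregularity 0-0.15, shadowing in half the cases at
0.2-0.5, halo in 30% at 1-2 px, speckle scale 0.25-0.40.

Not emulated: frequency-dependent attenuation and TGC, refraction and
reverberation artifacts, anatomical context (ducts, fascia, ribs), operator
pre-compression, and real margin texture. A green phantom test therefore
establishes that the machinery (training, voting, level sets, metrics)
behaves correctly on images with B-mode-like first-order statistics — not
clinical-grade segmentation accuracy.

## Preprocessing

The longer image edge is scaled to 208 (bilinear, anti-aliased), the shorter
by the same factor, and the result centered with zero padding (odd remainder
to bottom/right); masks are resampled nearest-neighbor and stay binary. The
placement record (scale, pad offsets) maps predictions back to the original
grid. Standard scoring is applied to the full padded raster, zeros included
(padding therefore shifts the mean; accepted as specified); a constant image
maps to zeros with a warning. Augmentation exposes exactly two transforms —
horizontal mirroring (probability 0.5) and equal-axis zoom (uniform in
0.9-1.1, center crop/pad back to shape) — because vertical flips, shears or
anisotropic scaling would corrupt acoustically meaningful features such as
shadow direction and mass aspect statistics.

## Known limitations

- The NumPy engine is single-device and unbatched across members; full-scale
  (208, b = 5) training is out of CPU reach — only inference and shape
  contracts are exercised at full scale.
- The unpadded comparator at desk scale (input 108, output 20) has a small
  field of view; its mapped-back predictions cover only the frame center,
  which exaggerates (in direction, not kind) the full-scale finding that the
  unpadded single network underperforms the voting ensemble.
- DRLSE uses the dense explicit scheme; no narrow-band acceleration.
- Phantoms are dimensionless (no physical pixel size or depth calibration).
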