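# Methods

## Overview

`strain2scar` localizes chronic myocardial infarcts from left-ventricular
strain fields. The pipeline has four stages: (1) a synthetic phantom
generator producing strain fields with known infarct masks; (2) a bullseye
renderer turning strains into standardized 3-channel images; (3) UNet-based
segmentation, single-fidelity and composite multi-fidelity; (4) strain
quantification from image frame pairs by registration and finite-strain
kinematics. This note records the models, the tunable parameters and their
defaults, the numerical choices, and what the synthetic data do and do not
emulate.

## Synthetic phantoms

A phantom is parameterized by infarct center (short-axis level 0–3 and
angle), infarct area fraction, scar stiffness scale, and a noise level.
Libraries are drawn by Latin hypercube sampling so each continuous
parameter is stratified — exactly one phantom per 1/n-width stratum per
dimension. Bounds follow the physiological ranges the generator emulates:
infarct size 5–60% of the LV disc, stiffness within ±30% of its mean
(`stiffness_scale` ∈ [0.7, 1.3]).

The healthy baseline is a uniform end-systolic contraction pattern,
E_CC = −0.15, E_RR = +0.35, E_LL = −0.12 (dimensionless Green–Lagrange
strain). These magnitudes sit in the physiological end-systolic range;
they are configurable constants, not fitted values. The infarct is a
contiguous patch in bullseye coordinates: an angular arc on a set of
adjacent levels, grown from the center by widening the arc first and
adding levels only when a full circle cannot hold the target area. Inside
the patch all strain components are multiplied by an attenuation factor
1/(1 + k·stiffness_scale) with k = 4 — a stiffer scar contracts less — and
a cosine taper over a 15° border zone outside the arc mimics the partially
contracting border myocardium. Additive Gaussian noise (default
σ = 0.01 strain units, small against the baseline magnitudes) models
measurement error. The binary ground-truth mask marks the patch proper,
not the border zone.

The low→high fidelity shift emulates the systematic gap between abundant
simulated data and scarce subject-specific data as a pointwise map
y = 0.85·x + 0.01 + 0.05·tanh(5x) + ε, ε ~ N(0, 0.015²). The linear part
gives the linear correction head something exactly representable; the
bounded tanh distortion gives the nonlinear head an identifiable target.
An all-zero shift is the exact identity.

What the phantoms do **not** emulate: realistic ventricular geometry,
through-wall strain gradients, fiber architecture, multiple or non-convex
scars, imaging artifacts, and inter-subject anatomical variability.
Passing tests therefore demonstrate that the architecture and training
machinery behave as specified under a controlled statistical structure,
not clinical-grade accuracy on measured data.

## Bullseye representation

The bullseye disc maps the apex to a central disc and three annuli
(apical, mid, base) outward, with default ring edges (0, 0.25, 0.5, 0.75, 1)
in radius fractions. The angular mapping is continuous (no 17-segment
discretization). Angle zero sits on the +x axis, increasing
counter-clockwise; this constant is shared by the renderer, the mask
rasterizer and the rotation augmentation, which keeps 90° image rotations
exactly equivariant with 90° rotations of the angular samples.

Each strain component is windowed to [0, 1] with fixed per-component
windows (C: [−0.30, 0.10], R: [−0.10, 0.60], L: [−0.30, 0.10]) rather than
per-image min–max scaling, which would destroy the absolute strain
information the classifier relies on. Pixels outside the inscribed circle
are white (value 1). Normalization divides by 255 when the input is
8-bit-scaled and is the identity on [0, 1] inputs, hence idempotent.
Augmentation appends the 90/180/270° rotations of every image/mask pair —
a fourfold increase — and is applied to training folds only, after
splitting, so no rotated copy of a validation subject leaks into training.

## Segmentation networks

The base UNet follows the classic schedule: four encoder stages of two 3×3
convolutions with ReLU (16, 32, 64, 128 channels), 2×2 max pooling, a
256-channel bottleneck, four decoder stages of 2×2 transposed convolution
+ skip concatenation + two 3×3 convolutions, and a final 1×1 convolution
with sigmoid. Blocks carry biases and no normalization layers; with this
choice the parameter count is exactly 1,941,105 (≈1.94 M), reproducible
from the per-layer closed form Σ(k²·c_in·c_out + c_out). Input resolution
must be divisible by 16 for the default five-entry ladder; a shorter
ladder (e.g. (8, 16, 32)) gives a proportionally cheaper network used at
reduced experimental scales.

The composite multi-fidelity model adds two correction heads on the
concatenation of the input image and the trunk prediction y_L: a plain
10×10 convolution (linear map f_l) and a 10×10 convolution with leaky
ReLU, slope 0.01 (nonlinear map f_nl); their sum passes through a sigmoid
by default so the output compares to binary masks as a probability
(`output_sigmoid=False` disables the squash, in which case heads
calibrated to pass-through reproduce y_L exactly). The 10×10 kernels use
zero padding (4 before, 5 after) to preserve shape. Heads are initialized
as a sharpened identity on y_L — head1 is a delta kernel with gain 8 and
bias −4, so sigmoid(8(y_L − ½)) preserves the trunk's 0.5-threshold
decision, and head2 starts near zero. The composite therefore begins at
the trunk's performance and high-fidelity training can only be asked to
improve it; with random heads the composite would first have to re-learn
the identity from a handful of samples.

Attention, dense and residual-attention variants graft the standard
published mechanisms (additive attention gates on skips; concatenative
dense connections in encoder blocks; residual encoder blocks plus gates)
onto the same channel schedule. Their exact parameter counts depend on
internal choices that published descriptions leave open, so only the
ordering (every variant exceeds the base count) is asserted.

The whole stack — convolutions via im2col + BLAS matrix products,
transposed convolutions, pooling, activations, Adam — is implemented in
numpy with explicit forward/backward passes. Gradients are verified
against central finite differences in float64 (`to_double()`); training
runs in float32.

## Losses and metrics

Binary cross-entropy, soft Dice loss and soft Jaccard (IoU) loss follow
their per-pixel definitions, averaged over the circular region of
interest (ROI) — the LV disc — by default; a `loss_domain="full"` option
preserves the literal all-pixels reading. Probabilities are clipped at
ε = 1e−7 in the cross-entropy; Dice/IoU carry a smoothing constant
δ = 1e−6 in numerator and denominator to avoid 0/0 on empty masks. The
multi-fidelity objective is MSE_L + MSE_H + λΣβ², each MSE term the mean
squared pixel error averaged over that fidelity's samples; λ defaults to
1e−5.

Evaluation thresholds predictions at 0.5 (strict >) and reports accuracy,
precision and recall over ROI pixels, and IoU/DSC on the infarct class
only, so background agreement never inflates overlap. Conventions for
degenerate cases: both masks empty → DSC = IoU = precision = recall = 1;
exactly one empty → 0. Pixels outside the ROI can never change a metric.

## Registration and strain

Registration minimizes Ψ(c, u) (intensity mismatch, correspondence
coupling, displacement-gradient smoothness; weights σᵢ = 1, σₓ = 1,
σ_T = 2 by default, mean-per-pixel norms) with a demons-style alternating
scheme: a correspondence step c = u + s·force, where the force is the
intensity residual times the warped-image gradient normalized by
‖∇‖² + (σᵢ/σₓ)²·residual², followed by Gaussian smoothing of width
σ_T/σₓ to produce u. The step length s is halved until the full cost
decreases, so the cost is non-increasing over accepted iterations by
construction; the loop stops at a relative decrease below 1e−6, at a step
that can no longer descend, or at 200 iterations.

Kinematics: incremental deformation gradients Fᵢ = I + ∂u/∂X use central
differences in the interior and one-sided differences at borders; 2-D
fields embed in 3-D with zero out-of-plane coupling and F[2,2] = 1.
Propagation multiplies increments pointwise with the latest increment
leftmost. E = (FᵀF − I)/2 is symmetric by construction. The local CRL
basis puts the radial unit vector in-plane from slice center to the
point, longitudinal along the long axis, and circumferential = radial ×
longitudinal, making Q proper-orthogonal (det Q = +1) with rows ordered
(C, R, L); the sign of the circumferential axis is a convention.
Recovery tests use band-limited random textures (Gaussian-filtered noise)
because demons forces vanish where the image gradient does; interior
margins of 5 px (translation) and 16 px (affine) exclude boundary effects,
and the affine test compares the interior-mean strain tensor with the
analytic value at σₓ = σ_T = 5, where the smoothing window is wide enough
to suppress noise yet Gaussian smoothing still preserves the affine field.

## Training protocols

Single-fidelity training uses Adam (lr 1e−3), default 100 epochs with
early-stop patience 5, batch size 128, 128×128 images, an 80/20
train/validation split by phantom stratified on infarct-fraction
quartile, and restores the weights of the best validation epoch. All
randomness (sampling, initialization, shuffling, splitting) is routed
through generators seeded from the config seed, so identical seeds
reproduce identical histories to floating-point determinism.

Multi-fidelity training minimizes the composite objective jointly over
trunk and heads: each step accumulates the MSE_L gradient from a
low-fidelity mini-batch and the MSE_H gradient from a high-fidelity
mini-batch (the small high-fidelity set is resampled every step, which
balances the two terms' gradients as the objective's equal weighting
intends when N_L ≫ N_H), plus 2λβ for every convolution weight, before
one Adam update.

Cross-validation plans: leave-one-out, or a rotating k-train/rest-test
scheme in which fold i trains on the k subjects starting at position i
(cyclically) and tests on the remainder, so every subject is tested at
least once and train/test sets are disjoint in every fold.

## The multi-fidelity benefit benchmark

The benchmark quantifies how held-out performance on the shifted
(high-fidelity) domain grows with the number of high-fidelity training
subjects. Scale choices, made once for single-CPU practicality: 64×64
images, 200 low-fidelity phantoms, a compact (8, 16, 32) UNet ladder, 20
held-out shifted test subjects, settings {0, 2, 4} high-fidelity training
subjects (each contributing 4 samples after rotation augmentation — 2
subjects → 8, 4 subjects → 16), and five seeds. The trunk is pre-trained
for 8 epochs on the *same objective as the composite's low-fidelity term*
(pixel MSE) so that joint fine-tuning continues rather than redirects its
optimization; the composite then trains 6 epochs at lr 5e−4. Setting 0 is
the single-fidelity baseline: the trunk evaluated directly on shifted
data. Reported numbers are mean ± sd DSC per setting across seeds, with a
CSV and a summary plot.

Because the phantom task is easy by construction, the single-fidelity
baseline is already strong and the fidelity gap is a few DSC points; the
benefit of added high-fidelity subjects is correspondingly small but
systematic in the seed mean. The benchmark demonstrates the *mechanism* —
correction heads learning a domain shift from very few subjects — not the
magnitude of benefit attainable on real multi-species data.

## Known limitations

* The phantom generator's analytic strain model replaces any mechanical
  simulation; its statistics, not its physics, are the training signal.
* The numpy networks are single-threaded CPU code; large-scale training
  (full 1.94 M-parameter ladder at 128×128 on hundreds of phantoms) is
  out of practical reach, which is why the benchmark uses the compact
  ladder.
* Registration is single-resolution; very large displacements beyond the
  capture range of the image gradient are not recovered.
* Variant architectures are standard re-implementations; their parameter
  counts are not calibrated against any external reference beyond
  exceeding the base UNet.
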