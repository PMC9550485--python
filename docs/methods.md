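# Methods

## The registration model

Given a reference volume F and a moving volume M on the same voxel grid
(affinely pre-aligned, intensity-normalized), the model predicts a dense
displacement vector field (DVF) u: each output voxel i reads the moving
image at i' = i + u(i), with trilinear interpolation over the 8 integer
neighbours of i' weighted by ∏_d (1 − |j_d − i'_d|).  Displacements are in
voxel units and added to the 0-based identity index grid; millimetre-space
fields are out of scope.  Out-of-domain samples are clamped to the border
by default (avoiding artificial zero halos around tissue), with a
zero-fill mode available.  Label maps are resampled with nearest-neighbour
lookup so label identities are never blended.

Training is unsupervised: the network parameters θ minimize

    L_total = α · L_sim(F, M∘φ) + λ · L_smooth(φ)

with α = 1 and λ = 3 by default.

**Similarity.** L_sim = −NCC(F, M∘φ), where NCC is the squared, locally
windowed normalized cross-correlation averaged over voxels — the windowed
form standard in intensity-based registration, which lies in [0, 1] and is
invariant to local affine intensity rescaling.  Window statistics are
moving sums over a cube of edge 9 (configurable, odd), normalized by the
number of in-bounds voxels of each window, so border windows are proper
correlations over their truncated support; a window with no variance
contributes 0 through the ε-stabilized denominator (ε = 1e−5).  The
count-aware normalization matters: with plain zero-padded statistics,
NCC(f, af + b) < 1 at the borders and a constant image shows spurious
border correlation.

**Smoothness.** A diffusion penalty: the squared forward differences of
all three displacement components along all three axes (9 partials per
voxel), averaged over the voxels that have a forward neighbour on each
axis.  A unit-slope ramp (u_x = x) therefore scores exactly 1.  Averaging
rather than summing makes λ independent of grid size; only the α:λ ratio
is identifiable, and the λ = 3 default is expressed in this normalization.

## Architecture

Input is the 2-channel concatenation (F ‖ M).  The stem is a multiscale
Inception block: parallel 3D conv branches with cubic kernels 1/3/5/7,
each producing 4 channels (16 after concatenation); every branch with
kernel > 1 is preceded by a 1×1×1 bottleneck down to 1 channel.  With the
paper-scale configuration (2 input channels, 4 output channels per branch)
the block holds 3968 bias-free weights without bottlenecks and 1994 with
them; the 1×1×1 branch carries no bottleneck — that placement is the only
one reproducing both counts (8 + 110 + 502 + 1374).

The encoder is four levels of (stride-2 3³ conv → stride-1 3³ conv), every
feature conv followed by LeakyReLU (slope 0.2); after four levels the grid
is 1/16 of the input, so input dimensions must be divisible by 16.  The
decoder is four levels of (×2 trilinear upsample → channel concat with the
same-resolution encoder map → 3³ conv + LeakyReLU).  Channel widths
default to enc = [16, 32, 32, 32], dec = [32, 32, 32, 16]; the description
this implementation follows leaves them open, and these defaults keep the
model trainable on a single CPU.

**Hierarchical forecast.**  The three coarsest decoder maps are upsampled
to full resolution (factors 8, 4, 2, trilinear), convolved to 3 channels
(φ_low, φ_mid, φ_high), channel-concatenated with the end-of-decoder
prediction φ_end, and reduced by a 1×1×1 conv to the fused output φ_final.
The loss is applied to φ_final only; the intermediate fields act through
the fusion, not through auxiliary loss terms.  Ablation flags remove the
Inception stem (replaced by one plain 3³ conv with matching channels)
and/or the forecast structure (φ_final ≡ φ_end).

**Initialization.**  Feature convs use He-style normal init adjusted for
the LeakyReLU slope.  All field-producing convs (the three heads and the
end conv) are zero-initialized, so the untrained network is exactly the
identity transform — this stabilizes early training.  The fusion conv is
initialized to average the four candidate fields rather than zeroed:
if both the field convs and the fusion were zero, every head gradient
would vanish identically at the first step (each is a product of the
other's weights), whereas the averaging fusion passes gradient 1/4 to
each head while still yielding φ_final ≡ 0 at initialization.

## Training

ADAM (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), batch size 1, one step per image
pair per epoch, pair order shuffled with the run seed.  Default protocol:
70 epochs, lr 1e−4 halved at the start of epoch 40 (with 625 training
pairs this is 43 750 steps).  Runs are fully reproducible given the seed;
a non-finite loss raises immediately.  Optional gradient-norm clipping is
off by default.

The compute core is a small tape-based reverse-mode autodiff engine on
numpy arrays (`mhnet.autodiff`): 3D convolution implemented as one GEMM
per kernel offset (peak memory one channel-slice copy rather than a full
im2col buffer), separable trilinear upsampling with half-pixel centres,
the spatial-transformer gather with gradients in both the image and the
field, and cumulative-sum box filters for the windowed NCC statistics.
Everything runs in float32 end to end; gradient correctness is verified
against central finite differences in the test suite.

## Dataset augmentation

A training set of N volumes is expanded by cross-registering every
ordered pair of distinct originals and keeping the warped moving image:
N(N−1) new images, N² total (25 originals → 600 new → 625).  The
registration backend is pluggable: the default is a self-contained
iterative optimizer that minimizes the same α·NCC + λ·diffusion objective
directly over a free displacement field per pair (ADAM, default 100
iterations, lr 0.5); a trained network or an external command template
(e.g. an ANTs quick-SyN call) can be substituted.  Failed tasks are
recorded and skipped, and the manifest stores (reference, moving, backend,
seed) per new image.  The fixed reference image used at training time is
not part of the augmentation pairs.

## Evaluation

Dice(S_f, S_w) = 2|S_f ∩ S_w| / (|S_f| + |S_w|) per label after warping
the moving label map, with conventions chosen to keep the metric total:
both sets empty scores 1 (vacuous agreement), exactly one empty scores 0.
Left/right hemisphere label pairs can be merged into one structure score
by arithmetic mean; the summary is the unweighted mean over evaluated
labels (volume-weighted averaging is deliberately not offered).

## Synthetic data

The generator produces desk-scale stand-ins for labelled brain anatomy:
label 1 is a large soft-edged ellipsoid (the organ outline) and labels
2..n are compact ellipsoidal blobs a few voxels across scattered inside
it, so their Dice is sensitive to voxel-scale misalignment — under the
default deformation the pre-registration foreground Dice is ≈ 0.65,
comparable to the affine-only baseline reported for real brain data.
Intensity is a per-structure level plus smooth random texture (sd 0.08,
correlation ≈ 1.5 voxels) that gives every window local contrast for NCC,
blurred by σ = 0.8.  Ground-truth deformations are Gaussian-smoothed white
noise vector fields: `deform_smoothness` is a FWHM-like correlation length
(kernel σ is half of it), smoothing is periodic so the field is
statistically stationary across the volume, and the field is rescaled so
its maximum displacement magnitude equals `deform_amplitude` (default 3
voxels, smoothness 8).  Moving images are the warped fixed images plus
additive Gaussian noise (sd 0.01 on [0, 1] intensities).

What the phantoms do not emulate: MRI physics (bias fields, modality
contrast, partial volume), anatomical shape statistics, and large or
discontinuous deformations.  Tests passing on phantoms therefore
demonstrate that the mechanics — warping, objective, optimization,
evaluation — behave as specified, not that the defaults are optimal for
any particular imaging study.

## Desk-scale training study

The test suite includes an end-to-end recovery study at 32³ on 8 phantom
pairs (amplitude 3, smoothness 8, fixed seed): the full model and the
"plain encoder-decoder" ablation are each trained and the mean foreground
Dice before and after registration is compared.  At this problem size the
published protocol's step count is not meaningful (43 750 steps at
lr 1e−4), so the study trains for 40 epochs (320 steps) at lr 1e−3,
halved mid-run — the same schedule shape at a step size matched to the
much shorter run.  Problem sizes throughout the suite (6³–10³ for oracle
comparisons, 16³ for structural network tests, 32³ for the recovery
study) are chosen so the whole suite runs on one CPU core in minutes.

## Numerical choices and edge cases

- Min-max intensity normalization per volume (constant volumes map to
  zeros); z-score available.  Per-volume rather than dataset statistics.
- Centered crop with floor on the left margin.
- Volumes are used in stored array index space; no reorientation is
  performed.  Inputs are assumed pre-aligned.
- Interpolation weights at exactly-integer sample locations put weight 1
  on the hit voxel; clamp-mode gradients with respect to the field are
  zeroed where the sample coordinate was clipped outside the domain.
- The DVF is written as 4D NIfTI with last dimension 3, voxel units.

## Known limitations

- No diffeomorphic guarantee: the predicted field can fold locally;
  inverse-consistency constraints are out of scope.
- CPU-only: practical at desk scale (≤ 64³); full-resolution brain volumes
  (160×192×160) would need hours per epoch in this implementation.
- Batch size is fixed at 1 (matching the training protocol); there is no
  multi-device or mixed-precision path.
- The NCC window edge and channel widths interact with image scale;
  defaults target 32³–64³ synthetic volumes.
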