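# Methods

## Model

NTSM is a 2-D encoder–decoder segmentation network for non-salient
(camouflaged) lesions.  The backbone is pinned for reproducibility: each
stage holds two 3×3 convolution blocks (instance normalization + LeakyReLU
0.01), stages 2..n open with a stride-2 convolution, the decoder mirrors the
encoder with kernel-2 stride-2 transposed convolutions and skip
concatenation, and supervision heads are 1×1 convolutions to two classes
(softmax).  Inputs must be divisible by 2^(stages−1).  Default widths are
(32, 64, 128, 256, 512).

Instance normalization is used in the backbone blocks because the training
protocol works at batch size 4, where batch statistics are noisy; batch
normalization is retained inside LFE and the LSA branches, where the design
of those submodules specifies it.  Batch size 1 is rejected in training.

### Difference-association (DA) module

DA processes the raw RGB image at full resolution and its output is
concatenated with the stem features and reduced by a 1×1 convolution — the
wiring that lets the learned difference maps modulate, rather than replace,
the stem.  The first convolutions inside LCD project 3 input channels to the
stage-1 width, reconciling channel counts.

*LCE contrast*: `LeakyReLU(InstanceNorm(F_local − F_context))` with no
affine terms, eps 1e-5, slope 0.01.  Instance normalization removes the
per-slice mean, so a spatially uniform difference is nulled — only spatial
*structure* of the local-vs-context difference survives.  It also couples
all pixels weakly through the slice statistics; the locality test therefore
checks that far-field responses are ≥20× below near-field ones rather than
exactly zero.

*LCD*: two LCE units (context dilations 4 and 8; local dilation 1), each
branch a dilated 3×3 convolution followed by LFE gating.  The two contrast
maps are fused by channel concatenation + 1×1 convolution (a `sum` variant
is exposed in `DAConfig.lce_fusion`); concatenation was chosen because it
preserves the two dilation scales' information separately.

*LFE*: coordinate-attention-style gating.  The input is average-pooled along
each spatial axis; the (b,C,h,1) strip and the transposed (b,C,w,1) strip
are stacked along the third axis, embedded by a shared 1×1 convolution +
batch norm + swish with bottleneck width `max(C/8, 4)` (the conventional
coordinate-attention ratio; exposed in the constructor), split at index h,
and turned into per-axis sigmoid gates by separate 1×1 convolutions.

*LSA*: four branches — (1) 1×1+BN; (2) 1×1 → 7×7 → 3×3 dilated 7;
(3, 4) 1×1 → 7×7 → 7×7 → 3×3 dilated 7 with independent weights — BN after
every convolution, GeLU (exact Gaussian-CDF form) after all but the last.
All branch convolutions preserve the channel count, so the concatenation has
4C channels and the fusing 3×3 (dilation 7) convolution maps 4C → C.  The
1×1 shortcut is applied to the LSA *input* (the residual reading; the only
one that type-checks against the addition).  Padding always equals
dilation × (kernel−1)/2, forced by extent preservation.

### Hadamard-product attention and FHPA

HPA stores a learnable tensor `p` of shape (depth, 16, 16) by default
(truncated normal, std 0.02, seeded; both exposed in `HPAParams`), resizes
it bilinearly (align-corners; the nominal grid must be ≥2 per axis) to the
input's trailing extents at every call, sharpens it with a per-slice 3×3
depthwise convolution, and multiplies elementwise.  The gate is independent
of the batch, so HPA is exactly linear in its input.

FHPA group-normalizes (4 groups by default), chunks the channels into four
equal groups, and attends to groups 1–3 along the height–width,
channel–height and channel–width axis pairs.  For the channel–height (zx)
axis the width dimension is moved to a batch-like leading position and a
single-slice gate over (group-channel, height) is broadcast across it;
channel–width mirrors this.  This convention keeps the parameter count
independent of the input size, which a per-width-slice filter bank would
violate.  Group 4 passes through 1×1 conv → GeLU → 3×3 depthwise; the
concatenated result is group-normalized and re-fused by 3×3 depthwise →
GeLU → 1×1 conv.  No residual connection is added around the block — the
fusion equations define none, and the substitution site (second conv of a
stage) already sits inside the backbone's plain feed-forward path.

Parameter economy: only the two 1×1 convolutions are dense in C
(`C²/16 + C²` scalars), against `9C²` for the replaced convolution, so the
block wins for C ≥ 16 with the default 16×16 grids (closed form in
`fhpa_param_count`, checked against enumeration).  At C = 8 and below the
p-tensors dominate and the block is *larger* than the conv it replaces —
which is why the desk-scale test configuration substitutes FHPA only at the
16- and 32-wide stages and why the ablation-ordering checks run on the
default widths.

## Loss

`L = Σᵢ λᵢ (BCE + k · DiceLoss)` per supervision level, finest first.
λ defaults to (1, ½, ¼)/1.75 (halving per scale, normalized to sum 1) and
k = 1; both exposed.  BCE is the per-pixel mean binary cross-entropy of the
softmax foreground probability (clipped at 1e-7 for stability); the Dice
loss is `1 − (2Σpy + s)/(Σp + Σy + s)` with smoothing s = 1e-5 — the soft
counterpart of `2TP/(FP + 2TP + FN)`.  Probabilities (not logits) keep the
two terms on comparable scales.  Targets are downsampled nearest-neighbor
(binarity-preserving) to each level.

## Metrics

Sen, Spe and Dice come from exact integer confusion counts; zero
denominators are reported as missing (`None`) and excluded from dataset
means with exclusion counts logged, never silently NaN.  95HD treats the two
masks' foreground pixel sets (row-major, 0-based, pixel-center coordinates)
as point sets, computes each directed nearest-neighbour distance multiset
via the exact Euclidean distance transform, takes the linear-interpolated
95th percentile of each, and combines by maximum; `percentile=100` recovers
the exact Hausdorff distance.  Distances are in pixels (photographs carry no
physical spacing).

Efficiency: parameters are summed learnable scalars; FLOPs are counted as
2 × multiply-accumulates of one eval-mode forward at a stated input size by
a counter inside the tensor ops (hardware-independent; the "per second"
reading of FLOPs is deliberately not implemented); memory is the serialized
checkpoint size in bytes.

## Numpy autodiff core

No deep-learning framework is used: `ntsm.autodiff` implements reverse-mode
differentiation over numpy arrays for the ~20 operations the model needs
(im2col convolution with dilation/groups, 2×2 transposed convolution,
matrix-based bilinear resizing, norms composed from primitives,
activations, slicing/concatenation).  All gradients are verified against
central finite differences in the test suite.  The default compute dtype is
float32 (keeping im2col workspaces small on CPU); modules can be cast to
float64 (`Module.astype`) — the oracle-agreement tests do this to make the
1e-5 comparisons meaningful.  Training is exactly reproducible: parameter
initialization draws from a single seeded generator in construction order,
and sampling uses its own seeded generator.

## Training protocol

SGD with Nesterov momentum 0.99, polynomial decay `lr·(1−t/T)^0.9`, weight
decay 3e-5, batch size 4, initial lr 0.001, 250 iterations × 300 epochs, and
five-fold cross-validation (deterministic shuffled near-equal split; 812 ids
split 163/163/162/162/162) are the defaults.  Class imbalance is countered
by forced-foreground sampling: each batch slot draws from the
lesion-containing pool with probability 0.33, otherwise from the
background-only pool (falling back to the whole set when a pool is empty).
The optimizer family is a config choice (the protocol specifies only lr and
weight decay); Nesterov-momentum SGD with polynomial decay is the standard
recipe for this backbone family.

Desk-scale checks use a reduced schedule of their own: the 300-step overfit
capacity test runs at lr 0.01 (a 300-step schedule needs a larger step size
than the 75 000-step full protocol; the threshold Dice > 0.90 is unchanged),
on widths (8, 16, 32) and 64×64 images.  The non-salience dial trains the
same tiny model for 150 steps on twelve 48×48 images at contrast 0.5 and
evaluates held-out sets at contrast 0.5/0.2/0.05; these sizes keep the whole
suite within desk-scale CPU budgets while leaving the effects being tested
(capacity, contrast sensitivity) far from their thresholds.

## Synthetic data

The generator emulates the regime that defines the application: lesions
statistically similar to their surroundings plus salient distractors.
Background: Gaussian-blurred white noise (correlation length
`texture_scale`, default 12 px; amplitude 18 intensity levels) on a reddish
tissue palette (mean ≈ (150, 92, 88)) with a ±10-level illumination ramp.
Lesions: ellipses radially perturbed by random Fourier harmonics (orders
2–5), rescaled so the enclosed area hits a target fraction sampled inside
`lesion_area_frac`, rasterized and re-tried until the pixel area lies within
the configured bounds; the interior mean is shifted by `contrast_delta`·255
on all channels and its texture field is independently re-phased, so
`contrast_delta = 0` leaves a pure texture-phase camouflage.  Distractors:
bright tooth-like ellipses (≈(238, 234, 222)) drawn only where the mask is
zero.  Default `contrast_delta` is 0.2 — visibly non-salient but learnable.
Everything is determined by `(seed, index)` and PNG output is byte-stable.

What the generator does *not* model: real anatomy, specular highlights,
JPEG artifacts, color casts between cameras, and lesion-boundary diffusion.
Passing tests therefore demonstrate that the architecture, losses, metrics
and pipeline behave correctly and that the model can exploit low-contrast
cues — not that clinical-grade accuracy transfers to real photographs.

## Degenerate inputs and numerical choices

Normalization eps is 1e-5 everywhere; BCE probability clip 1e-7; Dice
smoothing 1e-5.  Empty masks or zero-denominator metrics → flagged missing.
Non-binary masks are rejected with the offending values named.  NaN losses
abort training with a diagnostic rather than continuing.  Bilinear resizing
of a 1-extent axis broadcasts the single sample.  Checkpoints (npz weights +
YAML config) round-trip bit-exactly.

## Known limitations

* The backbone is pinned rather than auto-configured, so absolute
  parameter/FLOP figures are specific to this configuration; only the
  *orderings* (FHPA cheaper than dense convolution at wide stages, more
  substitutions → fewer parameters) are meaningful claims.
* CPU-only numpy training is practical at desk scale (minutes), not at
  clinical scale.
* Single foreground class; 2-D only; no test-time augmentation.
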