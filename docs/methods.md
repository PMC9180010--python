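# Methods

## Model

MVDNet is a U-shaped encoder–decoder for ten-class segmentation of
endoscopic neurosurgical scenes. The encoder reduces resolution three
times (stride-2 3×3 convolutions to 1/2, 1/4, 1/8) and extracts context
with three blocks of Light Asymmetric Bottleneck (LAB) modules; the
decoder restores resolution with three Feature Fusion Modules (FFM), a
1×1 classifier and a final 2× bilinear interpolation. Default
configuration: stage channels 32/64/128, block depths (n, m, l) =
(2, 4, 4), dilation rates 2/4/8, ten classes; 716,074 trainable
parameters (0.72 M).

### LAB module

Channel-halving 1×1 convolution, 3×1 then 1×3 *depthwise dilated*
convolutions (a rank-1 factorization of a 3×3 kernel), channel-restoring
1×1 pointwise convolution, residual addition. The pre-activation scheme
places BN + PReLU before each convolution; the final pointwise
convolution has neither a pre-activation nor a trailing nonlinearity.
Consequences for parameter bookkeeping, applied consistently everywhere:
a convolution whose output feeds a BN carries no bias; the 1×3 depthwise
convolution (which feeds the pointwise convolution directly) and the
pointwise convolution itself carry biases.

Dilated taps use symmetric zero padding equal to the dilation rate, so
resolution is preserved at every block and small feature maps are legal
(taps beyond the border read zeros). A LAB module rejects inputs
smaller than 3×3 — below the nominal kernel extent no spatial context
exists at all.

### Stage-boundary fusion

At the end of every encoder stage the block input, the block output and
an average-pooled copy of the RGB input (kernel = stride = 2, applied
1×/2×/3×) are concatenated, giving c + c + 3 channels. After stages 1
and 2 this concatenation feeds the stride-2 downsampler; after stage 3
it is the high-level input of the first FFM (259 channels into its 3×3
convolution). Treating the third boundary exactly like the first two is
the design choice that makes the long-range image shortcut reach every
block and brings the parameter audit to 0.72 M; routing only the bare
block output into the decoder would leave the stage-3 concatenation
without a consumer and audit ~0.16 M short. Both concatenation sources
are independently togglable (`use_block_concat`, `use_image_injection`)
for the ablations, as is the whole FFM decoder (`use_ffm`: classifier
at 1/8 resolution + 8× bilinear upsampling) and the channel-pooling
step inside the FFM (`ffm_channel_pool`).

### FFM

The low-level branch applies 1×1 convolution and BN, averages across
channels to one map, and passes a sigmoid, giving a spatial attention
map strictly inside (0, 1). The high-level branch is 2× bilinearly
upsampled (in the second and third FFM only; the first operates at the
same scale) and passes one shared 3×3 convolution whose output is used
both in the gated product and the additive skip:
`PReLU(BN(A ⊗ H' + H'))`. The output takes the low-level branch's
channel count and spatial size.

## Numerical conventions

* BN: eps 1e-3, running-statistics momentum 0.1 (biased variance for
  normalization, unbiased for the running estimate), affine.
* PReLU: one learnable slope per channel, initialized at 0.25.
* Weight init: Kaiming normal with the PReLU gain for convolutions
  (fan-in), BN weight 1 / bias 0, biases 0; seeded, so builds are
  reproducible.
* Bilinear interpolation uses half-pixel centers; its backward pass is
  the exact adjoint.
* FLOPs are counted as 2 per multiply-accumulate, plus documented
  elementwise costs (BN 2/elem, PReLU 2/elem, sigmoid 4/elem,
  add/mul/pool 1/elem, bilinear 7/output elem). No standard convention
  exists, so FLOP figures are reported for comparison between
  configurations of *this* audit only.
* The profiler computes parameters/FLOPs/traces/receptive fields in
  closed form from the declarative spec, never from weight containers;
  the test suite holds it equal to the built network's enumeration
  across depths and every ablation toggle.
* The parameter report also provides a convolution-only vs
  norm/activation breakdown (709,098 + 6,976), since published
  megacounts do not always state whether BN/PReLU parameters are
  included; at two decimals the total rounds to 0.72 M with them and
  0.71 M without.

## Training protocol

Mini-batch SGD: batch 8, momentum 0.9, weight decay 1e-4 (applied to
all parameters), poly learning rate `0.16 · (1 − step/total)^0.9`
stepped per iteration, 100 epochs, plain mean pixel cross-entropy, no
class weighting and no ignore label — every pixel is scored.
Augmentation: joint horizontal flip (p = 0.5), image-only Gaussian blur
(p = 0.5, σ ∈ [0.15, 1.15]), per-channel standardization with
statistics computed over the training split at corpus build time, joint
random 512×512 crop (images smaller than the crop are reflect-padded;
masks are never interpolated). Validation runs at full resolution with
no cropping or multi-scale tricks. mIoU averages all classes with a
nonempty union, background included by default; a foreground-only mode
exists because stratified accuracy tables in this domain list only the
nine foreground classes, leaving background's inclusion ambiguous.

One master seed fans out (via named substreams) to data order and the
augmentation stream per epoch; checkpoints embed the architecture spec,
optimizer momentum, BN running statistics and the loss log, so a run
interrupted at an epoch boundary resumes bit-identically — the suite
asserts this.

## Synthetic scenes

The generator emulates the *label structure* of the surgical corpus,
not its appearance: 768×576 canvases (any size is configurable), up to
seven structures per scene (at least one) drawn as cubic-spline tubes — nerves as broader
pale bands, vessels as narrower red/purple tubes — over a low-frequency
tissue background, with specular highlight blobs, Gaussian noise and
mild blur. Wherever a vessel tube crosses the facial-nerve band the
mask takes the corresponding composite class; vessels are routed
through a waypoint on the partner nerve's centerline, so composites
genuinely occur. Per-scene metadata (age group, gender) is sampled with
the proportions of the stratified test split (107/117/84 by age,
124/184 by gender). Everything derives from a single per-scene seed;
corpora built from the same master seed are file-for-file identical.

Geometry priors: tube width uniform in 9–17% of the canvas' short side
(nerve bands 1.25× wider), so structures survive the encoder's 1/8
downsampling even on small canvases. Appearance: per-class base colors
with small per-structure jitter, composites blended 0.65 vessel / 0.35
nerve.

What passing on this data shows: that the architecture, loss, optimizer
and evaluation machinery learn thin elongated multi-class structures
with composite overlaps end to end. What it does not show: performance
on real MVD imagery, whose classes are far less color-separable, whose
lighting and occlusion are harsher, and whose metadata correlates with
anatomy rather than being sampled.

## Desk-scale problem sizes

The default test fixture is a 24-scene 128×128 corpus (16/4/4 split).
The learning-capability check trains the default architecture on it for
40 epochs with the standard recipe, using full 128×128 scenes per batch
rather than sub-crops, and evaluates the 8 held-out scenes at full
resolution (mIoU ≥ 0.5, strictly decreasing loss over the first five
epochs). Training on 64×64 sub-crops was rejected deliberately: with
dilation-8 modules operating on 8×8 stage-3 maps, every dilated tap
reads padding at training scale but real neighbors at evaluation scale,
and the resulting train/eval activation shift caps held-out mIoU near
0.13. Crop-based training is appropriate only when the crop is large
relative to the encoder's receptive scale, as in the full 512-crop
protocol.

## Known limitations

* CPU NumPy execution: single-image 768×576 inference takes seconds,
  so the FPS harness measures *relative* cost only; published
  real-time figures require GPU execution and are out of scope.
* The factorized depthwise pair is mathematically a rank-1 3×3 kernel
  only when the intervening BN/PReLU are identities (the equivalence
  the tests verify in that configuration); in the trained network the
  interleaved nonlinearities make it strictly more expressive per the
  architecture's design.
* No distributed training, mixed precision, test-time augmentation, or
  pretrained weights.
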