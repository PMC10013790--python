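# Methods

This note documents the models, procedures and numerical choices behind
`wheatseg`, and what the fixture-scale experiments do and do not establish.

## Problem setting and data model

The target task is binary semantic segmentation of wheat heads (spikes) in
RGB field images under severe annotation scarcity: one annotated frame to
synthesize training data (w_t), one for validation data (w_v), and a short
video clip whose remaining frames are unannotated. Frames of a clip are
partitioned five ways — w_t, w_v, an annotated test set, a small validation
set, and the unlabeled remainder used for pseudo-labeling. Test and
validation frames must lie more than one second away from w_t and w_v in
clip time; we interpret "one second" as a frame-index distance of
round(fps), with strict inequality, so a frame exactly fps+1 indices away is
eligible. The same window is applied to the validation set, which is the
conservative reading; w_t and w_v themselves are excluded from every other
part so the two annotated frames can never leak into evaluation or
pseudo-label pools. Frames keep their original clip indices across striding
so the exclusion window always operates in clip time.

## Cut-and-paste synthesis

Real cutouts are head instances cropped to their tight bounding box, with
the instance footprint kept as an alpha channel (patches retain background
pixels outside the footprint; only footprint pixels are pasted). When
instances are not given, 8-connected components of the semantic mask define
them. Fake cutouts reuse the real footprints as cookie cutters over
head-free pixels; placement is seeded rejection sampling over uniform
positions with a default budget of 1000 attempts per template, and a
placement is valid only if its translated footprint intersects the head
union in zero pixels (asserted exactly in tests).

Composites paste fakes first, then reals (painter's order). Because all
fakes precede all reals, the ground-truth mask reduces to the union of the
pasted real footprints clipped to the canvas; an occluding real head removes
exactly the hidden pixels from the occluded head's contribution without
changing the union. The per-composite head counts are two independent
uniform draws from {10..100} for fakes and reals — the text we follow reads
as one rule applied to both, and independent draws are the simplest
consistent choice. Placements whose footprint crosses the canvas border are
clipped rather than rejected, since real field images contain truncated
heads at their borders.

Geometric augmentation (applied identically to patch and footprint before
pasting): horizontal/vertical flips with probability 0.5 each, rotation
uniform in [-180°, 180°], scale uniform in [0.5, 1.5], and elastic
deformation (Gaussian-smoothed displacement field, amplitude 1.5 px,
smoothness σ = 3 px, probability 0.3). Footprints are interpolated
bilinearly and re-binarized at 0.5; a transform that empties the footprint
is resampled, up to 10 times. Color augmentation — brightness/contrast
jitter, hue/saturation jitter, occasional blur and Gaussian noise — is
applied only to the finished composite, never to the mask, so the label
remains computationally inferable. The exact augmentation ranges are
package defaults; only the transform families are prescribed by the
protocol.

## Network and loss

The segmentation network is a compact numpy U-Net with hand-written
backpropagation: per encoder level two 3×3 same-padded convolutions with
ReLU followed by 2×2 max pooling, a two-convolution bottleneck, and a
decoder with nearest-neighbour upsampling, skip concatenation and one
convolution per level, closed by a 1×1 convolution producing one logit per
pixel. Two presets exist: `tiny` (widths 8/16, bottleneck 32, ~27k
parameters, stride 4) for tests and fixture-scale studies, and `base`
(widths 16/32/64, bottleneck 128, ~440k parameters, stride 8). Inputs must
be divisible by the stride; the estimator zero-pads and crops
transparently. Convolutions are computed by im2col plus a single matrix
product, and the input gradient by the transposed convolution of the output
gradient with spatially flipped kernels — verified against central finite
differences through the whole network (relative error ~1e-8 in float64).
Weights are He-initialized from a seeded generator. No pretrained weights
are bundled; `pretrained_init` is rejected with a clear error, and all
reported experiments start from seeded random initialization.

The loss is the batch mean over images of (smoothed Dice loss + mean binary
cross-entropy), with ε = 1e-5 inside the Dice ratio and probabilities
clamped to [1e-7, 1 − 1e-7] inside the logarithms (the loss is undefined at
p ∈ {0, 1}); the analytic gradient uses the unclamped (p − g) BCE term. The
optimizer is SGD with learning rate 0.01 (the protocol's setting) and
momentum 0.9 — the protocol names plain "SGD", momentum being our default as
standard CNN practice and exposed as a parameter. Model selection at every
stage keeps the epoch with the smallest validation loss.

## Domain adaptation

Step I (model D) fine-tunes model S on all 360 integer-degree rotations
(0..359) of w_t, validating on the rotations of w_v. Rotated canvases are
expanded to contain the full frame (zero fill for image and mask) rather
than cropped, preserving every head pixel; degree 0 is the original image
and right-angle rotations are computed exactly with array transposition,
other angles bilinearly (image) and nearest-neighbour (mask). Training
records are flagged for strong online augmentation: each access re-applies
label-preserving geometric transforms (flips, right-angle rotations, applied
to image and mask together) plus photometric jitter (image only). Off-square
canvases restrict the right angles to half-turns so batch shapes stay
uniform.

Step II (model P) predicts masks for the unlabeled frames with model D and
fine-tunes on the resulting hard, 0.5-thresholded pseudo-labels, with the
held-back validation frames pseudo-labeled the same way for the epoch
selection (they carry no manual masks by design). No confidence weighting is
applied — the protocol prescribes prediction followed by fine-tuning,
nothing more.

Step III (model G) fine-tunes model P on the externally annotated frames
plus w_t/w_v, each expanded with rotations: "all 359 rotations" plus the
original is harmonized with Step I's "360 rotations (0 to 359°)" by treating
0° as the original, so both steps emit 360 records per frame. Online strong
augmentation defaults to off for stages P and G (it is prescribed explicitly
only for Step I) and is exposed as a flag. The Baseline uses the Step III
data alone, trained from scratch with the same hyperparameters.

During training, all images of a stage (train and validation) are zero-padded
to one common divisor-aligned canvas so rotation-expanded sets, whose sizes
depend on the angle, batch uniformly.

## Metrics and test-time augmentation

Dice and IoU are computed per image and macro-averaged over images (and per
domain); the protocol reports set-level scores without stating the pooling,
and macro-averaging weights every image equally. When both masks are empty
the pair scores 1 in both metrics (the 0/0 case is read as perfect
agreement). Binarization uses p ≥ threshold with threshold 0.5. TTA
predicts on the original image, a Gaussian-noise variant (σ = 0.05 on the
[0, 1] scale, seeded) and a Sepia variant (the standard fixed 3×3
color-mixing matrix, clipped); both variants are photometric, so the three
binarized predictions align pixelwise and are combined by per-pixel
majority vote — three voters, hence no ties.

## The field simulator

`fieldsim` emulates the study inputs at desk scale: backgrounds are
two-tone low-frequency noise fields with fine speckle around a configurable
palette; heads are textured ellipses (6–14 px axes by default) with a
sinusoidal spikelet pattern and a few awn strokes painted on the image but
excluded from the mask, mirroring the annotation convention that awns are
not part of the head region. Clips are windows drifting across a larger
latent scene, so consecutive frames are temporally coherent and every
frame's mask is exact by construction — fixture ground truth has zero
annotation noise. The simulator does not attempt photorealism, illumination
or growth-stage variation, motion blur, or camera perspective; consequently,
passing fixture-scale experiments demonstrates that the pipeline's machinery
(synthesis, annotation bookkeeping, staged training, selection, TTA,
reporting) is correct and that the staged protocol helps under a controlled
appearance shift — it does not predict absolute accuracy on real wheat
imagery.

## Fixture study problem sizes

The end-to-end study runs on 96×96 canvases: a 60-frame clip (fps 10, drift
1 px/frame), 4 background frames from a shifted palette (a deliberate
appearance gap between composites and clip frames), 300 training and 30
validation composites (keeping the protocol's 10:1 ratio of the
10,000/1,000 design), batch size 8, learning rate 0.01, and stage epochs
S=10, D=3, P=3, G=2, baseline=2. Validation of rotation-expanded stages is
subsampled to 60 images per epoch (`max_val_images`) to keep per-epoch
validation proportionate. The S-versus-D contrast repeated over ten seeds
uses a lighter variant (48×48 canvases, 48 composites, 5–25 heads, S 4
epochs, D 1 epoch) so the repetition stays cheap; these sizes are the
package's fixture-scale defaults, chosen to keep a full run in the
ten-minute range on a single CPU.

At this scale the Baseline can score close to model G: the simulated
"external" frames come from the same generative family as the clip, so
training on them from scratch is easier than in real studies, where the
baseline suffers from cross-domain diversity that the simulator does not
model. The monotone S → D → G improvement on held-out clip frames, and the
D ≥ S ordering across seeds, are the properties the fixture study is
designed to exercise.

## Known limitations

- The encoder is a generic compact CNN, not the large pretrained backbone a
  production deployment would use; absolute scores at fixture scale do not
  transfer to real imagery.
- Pseudo-label quality is bounded by model D; no confidence filtering is
  applied, so a poor D can propagate errors to P (visible in some seeds as a
  flat P-over-D gain).
- Geometric TTA (with inverse warping) and pooled-pixel metric variants are
  deliberately out of scope.
- Video container decoding depends on the available imageio plugins;
  directories of extracted frames are the portable input path.
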