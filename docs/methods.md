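# Methods

## Scope and engine

The package implements the bespoke components of a lightweight
single-stage rice-disease detector and the scaffolding needed to exercise
them — assembly, complexity accounting, synthetic data, training and
evaluation — at desk scale on one CPU. All neural computation runs on a
package-internal reverse-mode automatic-differentiation engine over NumPy
arrays (`rdblocks.autograd`): a tape of closures per operation, float32
throughout, with grouped/dilated 2-D convolution via loop-over-taps
im2col/col2im (column buffers are recomputed in the backward pass rather
than stored, which bounds peak memory), max/average/adaptive pooling,
batch and group normalisation, and the usual pointwise/reduction ops.
Gradients of every primitive are tested against central finite
differences.

## The blocks

**LSKAC.** The attention chain is, in order: a 1×(2d−1) and a (2d−1)×1
depth-wise convolution (the separable local pair), one ⌊k/d⌋×⌊k/d⌋
depth-wise convolution with dilation d (the remote-context stage), and a
1×1 channel-mixing convolution; the resulting map multiplies the input
element-wise. There is no nonlinearity inside the chain, all convolutions
are bias-free and same-padded (even effective kernels get the odd pixel on
the bottom/right), so the structural weight count equals the closed form
`(2d−1)·C·2 + ⌊k/d⌋²·C + C²` exactly and FLOPs are that count times H·W.
The floor in ⌊k/d⌋ is a deliberate rounding rule. Defaults k = 23, d = 3,
a standard large-kernel decomposition setting. The companion `lska`
formula replaces the separable pair's cost with a dense (2d−1)² local
kernel.

**SPPFLKC.** The published description names the ingredients (LSKAC,
MaxPool2d, AvgPool2d, self-attention, Concat) but not the wiring; the
reference wiring here keeps the SPPF skeleton — 1×1 reduction to C/2,
three serial stride-1 max-pools (kernel 5, −∞ padding), concat — and adds
the LSKAC gate after the reduction, a parallel stride-1 average-pool
branch (padded cells excluded from the mean), and a single-head channel
self-attention before the 1×1 output projection. The self-attention
treats channels as tokens whose feature is the global-average descriptor,
with scalar query/key/value projections and a sigmoid gate — deliberately
near-parameter-free so the block's cost stays in the convolutions.

**CAFormer + CGLU (C3k2-CFCGLU).** The gate derives a per-channel weight
from group normalisation: W_γ = γ/Σγ, multiplied by the channel's spatial
mean response of the normalised map and squashed by a sigmoid; a fixed
threshold t (default 0.5) splits the weights into informative (w ≥ t) and
non-informative (w < t) parts. Gating is soft — the masks select which
continuous gate value applies — preserving differentiability. The
informative weights scale a refined branch (1×1 reduction, 3×3 depth-wise,
1×1 point-wise — a plain depth-wise pair; no deformable sampling offsets,
which the source design names but never specifies), the non-informative
weights scale the identity branch, and the two maps are cross-reconstructed
by swapping contiguous channel halves and concatenating. Group count for
the normalisation is the largest of {16, 8, 4, 2} dividing C with at least
two channels per group (a single-channel group would normalise to zero
mean and pin its gate at sigmoid(0)). The CGLU compresses with a 1×1
conv, splits channels α : β : rest (defaults 0.5/0.25/0.25), runs the
upper segment through parallel group-wise (g = 2) and point-wise 3×3/1×1
convolutions, the lower through a 3×3 depth-wise separable convolution
with GELU, gates both by a linear fusion of their pooled descriptors, and
projects the re-concatenated segments to the output width. Inside C3k2,
the first two bottleneck units are replaced by CAFormer then CGLU; the
cross-stage-partial wiring (split, stacked units, fused 1×1) is untouched.
The working width of every C3k2 variant is rounded to an even number so
the reconstruction halves exist at any scale.

**CSCBAM (C3k2-CSCBAM).** Compression: spatial max and average pooling
produce two length-C descriptors, fused by a shared two-layer MLP
(reduction 16, hidden at least 4) and added; channel max and average
pooling produce two H×W maps, stacked and fused by a 7×7 convolution — a
per-position MLP on a one-channel map would degenerate to a scalar scale,
so the convolutional fusion is used deliberately. Interaction: the
flattened spatial descriptor and the channel descriptor concatenate into
an (S² + C)-vector passed through a one-hidden-layer MLP; because a dense
MLP pins the block to one resolution, the spatial descriptor is
adaptively pooled to a fixed S×S token grid (default S = 20) and the
returned spatial gate is resized back by nearest neighbour. The hidden
width is (S² + C)/8 — chosen so the attention unit undercuts the
bottleneck it replaces at the channel widths the detector actually uses;
a /4 hidden would exceed a bottleneck's weight count below ~96 channels
and defeat the block's purpose. Separation: the joint vector splits back
into its two parts, each squashed by a sigmoid; the channel gate applies
first, then the spatial gate, so every output magnitude is bounded by the
input's. The C3k2-CSCBAM block carries exactly one batch-normalisation
and one ReLU, applied to the working branch immediately before the fusion
concat; its projections are biased 1×1 convolutions with SiLU so no other
normalisation enters the inventory.

**Small-object head.** When enabled, the stride-8 neck output is
upsampled to the head stride (default 4; stride 2 available by
configuration but four times as expensive), passed through an SPPFLKC
gate, concatenated with the stride-4 backbone feature, fused by a C3k2
block (the CSCBAM variant when that switch is on), and decoded by a head
whose second convolution is a detail-enhanced convolution: a vanilla 3×3
kernel summed with central-, angular-, horizontal- and vertical-difference
kernels derived from free parameters, collapsed into one effective kernel
at forward time. The extra head raises parameter count and, because it
operates on a 160×160 grid at 640 px input, adds a large share of FLOPs.

## Assembly, scales, calibration

The graph follows the YOLO v11 convention: stem and four strided stages
with C3k2 blocks (channel plan 64/128/256/512/1024 × width multiplier,
capped at 1024; one unit per block at depth multiplier 0.5; the deeper two
stages use C3k sub-blocks), SPPF (or SPPFLKC) at stride 32, a PAN neck
whose two top-down blocks are the CSCBAM substitution sites, and
anchor-free heads (two 3×3 convs and a 1×1 predictor; 4 box distances via
softplus plus class logits, class bias initialised to −4 so early
training is not dominated by negative cells). The post-pyramid attention
stage some releases place after SPPF is omitted; the pooling pyramid is
the only stride-32 context block.

Channel widths quantise to multiples of 4, so the width multiplier is a
step function of parameters. The `calibrated` scale (width 0.551) is the
grid point whose baseline structural count, 11.524 M, reproduces the
11.5 M reference baseline to printed precision; it was solved once by
scanning the width grid and is fixed as configuration. `official-n` is
width 0.25; `tiny` (width 0.125) exists for desk-scale training runs.
FLOPs are counted as multiply-accumulates (one MAC = one FLOP, the
convention under which a convolution costs its weight count times the
output grid), tallied by the engine's profiler during a real forward pass
and checked in the tests against per-layer closed-form counts.

With this architecture the component switches move the totals in the
directions the design intends — the CAFormer/CGLU and CSCBAM
substitutions each remove roughly 0.3 M parameters at the calibrated
scale, together more than either alone; the pooling pyramid adds a
little; the stride-4 head adds about 1 M parameters and most of a
doubling in FLOPs. The *magnitudes* of published multi-million-parameter
reductions for these substitutions are not reachable from any
standard-depth assembly of this family, in which the replaced blocks
simply do not hold that many parameters; the acceptance script reports
what the assembled models actually measure.

## Training

The loss is an anchor-free composite: each ground-truth box is assigned
to the scale whose stride is nearest (in log2) to size/4 and to the cells
of its centre's 3×3 neighbourhood lying inside the box; positive cells
regress left/top/right/bottom distances (softplus, stride units) with a
1 − IoU loss, and class scores train with binary cross-entropy on logits
(one for the true class at positives, zero elsewhere), both normalised by
the positive count, combined with weights 1 (class) and 5 (box). The
optimiser is SGD with momentum 0.937, weight decay 0.005 on matrix-shaped
weights, linear warm-up (3 epochs) and cosine decay from lr 0.01. The
reference recipe (300 epochs, batch 32, 640 px) ships as the config
default; desk-scale runs cap `max_iterations` and shrink the image.
Training is deterministic given the seed under single-threaded execution,
and the loop aborts with a diagnostic on a non-finite loss. A task-aligned
assigner with distribution-focal box regression is the convention in
full-scale trainers; the simpler centre-prior assignment and IoU loss
were chosen deliberately — they keep the tape small and are sufficient
for the scaled-down learning checks this package targets.

Evaluation decodes at a low confidence (0.01) so average precision sees
the full precision–recall sweep, while headline precision/recall use the
0.25 operating point; AP uses 101-point COCO interpolation (precision at
each grid recall is the enveloped precision of the first measured point
at or beyond it — the tests pin this against an exhaustive-threshold
oracle), mAP50-95 averages IoU thresholds 0.5:0.05:0.95, and the
confusion matrix matches class-agnostically at IoU 0.45/confidence 0.25.

## Synthetic scenes

The generator renders leaf-blade backgrounds (smoothed noise plus tilted
green strips with midribs) and three lesion phenotypes with disjoint
geometry and colour signatures: brown spot — near-circular (aspect
1.0–1.3) dark-brown cores with yellow halos; rice blast — diamond lesions
(aspect 2.0–2.8) with pale grey cores and dark rims; bacterial blight —
long stripes (aspect 4.5–7.0, near-vertical like the blades) in yellow.
Scenario modes modulate the scene: sunny brightens and raises contrast;
cloudy dims, lowers contrast and blurs slightly; dense doubles the blade
count, clusters lesions around a centre (raising box-overlap frequency)
and paints occluding blades over them. Scene randomness is split into a
geometry stream (labels) and a background stream (pixels), so
annotation-only generation at protocol scale (4000 records in seconds) is
label-identical to full rendering. Images with an assigned dominant class
receive a strict majority of that class's lesions (n − ⌊n/3⌋ of n), so
dominant-class counts follow the 4:3:3 ratio exactly and the stratified
7:2:1 split lands on 2800/800/400 at n = 4000.

What the generator does not emulate: real leaf texture and venation,
perspective and depth of field, disease-stage progression, weeds and
water surfaces, sensor noise, and intra-class variability beyond the
parameter ranges above. Tests passing on these scenes demonstrate that
the pipeline — blocks, assembly, loss, optimisation, decoding, metrics —
is internally correct and can fit visually separable phenotypes; they say
nothing about accuracy on field imagery.

## Problem sizes and numerical choices

The test suite runs the 16-variant forward checks at the `tiny` scale and
the learning sanity run on 16 scenes at 320 px with batch 4 and at most
200 iterations — sizes chosen so the whole suite completes comfortably on
one CPU. Ties in the gate threshold go to the informative side (w ≥ t);
the channel-half split in the reconstruction is contiguous
first-half/second-half; max-pool padding uses −∞ semantics and
average-pool excludes padded cells; IoU uses a 1e-7 union floor;
same-padding places the odd pixel of even effective kernels on the
bottom/right. Degenerate inputs fail loudly: channel mismatches,
thresholds outside (0,1), ratios that empty a CGLU branch, non-odd pool
kernels and invalid scene configurations all raise `ValueError`.

## Known limitations

* The engine is single-threaded NumPy: roughly two orders of magnitude
  slower than a compiled framework, so full-recipe training (300 epochs,
  4000 images, 640 px) is out of reach; the package targets structural
  verification and scaled-down learning checks.
* The FLOP cross-check is between two internal routes (runtime MAC tally
  vs per-layer closed form), not an external profiler.
* The published wiring of the pooling pyramid's figure, the deformable
  offsets of the CAFormer sub-branch, and the interaction MLP's exact
  shape are unspecified in the source design; the choices here are
  documented above and in the code, and marked where they deviate from a
  literal reading.
* mAP50-95 uses COCO interpolation; an all-point integrator would differ
  in the third decimal on small sets.
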