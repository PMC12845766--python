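# Methods

## Problem and scope

The package performs binary semantic segmentation of cell nuclei
(foreground) versus background in RGB microscopy images. It does not
attempt instance segmentation: per-nucleus masks in the input layout
are merged by pixelwise OR into one binary mask per image, and all
metrics are pixelwise.

## Data model and splitting

A sample is one image plus its union mask (`ImageRecord`). Images are
kept at native size until patch extraction; grayscale inputs are
replicated to three channels and RGBA inputs drop alpha, because the
network input is fixed at three channels. Mask files are binarized at
intensity > 0 (instance masks in the wild are 0/255 PNGs).

The train/validation/test split is 80:10:10 **by whole image**, before
patch extraction, so no source image leaks across subsets. Sizes are
`floor(0.8 n)` / `floor(0.1 n)` / remainder — deterministic and summing
exactly to `n`. Records are ordered by id before the seeded shuffle, so
the split is independent of filesystem enumeration order.

## Balanced patch extraction

Patch geometry is controlled by the kernel size `k` (default 128),
stride `s` (default 64, i.e. 50% overlap — overlap is intentional, it
multiplies the effective training views of each nucleus), padding fixed
at 0 and dilation fixed at 1 (the dilation knob exists in the parameter
set for completeness but plays no role in the grid arithmetic). Window
counts per axis use a ceiling, `ph = ceil((h-k)/s) + 1`, so the grid
always covers the image; because padding is zero, the last window
origin per axis is clamped to `h-k`, producing extra overlap at the
border rather than padded pixels. Clamped origins are kept even if they
coincide with the previous origin, so the patch count always equals
`ph * pl`. (With this ceiling the clamped origin in fact never
duplicates an earlier one, which the brute-force enumeration tests
confirm.) Images smaller than `k` are reflect-padded up to `k` and the
event is logged.

The balance filter keeps a patch only when its foreground-pixel count
**strictly exceeds** `alpha_threshold` (default 9). The count of
discarded patches, `alpha`, is tracked per image and aggregated per
subset in the balance report. Note that 10 pixels is ~0.06% of a
128x128 patch — the filter removes essentially-empty windows rather
than enforcing any sizeable minimum coverage; that is enough to raise
the ensemble's foreground fraction because real (and synthetic)
collections contain many empty fields.

Augmentation applies a randomly composed subset of {vertical flip,
horizontal flip, rotation by a random multiple of 90 degrees, Gaussian
blur} to a configurable fraction (default 0.25) of kept **training**
patches, appending the transformed copies to the ensemble. Geometric
transforms are applied identically to image and mask; blur touches the
image only, so masks stay binary and foreground counts are preserved.
Whether the filter's accounting is per-image or per-dataset is a
genuine design fork; it is implemented per-image with dataset-level
aggregation in the balance report.

## Network

A six-level U-shaped encoder–decoder for `(128, 128, 3)` inputs.
Channel schedule of the default (full-width) model:

| block        | conv1 | conv2 | spatial |
|--------------|------:|------:|--------:|
| downblock-1  |     8 |     8 | 128x128 |
| downblock-2  |    16 |    16 |   64x64 |
| downblock-3  |    32 |    32 |   32x32 |
| downblock-4  |    64 |    64 |   16x16 |
| downblock-5  |   128 |    16 |     8x8 |
| downblock-6  |   256 |    32 |     4x4 |
| middleblock  |   512 |    64 |     2x2 |
| upblock-6..1 | 256,128,64,32,16,8 | 32,16,64,32,16,8 | mirror |
| output       |     2 | — | 128x128 |

Block structure: two 3x3 same-padded convolutions, ReLU after each,
one dropout after the block. The 2x2 max-pool sits at the head of
downblocks 2–6 and of the middle block (the only placement consistent
with the spatial sizes above). Decoder blocks open with a 2x2 stride-2
transposed convolution whose output channels equal the block's first
convolution width, then concatenate the skip partner's final feature
map (the second convolution's output of the same-numbered encoder
block), then run conv–ReLU–conv–ReLU–dropout. The head is a 1x1
convolution to 2 channels with per-pixel softmax. Note the schedule is
asymmetric by design: encoder blocks 5/6 collapse their second
convolution to 16/32 channels and decoder blocks 6/5 end at 32/16, so
the decoder is *not* an exact mirror of a classical U-Net.

Weights are He-uniform initialized (seeded per layer via spawned seed
sequences; ReLU-appropriate), biases zero, and every convolution
carries a bias. No pre-trained weights are used anywhere.

`width_divisor` divides every filter count (floor, minimum 2) to give a
topology-identical reduced model for desk-scale experiments.

### NumPy engine

The engine is a small hand-written CNN stack: shift-and-accumulate
same-padded convolution (one `(B*H*W, Cin) x (Cin, Cout)` BLAS matmul
per kernel offset — substantially less memory traffic than im2col at
these narrow widths), reshaping 2x2 max-pool with argmax routing, an
einsum-based 2x2 stride-2 transposed convolution (kernel == stride, so
output blocks are disjoint), inverted dropout, and explicit reverse-
order backprop with concatenation gradients split back into decoder
and encoder halves. Correctness is pinned by tests: forward
convolution against `scipy.signal.correlate`, and central-difference
gradient checks in float64 (tolerance 1e-6 per layer; whole-network
agreement is limited only by near-kink ReLU units). Computation is
float32 in training, with a parameter-dtype switch used by the
verification tests.

## Loss, optimizer, schedule

The loss is mean per-pixel binary cross-entropy on the softmax
foreground channel — algebraically identical to two-class categorical
cross-entropy — with probabilities clipped at 1e-7 before the logs (the
clip affects reported loss values only; the gradient uses the exact
`softmax - onehot` identity). Optimization is Adam (beta1 0.9, beta2
0.999, eps 1e-7) with decoupled weight decay 1e-4 applied to weight
matrices only.

Learning rate: `lr(e) = lr0 * 0.5 ** floor(e / (f * E))` with 0-based
epoch `e`, total epochs `E`, interval fraction `f` (default 1/8). With
the full-protocol defaults (lr0 3e-4, E 500) the rate is constant
through epoch 62 and halves at each 62.5-epoch boundary, taking 8
distinct values. Epoch indices are 0-based throughout; an interval
shorter than one epoch is a configuration error.

Early stopping monitors validation F1 with patience 50 (an epoch
"improves" only if F1 strictly increases, or ties with a strictly
higher MeanIoU); the same criterion selects the best checkpoint, which
is written as a compressed NumPy archive and verified by a
reload-and-re-evaluate test.

## Metrics

`precision = tp/(tp+fp)`, `recall = tp/(tp+fn)`, F1 their harmonic
mean, `IoU = tp/(tp+fp+fn)` for each class, and MeanIoU the arithmetic
mean of foreground and background IoU. Confusion counts are summed over
all evaluated patches before deriving scores (micro-averaging);
per-image macro-averaging is available behind a flag. Ratios with zero
denominator are defined as 1.0 — an all-background image predicted
all-background is vacuously perfect; this choice only matters for
empty-foreground edge cases. Binarization of the softmax output is
argmax with exact ties (0.5) assigned to foreground. Published
comparisons of this model family report F1 above both precision and
recall, which a harmonic mean cannot produce; this package computes F1
strictly from the formula.

## Synthetic data

`generate_sample` renders `n` ellipses (axes uniform in
`radius_range`, random orientation, overlap allowed with union
semantics) at `contrast` (+70 by default) over a textured background
(Gaussian-smoothed broadband noise, sigma 6 px, +/-25 intensity), adds
per-pixel Gaussian noise (sigma 8) and small per-channel offsets, and
clips to [0, 255]. `bright-on-dark` and `dark-on-bright` modes cover
both common stain polarities. When `target_fg_fraction` is set the
nucleus count is derived from the mean ellipse area and the render is
retried (bounded) until the achieved fraction is within a factor of
two of the target. `generate_dataset` jitters image sizes (default
128–192 px) and renders a configurable fraction of images (default
0.15) with no nuclei at all — sparse fields are ubiquitous in real
screens and are precisely what the balance filter exists to remove.
Instance masks are written one file per nucleus so the loader's merge
path is exercised end to end.

What the generator does **not** emulate: realistic stain textures and
color distributions, out-of-focus fields, touching-nuclei boundary
ambiguity, annotation noise. Passing the synthetic end-to-end test
therefore demonstrates that the pipeline's machinery — balancing,
training dynamics, checkpointing, evaluation — works, not that the
model reaches benchmark accuracy on real data.

## Desk-scale end-to-end conditions

The end-to-end test trains on 64 synthetic images (~5% foreground,
sizes 128–192, seed 42) with the standard extraction settings (k=128,
s=64, threshold 9, 25% augmentation), a width-divisor-4 model, batch
16, lr0 3e-3 with one halving mid-run, weight decay 1e-4, and at most
40 epochs — a few hundred optimizer steps, sized so the whole suite
runs on a single CPU. Two deliberate deviations from the full-protocol
defaults, both consequences of the reduced width: the learning rate is
10x the full-scale default (small networks tolerate and need larger
steps, and the run is two orders of magnitude shorter than the
500-epoch protocol), and dropout is disabled — element-wise 20% dropout
on blocks that are only 2–4 channels wide removes most of the signal
path, which a network this narrow cannot afford. Training on
imbalanced BCE characteristically first collapses to the background
prior, then carves out the foreground; the budget above gives the
escape comfortable headroom (the end-to-end test's history records the
trajectory).

## Known limitations

- No GPU or multithreading; throughput is what single-threaded BLAS
  provides. Full-width 500-epoch training is possible but slow.
- Binary task only; no instance separation, no object-level metrics.
- The stride needed to reproduce any particular published patch count
  on external data is not determinable from the published protocol;
  stride is therefore a surfaced, required parameter.
- Whole-image stitched evaluation (overlap-averaged probabilities) is
  not implemented; evaluation is per patch, matching the training
  representation.
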