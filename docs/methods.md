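# Methods

## Problem setting

The target structures are thin, curved ribbons — prototypically the
glomerular basement membrane in renal transmission electron micrographs —
whose gray level differs from surrounding tissue only in the mean, not
reliably per pixel. Two modeling consequences follow: context must be
aggregated along the ribbon's axis (a square receptive field mostly sees
background), and the loss must concentrate effort on pixels whose label
disagrees with their neighborhood, because those are the pixels an
annotator also finds hard.

## Model

**Backbone.** Five stages. A strided 3×3 stem (stride 2) and a residual
stage give the low-level features f₁ (stride 2) and f₂ (stride 4). Three
further residual stages give the high-level features f₃–f₅. Each residual
block reduces channels 1×1, splits them in two, passes the second half
through a 3×3 convolution that also receives the first half's output
(a hierarchical intra-block connection, giving two effective receptive-field
scales per block), concatenates, expands 1×1 and adds a projected skip.
Blocks use a per-channel spatial normalization (each channel standardized
over H×W, learned gain/offset). This normalization carries no running
statistics, so inference is deterministic and batch-size independent; in a
small from-scratch network it is what makes a few hundred optimization
steps sufficient.

With `use_dilated` (default), stages 4–5 keep stride 1 and use dilation
rates 2 and 4, so f₃, f₄, f₅ share one spatial size — stride 8 of the input
for the full-scale preset, stride 4 for the tiny preset (see *Presets*).
With the toggle off, stages 4–5 stride instead, and the global-map head
upsamples them to f₃'s grid before fusing.

**Refined strip pooling (RSP).** Applied independently to f₃, f₄, f₅
(parameters not shared). Three branches: row means (1×W window) refined by
a 3×1 convolution and broadcast back across the width; column means (H×1)
refined by 1×3 and broadcast down the height; a d×d average pooling
(default d = 4) refined by 3×3 and bilinearly upsampled. Branches are
summed (channel concatenation is available via `rsp_fusion="concat"`),
mixed by a 1×1 convolution, and squashed into a sigmoid gate applied
multiplicatively to the input with an identity skip — the block modulates
features, it cannot destroy them.

**Decoder.** A top-down fusion (1×1 reductions, two 3×3 fusion steps) of
the three RSP-refined stages yields the coarse global logit map S₀. Three
reverse-attention steps then walk the cascade deepest-first:
(f₅, S₀) → S₁, (f₄, S₁) → S₂, (f₃, S₂) → S₃. Each step computes
A = 1 − σ(S_prev) (the previous prediction resampled to the feature grid),
gates R = f ⊙ A, and predicts a residual correction
S = head(R) + S_prev with a two-convolution head. Erasing already-confident
regions forces each refinement to spend capacity on uncertain pixels, which
for ribbon targets are almost exactly the boundary pixels. All four maps
are bilinearly upsampled to the input size; S₃ is the prediction.

**Input handling.** Grayscale images in [0,1] are replicated to 3 channels.
Input sides must be divisible by 32 (configurable `resize_policy="resize"`
resizes instead of raising).

## Loss

For ground truth gt ∈ {0,1}^{H×W} and probabilities p = σ(S):

* difficulty α_ij = Σ_windows |mean(gt over window centered at ij) − gt_ij|
  over the three windows 31×1, 1×31, 31×31. Window means at the border are
  taken over the in-bounds part of the window only (no padding bias). Each
  term uses the absolute difference, so α ≥ 0 and ω = 1 + γ·α ≥ 1
  (γ = 5 by default). A signed version would allow negative weights, which
  contradicts ω's role as an importance weight.
* weighted soft IoU: 1 − Σ(gt·p·ω) / Σ((gt + p − gt·p)·ω); defined as 0
  when gt and p are both identically zero.
* weighted BCE: −Σ ω (gt log p + (1−gt) log(1−p)) / Σω, with p clamped to
  [1e−7, 1−1e−7]; written as a positive quantity to be minimized.
* total = Σ_k (IoU_k + BCE_k) over the supervised outputs S₀–S₃, with
  equal weights (no evidence favored a schedule).

`adaptive_loss=False` sets ω ≡ 1 — the non-adaptive ablation.

The denominator of the weighted IoU applies ω to the whole union expression
(gt + p − gt·p), not to each term separately, and α sums (does not average)
the three window terms; both choices follow the formula as written in the
lineage this loss comes from.

## Metrics

Dice and IoU are computed on predictions binarized at 0.5; MAE, S-measure
and weighted F-measure on the continuous probability map (the convention of
the literature this metric panel comes from; the package takes no position
on which the original experiments used). Empty-vs-empty overlap is scored 1
so perfect-background images do not poison dataset means. S-measure is the
λ = 0.5 combination of an object-aware term (foreground/background
similarity weighted by mask coverage, degenerate masks falling back to
mean-based scores) and a region term (SSIM-style similarity over the 4-way
split of the image at the mask centroid). Weighted F-measure spreads
foreground errors through a 7×7 Gaussian (σ = 5) dependency kernel and
decays background errors with 2 − exp(ln(0.5)/5 · Δ) of the distance Δ to
the foreground, then forms Fβ with β² = 1. Both are verified in the test
suite against independent loop-based implementations of the same
definitions.

## Thickness measurement

Closing with a disk of radius 2 removes pinholes; components under 64 px
(configurable) are dropped. Topology-preserving thinning yields the
skeleton, turned into an 8-adjacency graph. The central axis is the longest
geodesic of the largest component: for tree-shaped skeletons (the typical
thinning outcome) an exact double BFS sweep; if cycles are present, the
longest shortest-path between skeleton endpoints is used (the true longest
simple path in a cyclic graph is not tractable, and the geodesic matches
the intent of "longest segment"). Thickness at an axis point is 2·d − 1
pixels, where d is the Euclidean distance transform sampled at the point:
d covers one side of the ribbon plus the axis pixel, so doubling and
removing the doubly-counted axis pixel yields a width — on a constructed
width-w ribbon the profile reads w within a pixel, which is the convention
the synthetic generator also uses. Five points (configurable) are trimmed
from each end of the axis because end caps bias the distance transform
downward. `nm_per_px` converts to physical units and must be supplied by
the user (magnification is instrument-specific); it defaults to 1.

## Synthetic data

Each sample draws a sweep direction, places 6 control points along it with
perpendicular jitter, interpolates a cubic spline, samples a per-arclength
width profile uniformly from [6, 16] px, and rasterizes: a pixel is
foreground iff its center lies within half the local width of the
centerline (ties included). Geometry is resampled until the mask is a
single 8-connected component filling 1–40% of the canvas. The image is a
smoothed-noise texture around 0.5, plus `contrast_delta` = 0.08 on the
ribbon, plus compact elliptical distractor blobs of the same contrast
strictly outside the mask (so local intensity alone cannot separate
classes), plus Gaussian noise of σ = 0.05, clipped to [0,1]. At these
defaults the ribbon/background intensity histograms overlap by more than
50% — the task is genuinely low-contrast.

What the generator does *not* emulate: the tissue ultrastructure around a
real membrane (organelles, cell boundaries that correlate with the
membrane's position), multi-ribbon images, staining gradients, and imaging
artifacts. Passing tests on this data show the architecture, loss,
optimization and measurement chain are correct and consistent with each
other; they say nothing about accuracy on clinical micrographs.

## Presets and problem sizes

* `paper` preset: width-32 backbone, output stride 8, Adam at 3e-4, batch
  2, 60 epochs, 1024×1024 inputs, multiscale factors {0.75, 1, 1.25}
  rounded to multiples of 32. This mirrors the full-scale protocol and is
  GPU territory; it is defined but not exercised by the test suite.
* `tiny` preset (the package's own experimental configuration): width-8
  backbone, output stride 4, Adam at 1e-3, 96×96 inputs, same multiscale
  factors. Output stride 4 keeps the representational ceiling well above
  the ribbon widths at this canvas size: upsampling ideal, perfectly
  confident logits from the output grid and thresholding bounds the
  attainable Dice, and at 96 px the stride-4 bound stays above 0.93 while
  the stride-8 bound falls well below it (both bounds are computed in the
  test suite). lr 1e-3 suits the small from-scratch network. One 300-step
  run takes a couple of minutes on one CPU core.

Multiscale resizing draws one factor per step. Validation for
checkpointing uses mean Dice of S₃ at scale 1. The learning rate is
constant (no schedule). No augmentation beyond multiscale is used.

## Numerical choices and edge cases

* All arithmetic is float64; finite-difference gradient checks hold to
  ~1e-5 relative.
* Standard pooling uses floor division and drops trailing partial windows.
* Rasterization includes pixels at exactly width/2 (≤ with a 1e-9 slack
  against floating-point representation of the distance).
* Degenerate inputs: coincident control points, non-binary ground truth,
  empty masks after cleaning, axis points on background, and empty training
  splits all raise explicit errors; single-node skeletons and empty
  ground-truth masks in Sm/Fm warn and take defined fallbacks.
* Everything is a pure function of (config, seed); repeated runs are
  bit-identical, which the test suite asserts at the file-byte level.

## Known limitations

* The Res2Net-style backbone is narrow and from-scratch; no pretrained
  weights are loaded (a checkpoint hook exists, untested against
  third-party weights).
* The cascade aggregation for S₀ is one reasonable top-down fusion among
  several; it is isolated in `GlobalMapHead` so alternatives are local
  edits.
* The cyclic-skeleton fallback returns a geodesic, which can undershoot the
  intuitive "longest segment" on skeletons with large loops.
* Thickness near junctions of branched ribbons reads the local inscribed
  half-width, which mixes the two branches' widths.
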