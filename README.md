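# stripseg

Segmentation and thickness quantification of **thin, strip-like structures**
in low-contrast grayscale images — the regime of the glomerular basement
membrane (GBM) in renal transmission electron micrographs, where a long,
curved membrane a few pixels wide must be separated from surrounding tissue
of nearly identical gray level, and its thickness (a diagnostic quantity in
nephropathy) measured along its length.

## What is in the box

* **A strip-pooling segmentation network.** A residual backbone with
  hierarchical intra-block splits yields five feature stages f₁–f₅; stages
  4–5 use dilated convolutions so f₃–f₅ share one spatial size. Each
  high-level stage passes through a *refined strip pooling* (RSP) gate that
  fuses horizontal strip pooling (window 1×W, i.e. row means), vertical
  strip pooling (H×1) and a small square pooling window into a sigmoid gate
  with a residual connection — long-range context along each axis for
  ribbon-shaped targets, square context for compact ones. A top-down fusion
  produces a coarse global logit map S₀, and a reverse-attention cascade
  refines it into side outputs S₁–S₃ by weighting features with
  A = 1 − σ(S_prev), concentrating each refinement on not-yet-confident
  (boundary) pixels. S₃ is the final prediction.
* **An adaptive anisotropically-weighted loss.** Per-pixel weights
  ω = 1 + γ·α with γ = 5, where the difficulty α sums, over three
  neighborhoods (31×1, 1×31, 31×31), the absolute difference between the
  neighborhood mean of the ground truth and the pixel's own label. The loss
  per supervised output is a weighted soft IoU term
  1 − Σ(gt·p·ω)/Σ((gt+p−gt·p)·ω) plus a weighted, weight-normalized binary
  cross-entropy, summed over S₀–S₃ (deep supervision).
* **Evaluation metrics**: Dice, IoU, S-measure, weighted F-measure, MAE,
  with dataset-level aggregation to CSV.
* **Skeleton-based thickness measurement**: morphological closing →
  topology-preserving thinning → longest skeleton path as the central axis →
  per-point thickness 2·d − 1 from the Euclidean distance transform, with
  optional nm-per-pixel scaling.
* **A synthetic-data generator** producing paired (image, mask) fixtures
  with the two properties the method exploits — elongated curvilinear shape
  and low contrast — plus compact distractor blobs, so the whole pipeline is
  testable without clinical data.

The numerical core is a compact reverse-mode autodiff engine over NumPy
arrays (`stripseg.autodiff`, `stripseg.nn`) sized for the small,
CPU-friendly model presets this package ships.

## Worked example

```bash
python examples/02_train_tiny_model.py
```

trains the tiny preset (96×96 inputs, width-8 backbone, Adam at 1e-3,
multiscale factors 0.75/1/1.25) for 120 steps on 8 synthetic ribbons and
prints, on one run:

```
 epoch  step  loss_total  loss_iou  loss_bce  val_dice
    30   118    3.456575  1.579065  1.877510       NaN
    30   119    2.431059  1.286049  1.145009       NaN
    30   120    1.626553  0.906400  0.720153  0.784398

training-set Dice after 120 steps: 0.784
```

The loss falls from ~8.8 at the first step; by step 120 the ribbons are
localized (Dice ≈ 0.78 against the same masks the model trained on — a
capacity/optimization sanity check, not a generalization claim; 300 steps
take the median run above Dice 0.9).

Thickness measurement on a synthetic ribbon
(`python examples/03_measure_thickness.py`):

```
axis points measured : 346
mean thickness       : 8.86 px = 22.14 nm (at 2.5 nm/px)
median / min / max   : 9.00 / 7.00 / 13.14 px
generator width range: [8.55, 13.97] px
```

The measured profile tracks the generator's ground-truth width profile —
the simulator and the measurement agree on what "width" means.

Command-line equivalents: `stripseg simulate`, `stripseg train`,
`stripseg predict`, `stripseg evaluate`, `stripseg measure` (see
`stripseg --help`).

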