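"""Segmentation / saliency evaluation metrics.

Overlap metrics (Dice, IoU) are computed on binarized predictions; the
saliency-style metrics (MAE, S-measure, weighted F-measure) operate on the
continuous probability map, following common practice in the salient-object
and medical-segmentation literature this metric set comes from.

* ``dice``/``iou`` — region-overlap ratios; ``dice = 2*iou/(1+iou)``.
* ``mae`` — mean absolute pixel error between map and mask.
* ``s_measure`` — structure measure: convex combination (λ=0.5) of an
  object-aware term (foreground/background similarity weighted by mask
  coverage) and a region term (SSIM-like similarity over a 4-way split of
  the image at the mask centroid).
* ``weighted_f_measure`` — Fβ (β²=1) on weighted precision/recall, where
  errors are propagated through a Gaussian dependency kernel within the
  foreground and decayed with distance outside it, so near-misses at the
  boundary count less than gross errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "dice",
    "iou",
    "mae",
    "s_measure",
    "weighted_f_measure",
    "MetricsReport",
    "evaluate_dataset",
]

_EPS = np.finfo(float).eps


def _binary(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype == bool:
        return m
    return m > 0.5


def dice(p, gt) -> float:
    """Dice coefficient 2|P∩G| / (|P|+|G|); 1.0 if both masks are empty."""
    p, gt = _binary(p), _binary(gt)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {gt.shape}")
    denom = p.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, gt).sum() / denom)


def iou(p, gt) -> float:
    """Jaccard index |P∩G| / |P∪G|; 1.0 if both masks are empty."""
    p, gt = _binary(p), _binary(gt)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {gt.shape}")
    union = np.logical_or(p, gt).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, gt).sum() / union)


def mae(p, gt) -> float:
    """Mean absolute difference between a probability map and a mask."""
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    return float(np.abs(p - g).mean())


# ---- S-measure -----------------------------------------------------------

def _object_score(x: np.ndarray) -> float:
    """Similarity of the values x covering one class region."""
    if x.size == 0:
        return 0.0
    mu = x.mean()
    sigma = x.std(ddof=1) if x.size > 1 else 0.0
    return float(2.0 * mu / (mu * mu + 1.0 + sigma + _EPS))

def _s_object(p: np.ndarray, gt: np.ndarray) -> float:
    u = gt.mean()
    o_fg = _object_score(p[gt])          # prediction inside the object
    o_bg = _object_score((1.0 - p)[~gt])  # inverted prediction on background
    return u * o_fg + (1.0 - u) * o_bg

def _region_ssim(p: np.ndarray, g: np.ndarray) -> float:
    n = p.size
    if n == 0:
        return 1.0
    x, y = p.mean(), g.mean()
    if n > 1:
        sx = p.var(ddof=1)
        sy = g.var(ddof=1)
        sxy = ((p - x) * (g - y)).sum() / (n - 1)
    else:
        sx = sy = sxy = 0.0
    a = 4.0 * x * y * sxy
    b = (x * x + y * y) * (sx + sy)
    if a != 0.0:
        return float(a / (b + _EPS))
    return 1.0 if b == 0.0 else 0.0

def _s_region(p: np.ndarray, gt: np.ndarray) -> float:
    H, W = gt.shape
    rows, cols = np.nonzero(gt)
    # centroid of the mask (image centre if empty; guarded upstream)
    cy = int(round(rows.mean())) + 1 if rows.size else (H + 1) // 2
    cx = int(round(cols.mean())) + 1 if cols.size else (W + 1) // 2
    area = H * W
    w1 = (cx * cy) / area
    w2 = ((W - cx) * cy) / area
    w3 = (cx * (H - cy)) / area
    w4 = 1.0 - w1 - w2 - w3
    q = (
        w1 * _region_ssim(p[:cy, :cx], gt[:cy, :cx].astype(float))
        + w2 * _region_ssim(p[:cy, cx:], gt[:cy, cx:].astype(float))
        + w3 * _region_ssim(p[cy:, :cx], gt[cy:, :cx].astype(float))
        + w4 * _region_ssim(p[cy:, cx:], gt[cy:, cx:].astype(float))
    )
    return float(q)


def s_measure(p, gt, lam: float = 0.5) -> float:
    """Structure measure Sm = λ·S_object + (1−λ)·S_region, clipped to [0,1].

    Degenerate masks fall back to a mean-based score: all-background gt
    scores ``1 - mean(p)``, all-foreground gt scores ``mean(p)``.
    """
    p = np.asarray(p, dtype=np.float64)
    gt = _binary(gt)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {gt.shape}")
    y = gt.mean()
    if y == 0.0:
        warnings.warn("s_measure: empty ground truth, mean-based fallback")
        return float(1.0 - p.mean())
    if y == 1.0:
        warnings.warn("s_measure: all-foreground ground truth, mean-based fallback")
        return float(p.mean())
    s = lam * _s_object(p, gt) + (1.0 - lam) * _s_region(p, gt)
    return float(np.clip(s, 0.0, 1.0))


# ---- weighted F-measure --------------------------------------------------

def _gaussian_kernel(size: int = 7, sigma: float = 5.0) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def weighted_f_measure(p, gt, beta2: float = 1.0) -> float:
    """Weighted Fβ between a probability map and a binary mask.

    The absolute error map is smoothed: inside the foreground each pixel's
    error is blended through a 7×7 Gaussian (σ=5) dependency kernel (a miss
    surrounded by hits matters less); background errors are scaled by
    ``2 − exp(ln(0.5)/5 · Δ)`` with Δ the distance to the foreground, so
    errors far from the object weigh up to twice as much as boundary-adjacent
    ones.  Weighted TP/FP then give precision/recall and the Fβ score.

    Returns 0 (with a warning) for an empty ground truth.
    """
    p = np.asarray(p, dtype=np.float64)
    gt = _binary(gt)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {gt.shape}")
    if not gt.any():
        warnings.warn("weighted_f_measure: empty ground truth -> 0")
        return 0.0
    g = gt.astype(np.float64)
    dist, (inds_r, inds_c) = ndimage.distance_transform_edt(
        ~gt, return_indices=True
    )
    err = np.abs(p - g)
    # background pixels inherit the error at their nearest foreground pixel
    err_t = err.copy()
    bg = ~gt
    err_t[bg] = err[inds_r[bg], inds_c[bg]]
    ea = ndimage.convolve(err_t, _gaussian_kernel(7, 5.0), mode="constant")
    min_e_ea = err.copy()
    take = gt & (ea < err)
    min_e_ea[take] = ea[take]
    b = np.ones_like(g)
    b[bg] = 2.0 - np.exp(np.log(0.5) / 5.0 * dist[bg])
    ew = min_e_ea * b
    tp_w = g.sum() - ew[gt].sum()
    fp_w = ew[bg].sum()
    recall = 1.0 - ew[gt].mean()
    precision = tp_w / (tp_w + fp_w + _EPS)
    return float(
        (1.0 + beta2) * precision * recall / (beta2 * precision + recall + _EPS)
    )


# ---- dataset-level evaluation -------------------------------------------

@dataclass
class MetricsReport:
    """Per-image metrics plus dataset means."""

    table: pd.DataFrame  # columns: image, dice, iou, sm, fm, mae
    means: dict[str, float]
    n_images: int

    def save_csv(self, path) -> None:
        out = self.table.copy()
        mean_row = {"image": "mean", **self.means}
        out = pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)
        out.to_csv(path, index=False)


def _load_gray(path: Path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0


def evaluate_single(pred_map: np.ndarray, gt_mask: np.ndarray,
                    threshold: float = 0.5) -> dict[str, float]:
    """All five metrics for one prediction/ground-truth pair."""
    gt_b = _binary(gt_mask)
    pred_b = np.asarray(pred_map) >= threshold
    return {
        "dice": dice(pred_b, gt_b),
        "iou": iou(pred_b, gt_b),
        "sm": s_measure(pred_map, gt_b),
        "fm": weighted_f_measure(pred_map, gt_b),
        "mae": mae(pred_map, gt_b.astype(float)),
    }


def evaluate_dataset(pred_dir, gt_dir, threshold: float = 0.5,
                     strict: bool = False) -> MetricsReport:
    """Evaluate every prediction in `pred_dir` against the ground-truth mask
    of the same filename in `gt_dir`.

    Predictions are 8-bit grayscale probability maps; ground truths are
    binary {0,255} masks.  Files present in only one directory are reported
    and skipped (or raise, if ``strict``).
    """
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    exts = {".png", ".tif", ".tiff"}
    preds = {f.stem: f for f in sorted(pred_dir.iterdir()) if f.suffix.lower() in exts}
    gts = {f.stem: f for f in sorted(gt_dir.iterdir()) if f.suffix.lower() in exts}
    common = sorted(set(preds) & set(gts))
    unmatched = sorted(set(preds) ^ set(gts))
    if unmatched:
        msg = f"unmatched files skipped: {unmatched}"
        if strict:
            raise FileNotFoundError(msg)
        warnings.warn(msg)
    if not common:
        raise FileNotFoundError(
            f"no matching prediction/ground-truth pairs between {pred_dir} and {gt_dir}"
        )
    rows = []
    for stem in common:
        p = _load_gray(preds[stem])
        g = _load_gray(gts[stem])
        rows.append({"image": stem, **evaluate_single(p, g, threshold)})
    table = pd.DataFrame(rows)
    means = {k: float(table[k].mean()) for k in ("dice", "iou", "sm", "fm", "mae")}
    return MetricsReport(table=table, means=means, n_images=len(common))
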