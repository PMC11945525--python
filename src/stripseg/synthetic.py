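"""Synthetic low-contrast ribbon images with paired ground-truth masks.

Real electron micrographs of thin membranes have two properties that drive
the design of this whole package: the structure of interest is a long,
curved, strip-like ribbon, and its gray level barely differs from the
surrounding tissue.  The generator reproduces exactly those two properties —
a smooth random centerline with a slowly varying width rasterized into a
binary mask, rendered onto a textured background with a small mean intensity
offset, compact blob distractors of the same contrast (so local intensity
alone cannot separate classes), and additive Gaussian noise.

Everything is a pure function of the configuration and seed, so datasets are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "SyntheticConfig",
    "SyntheticSample",
    "make_ribbon_mask",
    "render_image",
    "generate_sample",
    "generate_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one ribbon sample.

    Defaults target the regime the segmentation method is designed for:
    ribbons a few to ~16 px wide on a 256-px canvas, a mean foreground /
    background offset of 0.08 (well inside the noise), noise σ = 0.05, and
    three compact distractor blobs per image.
    """

    canvas_size: int = 256
    ribbon_width_px: tuple[float, float] = (6.0, 16.0)
    n_control_points: int = 6
    contrast_delta: float = 0.08
    noise_sigma: float = 0.05
    n_distractors: int = 3
    texture_strength: float = 0.06
    texture_scale: float = 12.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.ribbon_width_px
        if not (2.0 <= lo <= hi):
            raise ValueError("ribbon widths must satisfy 2 <= min <= max")
        if hi >= self.canvas_size / 4:
            raise ValueError("max ribbon width must be < canvas_size / 4")
        if not (0.0 <= self.contrast_delta <= 0.3):
            raise ValueError("contrast_delta must lie in [0, 0.3]")
        if self.n_control_points < 3:
            raise ValueError("need at least 3 control points")


@dataclass
class SyntheticSample:
    """A paired image/mask with its generation metadata."""

    image: np.ndarray  # H×W float in [0,1]
    mask: np.ndarray   # H×W uint8 {0,1}
    meta: dict = field(default_factory=dict)


def _interp_centerline(control_points: np.ndarray, n_samples: int) -> np.ndarray:
    """Cubic smooth interpolation through the control points, arc-sampled."""
    k = min(3, len(control_points) - 1)
    tck, _ = interpolate.splprep(
        [control_points[:, 0], control_points[:, 1]], s=0, k=k
    )
    t = np.linspace(0.0, 1.0, n_samples)
    r, c = interpolate.splev(t, tck)
    return np.column_stack([r, c])


def make_ribbon_mask(
    control_points,
    width_profile,
    canvas_size: int,
) -> tuple[np.ndarray, dict]:
    """Rasterize a smooth ribbon of (possibly varying) width into a mask.

    The centerline is a cubic interpolating spline through `control_points`
    (≥ 3 points, (row, col), inside the canvas).  A pixel belongs to the mask
    iff the Euclidean distance from its centre to the centerline is at most
    half the local width; ties at exactly width/2 are included.

    Parameters
    ----------
    control_points : (k, 2) array of (row, col) points, k >= 3.
    width_profile : scalar width, or array of widths (linearly interpolated
        over normalized arclength), all >= 2 px.
    canvas_size : side of the square canvas.

    Returns
    -------
    mask : uint8 H×W in {0,1}
    meta : dict with the dense ``centerline`` samples and per-sample
        ``widths``.
    """
    pts = np.asarray(control_points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 control points of shape (k, 2)")
    if (pts < 0).any() or (pts >= canvas_size).any():
        raise ValueError("control points must lie inside the canvas")
    if (np.linalg.norm(np.diff(pts, axis=0), axis=1) < 1e-9).any():
        raise ValueError("degenerate (coincident) consecutive control points")

    widths = np.atleast_1d(np.asarray(width_profile, dtype=np.float64))
    if (widths < 2.0).any():
        raise ValueError("ribbon widths must be >= 2 px")

    # dense arc sampling: step well below half a pixel
    n_samples = max(8 * canvas_size, 256)
    line = _interp_centerline(pts, n_samples)
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    arc_n = arc / max(arc[-1], 1e-12)
    if widths.size == 1:
        w_dense = np.full(n_samples, widths[0])
    else:
        w_dense = np.interp(arc_n, np.linspace(0, 1, widths.size), widths)

    tree = cKDTree(line)
    rr, cc = np.mgrid[0:canvas_size, 0:canvas_size]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    dist, idx = tree.query(pix, workers=-1)
    mask = (dist <= w_dense[idx] / 2.0 + 1e-9).reshape(canvas_size, canvas_size)
    meta = {"centerline": line, "widths": w_dense}
    return mask.astype(np.uint8), meta


def _textured_background(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.canvas_size
    base = np.full((n, n), 0.5)
    if cfg.texture_strength > 0:
        field_ = ndimage.gaussian_filter(rng.standard_normal((n, n)), cfg.texture_scale)
        std = field_.std()
        if std > 0:
            base = base + field_ / std * cfg.texture_strength
    return base


def _add_distractors(
    img: np.ndarray, mask: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Compact blobs, same contrast as the ribbon, strictly outside the mask."""
    n = cfg.canvas_size
    rr, cc = np.mgrid[0:n, 0:n]
    out = img.copy()
    for _ in range(cfg.n_distractors):
        r0, c0 = rng.uniform(0, n, 2)
        a = rng.uniform(4.0, 12.0)
        b = rng.uniform(4.0, 12.0)
        theta = rng.uniform(0, np.pi)
        dr, dc = rr - r0, cc - c0
        u = dr * np.cos(theta) + dc * np.sin(theta)
        v = -dr * np.sin(theta) + dc * np.cos(theta)
        blob = ((u / a) ** 2 + (v / b) ** 2) <= 1.0
        blob &= mask == 0
        out[blob] += cfg.contrast_delta
    return out


def render_image(
    mask: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Render a grayscale image for a given ground-truth mask.

    Background is a smoothed-noise texture around 0.5; ribbon pixels are
    shifted up by ``contrast_delta`` (an offset in expectation, not a
    per-pixel guarantee once noise is added); distractor blobs with the same
    contrast are placed outside the mask; i.i.d. Gaussian noise is added and
    the result clipped to [0, 1].
    """
    mask = np.asarray(mask)
    if mask.shape != (cfg.canvas_size, cfg.canvas_size):
        raise ValueError("mask does not match canvas size")
    img = _textured_background(cfg, rng)
    img = img + cfg.contrast_delta * (mask > 0)
    img = _add_distractors(img, mask, cfg, rng)
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def _sample_geometry(cfg: SyntheticConfig, rng: np.random.Generator):
    margin = cfg.ribbon_width_px[1]
    n = cfg.canvas_size
    # control points ordered along a random sweep direction, jittered, so the
    # centerline is a long open curve rather than a scribble
    theta = rng.uniform(0, np.pi)
    d = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-d[1], d[0]])
    center = np.array([n / 2.0, n / 2.0])
    span = rng.uniform(0.55, 0.9) * n
    offsets = np.linspace(-span / 2, span / 2, cfg.n_control_points)
    wiggle = rng.uniform(-0.18, 0.18, cfg.n_control_points) * n
    pts = center + offsets[:, None] * d + wiggle[:, None] * perp
    pts = np.clip(pts, margin, n - 1 - margin)
    widths = rng.uniform(*cfg.ribbon_width_px, size=cfg.n_control_points)
    return pts, widths


def generate_sample(cfg: SyntheticConfig, seed: int | None = None) -> SyntheticSample:
    """Draw one paired (image, mask) sample.

    Geometry is resampled (bounded retries) until the mask is a single
    8-connected component with foreground fraction in [0.01, 0.4].
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    for _ in range(32):
        pts, widths = _sample_geometry(cfg, rng)
        try:
            mask, meta = make_ribbon_mask(pts, widths, cfg.canvas_size)
        except ValueError:
            continue
        frac = mask.mean()
        ncomp = measure.label(mask, connectivity=2).max()
        if 0.01 <= frac <= 0.4 and ncomp == 1:
            break
    else:
        raise RuntimeError("could not sample a valid ribbon geometry")
    image = render_image(mask, cfg, rng)
    meta.update(
        {
            "seed": seed,
            "control_points": pts,
            "width_min": float(widths.min()),
            "width_max": float(widths.max()),
            "foreground_fraction": float(frac),
            "config": cfg,
        }
    )
    return SyntheticSample(image=image, mask=mask, meta=meta)


def _save_png(path: Path, arr: np.ndarray, binary: bool) -> None:
    if binary:
        data = (np.asarray(arr) > 0).astype(np.uint8) * 255
    else:
        data = np.clip(np.asarray(arr) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def generate_dataset(
    n: int,
    cfg: SyntheticConfig,
    out_dir,
    splits: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> pd.DataFrame:
    """Write `n` image/mask PNG pairs plus a manifest CSV.

    Layout: ``out_dir/images/<id>.png`` (8-bit grayscale),
    ``out_dir/masks/<id>.png`` ({0,255}), ``out_dir/manifest.csv`` with
    columns ``id,seed,split,width_min,width_max``.  Sample i uses the
    deterministic seed ``(cfg.seed * 100003 + i) mod 2^31``; regeneration
    with the same config is bit-identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(sum(splits) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    n_train = int(round(splits[0] * n))
    n_val = int(round(splits[1] * n))
    rows = []
    for i in range(n):
        seed_i = (cfg.seed * 100003 + i) % (2**31)
        sample = generate_sample(cfg, seed=seed_i)
        sid = f"sample_{i:04d}"
        _save_png(out_dir / "images" / f"{sid}.png", sample.image, binary=False)
        _save_png(out_dir / "masks" / f"{sid}.png", sample.mask, binary=True)
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        rows.append(
            {
                "id": sid,
                "seed": seed_i,
                "split": split,
                "width_min": sample.meta["width_min"],
                "width_max": sample.meta["width_max"],
            }
        )
    manifest = pd.DataFrame(rows, columns=["id", "seed", "split", "width_min", "width_max"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
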