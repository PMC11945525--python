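"""Pooling operators for elongated-structure segmentation.

Two families of context aggregation:

* **standard pooling** — a square d×d averaging window, suited to compact
  objects;
* **strip pooling** — a (1, W) or (H, 1) window that averages an entire row
  or column, capturing long-range context along one spatial axis, which is
  what thin ribbon-like structures (membranes, vessels) call for.

The :class:`RSPBlock` (refined strip pooling) fuses three parallel branches —
horizontal strip, vertical strip, and a small square pooling window — into a
sigmoid gate applied multiplicatively to the input feature map, with a
residual connection, so strip and non-strip evidence are combined in a single
module applied independently to each high-level backbone stage.

The plain-array operators (`standard_pool`, `strip_pool_h`, `strip_pool_v`)
are pure functions on C×H×W (or H×W) grids; `RSPBlock` is a learnable module
on NCHW tensors.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, avg_pool2d, sigmoid, upsample_bilinear, concat
from .nn import Conv2d, Module

__all__ = ["standard_pool", "strip_pool_h", "strip_pool_v", "RSPBlock"]


def _as_chw(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None], True
    if x.ndim == 3:
        return x, False
    raise ValueError(f"expected H×W or C×H×W grid, got shape {x.shape}")


def standard_pool(x: np.ndarray, d: int) -> np.ndarray:
    """Non-overlapping d×d average pooling.

    Output pixel (i0, j0) is the mean of the d×d block with top-left corner
    (i0·d, j0·d).  Output size is (H//d, W//d); trailing rows/columns that do
    not fill a complete window are dropped.

    Parameters
    ----------
    x : array, shape (H, W) or (C, H, W)
    d : pooling window size, 1 ≤ d ≤ min(H, W)
    """
    grid, squeeze = _as_chw(x)
    C, H, W = grid.shape
    if d < 1:
        raise ValueError(f"pool window must be >= 1, got {d}")
    if d > min(H, W):
        raise ValueError(f"pool window {d} exceeds input size {H}x{W}")
    H0, W0 = H // d, W // d
    out = grid[:, : H0 * d, : W0 * d].reshape(C, H0, d, W0, d).mean(axis=(2, 4))
    return out[0] if squeeze else out


def strip_pool_h(x: np.ndarray) -> np.ndarray:
    """Horizontal strip pooling: window (1, W), i.e. per-row means.

    Returns shape (C, H, 1) for a (C, H, W) input (or (H, 1) for 2-D input).
    """
    grid, squeeze = _as_chw(x)
    out = grid.mean(axis=2, keepdims=True)
    return out[0] if squeeze else out


def strip_pool_v(x: np.ndarray) -> np.ndarray:
    """Vertical strip pooling: window (H, 1), i.e. per-column means.

    Returns shape (C, 1, W) for a (C, H, W) input (or (1, W) for 2-D input).
    """
    grid, squeeze = _as_chw(x)
    out = grid.mean(axis=1, keepdims=True)
    return out[0] if squeeze else out


class RSPBlock(Module):
    """Refined strip pooling: gated fusion of strip and square context.

    Three parallel branches on an NCHW feature map f:

    a. horizontal strip pooling → 1-D refinement along the height axis
       (3×1 convolution) → broadcast back over the width;
    b. vertical strip pooling → 1-D refinement along the width axis
       (1×3 convolution) → broadcast back over the height;
    c. standard pooling with a small square window (default 4) →
       3×3 refinement → bilinear upsampling back to (H, W).

    The branches are fused (summed by default; channel concatenation
    optionally), mixed by a 1×1 convolution, squashed by a sigmoid into a
    gate g ∈ (0,1)^{C×H×W}, and applied as ``f ⊙ g`` with a residual
    connection (``+ f``) so the block can only modulate, never destroy,
    its input.

    Parameters
    ----------
    channels : feature channels (preserved).
    pool_window : square-pool window d for branch (c); input must be ≥ d×d.
    fusion : "add" or "concat".
    residual : include the identity skip (default True).
    """

    def __init__(
        self,
        channels: int,
        pool_window: int = 4,
        fusion: str = "add",
        residual: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if fusion not in ("add", "concat"):
            raise ValueError(f"fusion must be 'add' or 'concat', got {fusion!r}")
        rng = rng or np.random.default_rng()
        self.pool_window = pool_window
        self.fusion = fusion
        self.residual = residual
        self.refine_h = Conv2d(channels, channels, (3, 1), rng=rng)
        self.refine_v = Conv2d(channels, channels, (1, 3), rng=rng)
        self.refine_sq = Conv2d(channels, channels, 3, rng=rng)
        mix_in = channels * (3 if fusion == "concat" else 1)
        self.mix = Conv2d(mix_in, channels, 1, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        f = ad.as_tensor(f)
        _, _, H, W = f.shape
        d = self.pool_window
        if H < d or W < d:
            raise ValueError(f"spatial size {H}x{W} below pool window {d}")
        # (a) horizontal strip: per-row context, refined along H
        hs = self.refine_h(f.mean(axis=3, keepdims=True))
        hs = upsample_bilinear(hs, H, W)  # broadcast over width
        # (b) vertical strip: per-column context, refined along W
        vs = self.refine_v(f.mean(axis=2, keepdims=True))
        vs = upsample_bilinear(vs, H, W)
        # (c) square context
        sq = self.refine_sq(avg_pool2d(f, d))
        sq = upsample_bilinear(sq, H, W)
        if self.fusion == "add":
            fused = hs + vs + sq
        else:
            fused = concat([hs, vs, sq], axis=1)
        gate = sigmoid(self.mix(fused))
        out = f * gate
        if self.residual:
            out = out + f
        return out
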