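"""Strip-pooling segmentation network with a reverse-attention decoder.

Architecture overview:

* a residual backbone with hierarchical intra-block splits produces five
  feature stages f1..f5; stages 4–5 trade stride for dilation so f3, f4 and
  f5 share one spatial size (stride 8 of the input by default);
* the three high-level stages are refined by per-stage strip-pooling gates
  (:class:`~stripseg.pooling.RSPBlock`);
* a top-down fusion of the refined features yields a coarse global logit map
  S0;
* a cascade of reverse-attention steps walks back through f5, f4, f3:
  each step gates the features by ``A = 1 − sigmoid(previous prediction)``
  — erasing already-confident regions so the refinement concentrates on
  uncertain (boundary) pixels — and predicts a residual correction,
  producing side outputs S1, S2, S3;
* all four maps are upsampled to the input size for deep supervision; S3 is
  the final prediction.

Every component is an independent switch (`use_dilated`, `use_rsp`,
`use_attention`) so ablations are plain config changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, relu, sigmoid, upsample_bilinear
from .nn import ChannelNorm, Conv2d, Module
from .pooling import RSPBlock

__all__ = [
    "NetworkConfig",
    "BackboneFeatures",
    "SideOutputs",
    "reverse_attention_step",
    "SSPNet",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Structural hyperparameters of the model.

    ``width`` scales every stage's channel count; the "tiny" preset is small
    enough for CPU training and testing, which is the configuration all the
    package's own experiments use.
    """

    width: int = 8
    in_channels: int = 3          # grayscale input is replicated to this
    out_stride: int = 8           # spatial stride of f3..f5 (4 or 8)
    use_dilated: bool = True
    use_rsp: bool = True
    use_attention: bool = True
    rsp_pool_window: int = 4
    rsp_fusion: str = "add"
    size_divisor: int = 32
    resize_policy: str = "error"  # or "resize"
    seed: int = 0

    @staticmethod
    def tiny(**overrides) -> "NetworkConfig":
        """CPU-friendly preset: narrow channels, output stride 4."""
        kw = dict(width=8, out_stride=4)
        kw.update(overrides)
        return NetworkConfig(**kw)

    @staticmethod
    def paper(**overrides) -> "NetworkConfig":
        """Full-scale preset (GPU territory; defined for completeness)."""
        kw = dict(width=32, out_stride=8)
        kw.update(overrides)
        return NetworkConfig(**kw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class BackboneFeatures:
    """Five feature stages and their strides w.r.t. the input."""

    f1: Tensor
    f2: Tensor
    f3: Tensor
    f4: Tensor
    f5: Tensor
    strides: tuple[int, int, int, int, int] = (2, 4, 8, 8, 8)

    def high_level(self) -> tuple[Tensor, Tensor, Tensor]:
        return self.f3, self.f4, self.f5


@dataclass
class SideOutputs:
    """Logit maps (upsampled to input size) and decoder internals."""

    maps: dict[str, Tensor]              # "S0".."S3" -> (N,1,H,W) logits
    attention: dict[str, Tensor] = field(default_factory=dict)  # "A3".."A5"
    attended: dict[str, Tensor] = field(default_factory=dict)   # "R3".."R5"

    def final(self) -> Tensor:
        return self.maps["S3"] if "S3" in self.maps else self.maps["S0"]


class Res2Block(Module):
    """Residual block with a hierarchical two-way split.

    1×1 reduce → split channels in half; the second half passes through a
    3×3 conv fed by the first half's output (hierarchical connection) →
    concat → 1×1 expand, plus a projected skip.  Stride/dilation apply to
    the 3×3 convs.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 dilation: int = 1, rng=None):
        super().__init__()
        mid = max(out_ch // 2 * 2, 2)
        half = mid // 2
        self.reduce = Conv2d(in_ch, mid, 1, rng=rng)
        self.norm_in = ChannelNorm(mid)
        self.conv_a = Conv2d(half, half, 3, stride=stride, dilation=dilation, rng=rng)
        self.conv_b = Conv2d(half, half, 3, stride=1, dilation=dilation, rng=rng)
        self.norm_out = ChannelNorm(mid)
        self.expand = Conv2d(mid, out_ch, 1, rng=rng)
        self.skip = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
        self.half = half
        self.stride = stride

    def forward(self, x):
        h = relu(self.norm_in(self.reduce(x)))
        a_in = _narrow_channels(h, 0, self.half)
        b_in = _narrow_channels(h, self.half, self.half)
        a = relu(self.conv_a(a_in))
        if self.stride > 1:
            b_in = ad.avg_pool2d(b_in, self.stride)
        b = relu(self.conv_b(b_in + a))  # hierarchical: b sees a's output
        merged = self.norm_out(ad.concat([a, b], axis=1))
        out = self.expand(merged)
        return relu(out + self.skip(x))


def _narrow_channels(x: Tensor, start: int, length: int) -> Tensor:
    """Differentiable channel slice of an NCHW tensor."""
    out = Tensor(x.data[:, start : start + length])
    out._parents = (x,)

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[:, start : start + length] = g
        x._accumulate(gx)

    out._backward = bw
    return out


class Backbone(Module):
    """Five-stage residual feature extractor.

    Stages 4 and 5 use dilated 3×3 convolutions (rates 2 and 4) instead of
    further striding when ``use_dilated`` so f3–f5 share one spatial size.
    """

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        w = cfg.width
        self.cfg = cfg
        s3 = 2 if cfg.out_stride == 8 else 1
        self.stem = Conv2d(cfg.in_channels, w, 3, stride=2, rng=rng)
        self.stage2 = Res2Block(w, 2 * w, stride=2, rng=rng)
        self.stage3 = Res2Block(2 * w, 3 * w, stride=s3, rng=rng)
        if cfg.use_dilated:
            self.stage4 = Res2Block(3 * w, 3 * w, stride=1, dilation=2, rng=rng)
            self.stage5 = Res2Block(3 * w, 3 * w, stride=1, dilation=4, rng=rng)
        else:
            self.stage4 = Res2Block(3 * w, 3 * w, stride=2, rng=rng)
            self.stage5 = Res2Block(3 * w, 3 * w, stride=2, rng=rng)
        base = cfg.out_stride
        if cfg.use_dilated:
            self.strides = (2, 4, base, base, base)
        else:
            self.strides = (2, 4, base, 2 * base, 4 * base)

    def forward(self, x) -> BackboneFeatures:
        f1 = relu(self.stem(x))
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        f5 = self.stage5(f4)
        return BackboneFeatures(f1, f2, f3, f4, f5, strides=self.strides)


class GlobalMapHead(Module):
    """Top-down fusion of the three high-level stages into one logit map S0."""

    def __init__(self, channels: int, rng):
        super().__init__()
        c = channels
        self.red3 = Conv2d(c, c, 1, rng=rng)
        self.red4 = Conv2d(c, c, 1, rng=rng)
        self.red5 = Conv2d(c, c, 1, rng=rng)
        self.fuse54 = Conv2d(c, c, 3, rng=rng)
        self.fuse43 = Conv2d(c, c, 3, rng=rng)
        self.head = Conv2d(c, 1, 1, rng=rng)

    def forward(self, f3, f4, f5) -> Tensor:
        _, _, H, W = f3.shape
        r3 = self.red3(f3)
        r4 = upsample_bilinear(self.red4(f4), H, W)
        r5 = upsample_bilinear(self.red5(f5), H, W)
        g = relu(self.fuse54(r5) + r4)
        g = relu(self.fuse43(g) + r3)
        return self.head(g)


class RefineHead(Module):
    """Two-conv refinement of attended features into a residual logit map."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, rng=rng)
        self.conv2 = Conv2d(channels, 1, 3, rng=rng)

    def forward(self, r):
        return self.conv2(relu(self.conv1(r)))


def reverse_attention_step(
    f_i: Tensor, s_next: Tensor, head: RefineHead
) -> tuple[Tensor, Tensor, Tensor]:
    """One reverse-attention refinement.

    ``A = 1 − sigmoid(s_next)`` (s_next already resampled to f_i's size),
    ``R = f_i ⊙ A`` broadcast over channels, and the new prediction is the
    residual ``S = head(R) + s_next``.

    Returns (A, R, S).
    """
    f_i, s_next = ad.as_tensor(f_i), ad.as_tensor(s_next)
    if f_i.shape[2:] != s_next.shape[2:]:
        raise ValueError(
            f"s_next spatial size {s_next.shape[2:]} must match f_i {f_i.shape[2:]}"
        )
    a = 1.0 - sigmoid(s_next)
    r = f_i * a  # (N,1,H,W) broadcasts over channels
    s = head(r) + s_next
    return a, r, s


class SSPNet(Module):
    """Full strip-pooling segmentation model.  See module docstring."""

    def __init__(self, cfg: NetworkConfig | None = None):
        super().__init__()
        self.cfg = cfg or NetworkConfig.tiny()
        rng = np.random.default_rng(self.cfg.seed)
        c = 3 * self.cfg.width
        self.backbone = Backbone(self.cfg, rng)
        if self.cfg.use_rsp:
            self.rsp3 = RSPBlock(c, self.cfg.rsp_pool_window, self.cfg.rsp_fusion, rng=rng)
            self.rsp4 = RSPBlock(c, self.cfg.rsp_pool_window, self.cfg.rsp_fusion, rng=rng)
            self.rsp5 = RSPBlock(c, self.cfg.rsp_pool_window, self.cfg.rsp_fusion, rng=rng)
        self.global_head = GlobalMapHead(c, rng)
        if self.cfg.use_attention:
            self.head5 = RefineHead(c, rng)
            self.head4 = RefineHead(c, rng)
            self.head3 = RefineHead(c, rng)

    # ---- input handling --------------------------------------------------
    def _prepare(self, image: np.ndarray) -> Tensor:
        """Grayscale H×W / (N,H,W) array in [0,1] -> NCHW tensor."""
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected H×W or N×H×W image, got {arr.shape}")
        N, H, W = arr.shape
        d = self.cfg.size_divisor
        if H % d or W % d:
            if self.cfg.resize_policy == "resize":
                from skimage.transform import resize as _resize

                H2, W2 = max(d, H // d * d), max(d, W // d * d)
                arr = np.stack([_resize(a, (H2, W2), order=1, anti_aliasing=False) for a in arr])
            else:
                raise ValueError(
                    f"input size {H}x{W} not divisible by {d} "
                    "(set resize_policy='resize' to auto-resize)"
                )
        x = np.repeat(arr[:, None], self.cfg.in_channels, axis=1)
        return Tensor(x)

    def backbone_features(self, image) -> BackboneFeatures:
        return self.backbone(self._prepare(image))

    def global_map(self, f3, f4, f5) -> Tensor:
        if self.cfg.use_dilated and not (f3.shape[2:] == f4.shape[2:] == f5.shape[2:]):
            raise ValueError("f3, f4, f5 must share a spatial size")
        return self.global_head(f3, f4, f5)

    def forward(self, image) -> SideOutputs:
        x = self._prepare(image) if not isinstance(image, Tensor) else image
        N, _, H, W = x.shape
        feats = self.backbone(x)
        f3, f4, f5 = feats.high_level()
        if self.cfg.use_rsp:
            f3, f4, f5 = self.rsp3(f3), self.rsp4(f4), self.rsp5(f5)
        s0 = self.global_head(f3, f4, f5)  # at f3's size
        maps_native = {"S0": s0}
        attention: dict[str, Tensor] = {}
        attended: dict[str, Tensor] = {}
        if self.cfg.use_attention:
            s_prev = s0
            for name, f, head, idx in (
                ("S1", f5, self.head5, 5),
                ("S2", f4, self.head4, 4),
                ("S3", f3, self.head3, 3),
            ):
                s_in = upsample_bilinear(s_prev, f.shape[2], f.shape[3])
                a, r, s = reverse_attention_step(f, s_in, head)
                attention[f"A{idx}"] = a
                attended[f"R{idx}"] = r
                maps_native[name] = s
                s_prev = s
        maps = {
            k: upsample_bilinear(v, H, W) for k, v in maps_native.items()
        }
        return SideOutputs(maps=maps, attention=attention, attended=attended)

    def predict_proba(self, image) -> np.ndarray:
        """Probability map(s) from the final side output, at input size."""
        out = self.forward(image)
        prob = 1.0 / (1.0 + np.exp(-out.final().data))
        return prob[:, 0] if prob.shape[0] > 1 else prob[0, 0]

    def predict_mask(self, image, threshold: float = 0.5) -> np.ndarray:
        """Binarized prediction: sigmoid(final logits) >= threshold."""
        return (self.predict_proba(image) >= threshold).astype(np.uint8)


# ---- checkpoints ---------------------------------------------------------

def save_checkpoint(path, model: SSPNet, extra: dict | None = None) -> None:
    """Single-file .npz checkpoint: weights + config JSON + config hash."""
    meta = {
        "config": json.dumps(asdict(model.cfg)),
        "config_hash": model.cfg.config_hash(),
        **(extra or {}),
    }
    np.savez(
        path,
        __meta__=np.array(json.dumps(meta)),
        **{k: v for k, v in model.state_dict().items()},
    )


def load_checkpoint(path) -> tuple[SSPNet, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg = NetworkConfig(**json.loads(meta["config"]))
        model = SSPNet(cfg)
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model, meta
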