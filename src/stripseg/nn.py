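"""Minimal neural-network layer library on top of :mod:`stripseg.autodiff`.

Modules hold named parameters (plain :class:`~stripseg.autodiff.Tensor`
objects), support recursive parameter collection, and serialize to/from flat
``name -> ndarray`` dicts so checkpoints are simple ``.npz`` files.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, relu

__all__ = ["Module", "Conv2d", "Sequential", "Adam"]


class Module:
    """Base class: tracks sub-modules and parameters by attribute name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """2-D convolution layer with He-normal initialization."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel_size: int | tuple[int, int] = 3,
        stride: int = 1,
        padding: int | None = None,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if padding is None:  # "same" for stride 1, odd kernels
            padding = (dilation * (kh - 1) // 2, dilation * (kw - 1) // 2)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kh * kw
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, (out_ch, in_ch, kh, kw)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding, dilation=self.dilation,
        )


class ChannelNorm(Module):
    """Per-channel spatial normalization (instance-norm style, no running
    statistics): each channel of each sample is standardized over H×W, then
    rescaled by learned gain/offset.  Batch-independent, hence deterministic
    at any batch size."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gain = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.offset = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gain + self.offset


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, m in enumerate(layers):
            setattr(self, f"layer{i}", m)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


def conv_relu(in_ch, out_ch, rng, **kw) -> Sequential:
    class _ReLU(Module):
        def forward(self, x):
            return relu(x)

    return Sequential(Conv2d(in_ch, out_ch, rng=rng, **kw), _ReLU())


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
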