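"""Layer/module abstraction over the autograd primitives.

Modules own named parameters and compose hierarchically; ``state_dict`` /
``load_state_dict`` give flat name->array views used by the checkpoint
format.  Weight initialization is He-normal (fan-in) from an explicit
``numpy.random.Generator`` so that model construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from . import functional as F


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        p = Tensor(array.astype(np.float32), requires_grad=True)
        self._params[name] = p
        return p

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

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(self._list):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        self.padding = kernel // 2 if padding is None else padding
        self.w = self.register("weight", _he(rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel**2))
        self.b = self.register("bias", np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.w, self.b, padding=self.padding)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        self.padding = kernel // 2 if padding is None else padding
        self.w = self.register("weight", _he(rng, (out_ch, in_ch, kernel, kernel, kernel), in_ch * kernel**3))
        self.b = self.register("bias", np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.w, self.b, padding=self.padding)


class ConvTranspose2d(Module):
    """Kernel-2, stride-2 learned upsampling."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 2):
        super().__init__()
        self.kernel = kernel
        self.w = self.register("weight", _he(rng, (in_ch, out_ch, kernel, kernel), in_ch * kernel**2))
        self.b = self.register("bias", np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.w, self.b, kernel=self.kernel)


class ConvTranspose3d(Module):
    """In-plane learned upsampling for volumetric features (kernel (1,2,2))."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: tuple[int, int, int] = (1, 2, 2)):
        super().__init__()
        self.kernel = kernel
        fan = in_ch * int(np.prod(kernel))
        self.w = self.register("weight", _he(rng, (in_ch, out_ch, *kernel), fan))
        self.b = self.register("bias", np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d(x, self.w, self.b, kernel=self.kernel)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.register("weight", _he(rng, (in_f, out_f), in_f))
        self.b = self.register("bias", np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class ChannelNorm2d(Module):
    """Instance normalization with a learnable per-channel affine.

    Statistics are taken per sample and channel over the spatial axes, so
    the layer behaves identically in training and inference (no running
    averages, no batch coupling).
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = self.register("gamma", np.ones(channels))
        self.beta = self.register("beta", np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=(2, 3), keepdims=True)
        xhat = centred * (var + self.eps) ** -0.5
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
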