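"""Layer modules built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError, ShapeError
from .autodiff import Parameter, Tensor, batch_norm, conv3d, matmul

__all__ = ["Module", "Conv3d", "Linear", "BatchNorm3d", "Dropout"]


class Module:
    """Minimal module container: tracks parameters, submodules and train mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        yield self
        for m in self._mods.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for mname, m in self._mods.items():
            yield from m.named_parameters(prefix=f"{prefix}{mname}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self._all_buffers().items():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        buffers = self._all_buffers()
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for name, buf in buffers.items():
            buf[...] = state[name]

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def _all_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {f"{prefix}{k}": v for k, v in self._buffers().items()}
        for mname, m in self._mods.items():
            out.update(m._all_buffers(prefix=f"{prefix}{mname}."))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv3d(Module):
    """3D convolution; He-initialized, optional bias."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1, padding: int = 0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.kernel, self.stride, self.padding = cin, cout, kernel, stride, padding
        fan_in = cin * kernel**3
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DownsampleConv3d(Conv3d):
    """Stride-2 convolution with an even kernel: exact spatial halving, no pooling.

    An even kernel with stride 2 tiles the input without the half-voxel offset
    an odd kernel would introduce.
    """

    def __init__(self, cin: int, cout: int, kernel: int = 2, rng=None):
        if kernel % 2 != 0:
            raise ConfigurationError("downsampling kernel size must be even")
        pad = (kernel - 2) // 2
        super().__init__(cin, cout, kernel, stride=2, padding=pad, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        spatial = x.data.shape[2:]
        if any(n % 2 for n in spatial):
            raise ShapeError(f"stride-2 downsampling needs even spatial dims, got {spatial}")
        return super().__call__(x)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = np.sqrt(1.0 / fin)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(fin, fout)))
        self.bias = Parameter(np.zeros(fout))

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float = 0.5):
        super().__init__()
        if not 0 <= p < 1:
            raise ConfigurationError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng()

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
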