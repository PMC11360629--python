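"""Neural-network layers built on the autograd tensor.

Parameters are float32 :class:`~ecganoise.nn.tensor.Tensor` leaves with
``requires_grad=True``.  Modules follow the familiar container protocol:
``parameters()``, ``state_dict()``/``load_state_dict()``, ``train()``/
``eval()`` (batch normalization switches between batch and running
statistics), and ``freeze()`` to exclude a subtree from optimization.
"""

from __future__ import annotations

from typing import Dict, Iterator, List

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    def __init__(self):
        self._params: Dict[str, Tensor] = {}
        self._modules: Dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Tensor]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple]:
        for k, p in self._params.items():
            yield f"{prefix}{k}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def freeze(self, frozen: bool = True):
        """Exclude (or re-include) every parameter from gradient updates."""
        for p in self.parameters():
            p.requires_grad = not frozen
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters(prefix)}
        for k, v in self._buffers().items():
            out[f"{prefix}{k}"] = v.copy()
        for name, m in self._modules.items():
            out.update(m.state_dict(f"{prefix}{name}."))
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray], prefix: str = ""):
        for k, p in self.named_parameters(prefix):
            p.data = state[k].copy()
        self._load_buffers(state, prefix)

    def _buffers(self) -> Dict[str, np.ndarray]:
        return {}

    def _load_buffers(self, state, prefix):
        for k in self._buffers():
            full = f"{prefix}{k}"
            if full in state:
                setattr(self, k, state[full].copy())
        for name, m in self._modules.items():
            m._load_buffers(state, f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


#: Parameter dtype; float32 keeps BLAS convolutions fast on one CPU.
DTYPE = np.float32


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
    return Tensor(w.astype(DTYPE), requires_grad=True)


class Conv1d(Module):
    """Same-padded, stride-1 1D convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = _he_init(rng, (out_ch, in_ch, kernel), in_ch * kernel)
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv1d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _he_init(rng, (in_f, out_f), in_f)
        self.bias = Tensor(np.zeros(out_f, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.matmul(x, self.weight) + self.bias


class BatchNorm1d(Module):
    """Batch normalization over (batch, length) per channel, shape (B, C, L)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, channels, 1), dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1), dtype=DTYPE), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros((1, channels, 1), dtype=DTYPE)
        self.running_var = np.ones((1, channels, 1), dtype=DTYPE)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = T.mean(x, axis=(0, 2), keepdims=True)
            var = T.mean((x - mu) ** 2, axis=(0, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = ((x - Tensor(self.running_mean))
                    * Tensor((self.running_var + self.eps) ** -0.5))
        return self.gamma * xhat + self.beta


class PReLU(Module):
    """Parametric ReLU with one learned slope per channel."""

    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.slope = Tensor(np.full((1, channels, 1), init, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.prelu(x, self.slope)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.2):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return T.leaky_relu(x, self.negative_slope)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers: List[Module] = []
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
            self.layers.append(layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ResidualBlock1d(Module):
    """conv-BN-act, conv-BN, plus identity shortcut (1x1 conv on channel change)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 activation: str = "relu"):
        super().__init__()
        self.conv1 = Conv1d(in_ch, out_ch, kernel, rng)
        self.bn1 = BatchNorm1d(out_ch)
        self.conv2 = Conv1d(out_ch, out_ch, kernel, rng)
        self.bn2 = BatchNorm1d(out_ch)
        self.act1 = PReLU(out_ch) if activation == "prelu" else _ReLU()
        self.act2 = PReLU(out_ch) if activation == "prelu" else _ReLU()
        self.shortcut = Conv1d(in_ch, out_ch, 1, rng, bias=False) if in_ch != out_ch else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.act1(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        s = self.shortcut(x) if self.shortcut is not None else x
        return self.act2(h + s)


class _ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)
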