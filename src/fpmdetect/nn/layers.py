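"""Module system: layers with parameters, built on the Tensor engine.

Initialization mirrors torch defaults (Kaiming-uniform fan-in for conv and
linear weights) so hyperparameters transplanted from reference recipes behave
comparably.  Every module draws its init from an explicit numpy Generator for
bit-stable construction.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from . import functional as F
from .tensor import Tensor, concatenate, softmax


class Module:
    def __init__(self) -> None:
        self._params: Dict[str, Tensor] = {}
        self._modules: Dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        object.__setattr__(self, name, module)
        return module

    def parameters(self) -> List[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for k, v in self._params.items():
            yield prefix + k, v
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        i = 0
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
                i += 1
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=float).reshape(p.shape)
        i = 0
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bn{i}.running_mean"], dtype=float)
                m.running_var = np.asarray(state[f"__bn{i}.running_var"], dtype=float)
                i += 1

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(
            _kaiming_uniform(rng, (out_features, in_features), in_features),
            requires_grad=True,
        )
        self.bias = (
            Tensor(_kaiming_uniform(rng, (out_features,), in_features), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose(1, 0)
        return y + self.bias if self.bias is not None else y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            _kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in),
            requires_grad=True,
        )
        self.bias = (
            Tensor(_kaiming_uniform(rng, (out_ch,), fan_in), requires_grad=True)
            if bias
            else None
        )
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            _kaiming_uniform(rng, (in_ch, out_ch, kernel, kernel), fan_in),
            requires_grad=True,
        )
        self.bias = (
            Tensor(_kaiming_uniform(rng, (out_ch,), fan_in), requires_grad=True)
            if bias
            else None
        )
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Tensor(np.ones(channels), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.relu() - (-x).relu() * self.slope


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self.register(str(i), m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)


class Embedding(Module):
    def __init__(self, num: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0, 1.0, size=(num, dim)), requires_grad=True)

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=int)]


class MultiheadAttention(Module):
    """Batched scaled-dot-product attention with ``heads`` parallel heads.

    Inputs are (B, L, D); q/k may carry additive positional terms supplied by
    the caller before projection.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ValueError("hidden_dim must be divisible by heads")
        self.dim = dim
        self.heads = heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def _split(self, x: Tensor, b: int, l: int) -> Tensor:
        hd = self.dim // self.heads
        return x.reshape(b, l, self.heads, hd).transpose(0, 2, 1, 3)

    def forward(
        self,
        query: Tensor,
        key: Tensor,
        value: Tensor,
        logit_bias: Optional[np.ndarray] = None,
    ) -> Tensor:
        """``logit_bias`` (Lq, Lk) is added to the pre-softmax scores of every
        head (e.g. a spatial locality prior)."""
        b, lq, _ = query.shape
        lk = key.shape[1]
        hd = self.dim // self.heads
        q = self._split(self.q_proj(query), b, lq)
        k = self._split(self.k_proj(key), b, lk)
        v = self._split(self.v_proj(value), b, lk)
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(hd))
        if logit_bias is not None:
            scores = scores + Tensor(logit_bias[None, None])
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, lq, self.dim)
        return self.out_proj(out)


class MLP(Module):
    """Simple ReLU MLP head (DETR-style 3-layer box head)."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        super().__init__()
        self.layers = Sequential(
            *[Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        )

    def forward(self, x: Tensor) -> Tensor:
        mods = self.layers.mods
        for i, m in enumerate(mods):
            x = m(x)
            if i < len(mods) - 1:
                x = x.relu()
        return x
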