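"""Dense layers, batch normalization and MLP stacks on the autodiff core."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["Module", "Linear", "BatchNorm1d", "MLP"]


class Module:
    """Base class: parameter registry plus train/eval mode switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def _submodules(self) -> list["Module"]:
        mods: list[Module] = []
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.append(value)
            elif isinstance(value, (list, tuple)):
                mods.extend(v for v in value if isinstance(v, Module))
        return mods

    def train(self) -> "Module":
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # flat state dict of raw arrays, keyed by attribute path
    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value.data
            elif isinstance(value, np.ndarray):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.state_arrays(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(prefix=f"{key}.{i}."))
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                if arrays[key].shape != value.data.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{arrays[key].shape} vs {value.data.shape}"
                    )
                value.data = np.array(arrays[key], dtype=np.float64)
            elif isinstance(value, np.ndarray):
                setattr(self, name, np.array(arrays[key], dtype=np.float64))
            elif isinstance(value, Module):
                value.load_state_arrays(arrays, prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_arrays(arrays, prefix=f"{key}.{i}.")


class Linear(Module):
    """Affine map ``x @ W + b`` with Kaiming-uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.in_dim = in_dim
        self.out_dim = out_dim
        rng = rng if rng is not None else np.random.default_rng()
        bound = np.sqrt(6.0 / in_dim)
        self.W = Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return as_tensor(x) @ self.W + self.b


class BatchNorm1d(Module):
    """Batch normalization over axis 0.

    Training mode normalizes with per-batch statistics and updates running
    averages; evaluation mode uses the running averages only, so forward
    passes are deterministic functions of the input.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbiased = var.data * (n / max(n - 1, 1))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased.ravel()
            )
            norm = centered / ((var + self.eps) ** 0.5)
        else:
            norm = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return norm * self.gamma + self.beta


class MLP(Module):
    """Stack of Linear (+ optional BatchNorm) + ReLU blocks, linear head.

    ``final`` selects the output activation: ``"linear"`` or ``"sigmoid"``.
    """

    def __init__(
        self,
        dims: Sequence[int],
        rng: Optional[np.random.Generator] = None,
        batchnorm: bool = True,
        final: str = "linear",
    ):
        super().__init__()
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        if final not in ("linear", "sigmoid"):
            raise ValueError(f"unknown final activation: {final}")
        rng = rng if rng is not None else np.random.default_rng()
        self.dims = tuple(int(d) for d in dims)
        self.final = final
        self.linears = [
            Linear(a, b, rng=rng) for a, b in zip(self.dims[:-1], self.dims[1:])
        ]
        self.norms = (
            [BatchNorm1d(d) for d in self.dims[1:-1]] if batchnorm else []
        )

    def __call__(self, x: Tensor) -> Tensor:
        h = as_tensor(x)
        last = len(self.linears) - 1
        for i, lin in enumerate(self.linears):
            h = lin(h)
            if i < last:
                if self.norms:
                    h = self.norms[i](h)
                h = h.relu()
        if self.final == "sigmoid":
            h = h.sigmoid()
        return h
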