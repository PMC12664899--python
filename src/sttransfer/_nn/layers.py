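"""Layers and an Adam optimizer on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                yield from (m for m in v if isinstance(m, Module))

    def train(self):
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters and buffers."""
        out: dict[str, np.ndarray] = {}

        def walk(mod: Module, prefix: str):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Tensor):
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        current = {}

        def walk(mod: Module, prefix: str):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, (Tensor, np.ndarray)):
                    current[key] = (mod, name, v)
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        for key, arr in arrays.items():
            if key not in current:
                raise KeyError(f"unknown state entry {key!r}")
            mod, name, v = current[key]
            if isinstance(v, Tensor):
                v.data = np.asarray(arr, dtype=np.float64)
            else:
                setattr(mod, name, np.asarray(arr))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (n_in + n_out))  # Glorot
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm1d(Module):
    """Feature-wise normalization; batch statistics while training, running
    statistics (exponential moving average, momentum 0.1) at inference."""

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            xhat = centered / (var + self.eps).sqrt()
            m = self.momentum
            n = x.data.shape[0]
            unbiased = var.data[0] * (n / max(n - 1, 1))
            self.running_mean = (1 - m) * self.running_mean + m * mu.data[0]
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            xhat = (x - self.running_mean) * (1.0 / np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
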