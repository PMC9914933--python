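"""Neural-network layers and optimisation on top of :mod:`ricerisk.autodiff`."""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A tensor that is updated by the optimiser."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; collects parameters from attributes recursively."""

    training: bool = True

    def parameters(self) -> List[Parameter]:
        params: List[Parameter] = []
        seen = set()

        def collect(obj) -> None:
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def train(self) -> None:
        self.training = True
        for v in vars(self).values():
            for m in _submodules(v):
                m.train()

    def eval(self) -> None:
        self.training = False
        for v in vars(self).values():
            for m in _submodules(v):
                m.eval()

    def state_dict(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Iterable[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data[...] = s


def _submodules(obj):
    if isinstance(obj, Module):
        yield obj
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            yield from _submodules(v)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class Embedding(Module):
    """Lookup table: integer indices -> learned vectors."""

    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n, d)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ad.getitem(self.weight, np.asarray(idx, dtype=int))


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = ad.tmean(x, axis=-1, keepdims=True)
        centred = ad.sub(x, mu)
        var = ad.tmean(ad.mul(centred, centred), axis=-1, keepdims=True)
        inv = ad.power(ad.add(var, self.eps), -0.5)
        return ad.add(ad.mul(ad.mul(centred, inv), self.gamma), self.beta)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return ad.mul(x, mask)


class Conv1dSame(Module):
    """Kernel-K 1-D convolution over the time axis with same-padding."""

    def __init__(self, d_in: int, d_out: int, kernel: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(d_in * kernel)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(kernel, d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d_same(x, self.weight, self.bias)


class Adam:
    """Adam optimiser with bias correction."""

    def __init__(self, params: List[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
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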