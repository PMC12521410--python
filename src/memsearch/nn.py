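"""Layers and optimizers on top of the autodiff core: GRU cell, linear maps,
and Adam.  Parameter initialization follows the usual uniform(-1/sqrt(d),
1/sqrt(d)) recipe for recurrent cells, seeded through an explicit generator.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class ParamStore:
    """A flat, ordered name -> Tensor parameter dictionary."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}

    def add(self, name: str, data: np.ndarray, trainable: bool = True) -> Tensor:
        t = Tensor(np.asarray(data, dtype=np.float64), requires_grad=trainable)
        self._params[name] = t
        return t

    def __getitem__(self, name: str) -> Tensor:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def names(self) -> list[str]:
        return list(self._params)

    def trainable(self) -> list[Tensor]:
        return [t for t in self._params.values() if t.requires_grad]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self._params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state dict")
            if state[k].shape != t.data.shape:
                raise ValueError(
                    f"shape mismatch for {k!r}: {state[k].shape} vs {t.data.shape}"
                )
            t.data = np.asarray(state[k], dtype=np.float64).copy()

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self._params.values())


def uniform_init(
    rng: np.random.Generator, shape: tuple[int, ...], scale: float
) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


class GRUCell:
    """Gated recurrent unit, torch gate conventions.

    r = sigmoid(x Wxr + h Whr + br);  z = sigmoid(x Wxz + h Whz + bz)
    n = tanh(x Wxn + bn + r * (h Whn + bhn));  h' = (1-z) n + z h
    """

    def __init__(
        self,
        store: ParamStore,
        prefix: str,
        input_dim: int,
        hidden_dim: int,
        rng: np.random.Generator,
    ):
        self.d = hidden_dim
        s = 1.0 / np.sqrt(hidden_dim)
        self.Wx = store.add(f"{prefix}.Wx", uniform_init(rng, (input_dim, 3 * hidden_dim), s))
        self.Wh = store.add(f"{prefix}.Wh", uniform_init(rng, (hidden_dim, 3 * hidden_dim), s))
        self.bx = store.add(f"{prefix}.bx", uniform_init(rng, (3 * hidden_dim,), s))
        self.bh = store.add(f"{prefix}.bh", uniform_init(rng, (3 * hidden_dim,), s))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        d = self.d
        gi = x @ self.Wx + self.bx  # (B, 3d)
        gh = h @ self.Wh + self.bh
        r = ad.sigmoid(gi[:, 0:d] + gh[:, 0:d])
        z = ad.sigmoid(gi[:, d : 2 * d] + gh[:, d : 2 * d])
        n = ad.tanh(gi[:, 2 * d : 3 * d] + r * gh[:, 2 * d : 3 * d])
        return (1.0 - z) * n + z * h


class Linear:
    def __init__(
        self,
        store: ParamStore,
        prefix: str,
        input_dim: int,
        output_dim: int,
        rng: np.random.Generator,
        bias: bool = True,
    ):
        s = 1.0 / np.sqrt(input_dim)
        self.W = store.add(f"{prefix}.W", uniform_init(rng, (input_dim, output_dim), s))
        self.b = store.add(f"{prefix}.b", uniform_init(rng, (output_dim,), s)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Adam:
    """Adam with the standard bias correction (no weight decay)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
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
        ad.zero_grads(self.params)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]
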