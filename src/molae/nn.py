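"""Recurrent layers, linear maps and Adam, built on :mod:`molae.autodiff`.

Conventions (these fix the exact trainable-parameter counts the package
reports):

* ``Linear(d_in, d_out)``: weight ``(d_in, d_out)`` plus bias ``(d_out,)``
  -> ``d_in*d_out + d_out`` parameters.
* ``GRULayer``: input and recurrent weights for the three gates (reset,
  update, candidate) each with its own bias vector ->
  ``3H(d_in + H) + 6H`` parameters.
* ``LSTMLayer``: four gates (input, forget, cell, output), two bias
  vectors -> ``4H(d_in + H) + 8H`` parameters.

Weights are initialized uniform in ``±1/sqrt(fan)`` (``fan`` = hidden size
for recurrent layers, input width for linear maps) from a seeded generator.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat


class Module:
    """Base: anything with an ordered list of named parameters."""

    def parameters(self) -> list[tuple[str, Tensor]]:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for _, p in self.parameters())


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], bound: float) -> Tensor:
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str = "linear"):
        bound = 1.0 / np.sqrt(d_in)
        self.name = name
        self.W = _uniform(rng, (d_in, d_out), bound)
        self.b = _uniform(rng, (d_out,), bound)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [(f"{self.name}.W", self.W), (f"{self.name}.b", self.b)]


class GRULayer(Module):
    """Single GRU layer; gate order (reset, update, candidate)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, name: str = "gru"):
        bound = 1.0 / np.sqrt(hidden)
        self.hidden = hidden
        self.name = name
        self.W_ih = _uniform(rng, (d_in, 3 * hidden), bound)
        self.W_hh = _uniform(rng, (hidden, 3 * hidden), bound)
        self.b_ih = _uniform(rng, (3 * hidden,), bound)
        self.b_hh = _uniform(rng, (3 * hidden,), bound)

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden
        gi = x @ self.W_ih + self.b_ih
        gh = h @ self.W_hh + self.b_hh
        r = (gi.narrow(0, H) + gh.narrow(0, H)).sigmoid()
        z = (gi.narrow(H, 2 * H) + gh.narrow(H, 2 * H)).sigmoid()
        n = (gi.narrow(2 * H, 3 * H) + r * gh.narrow(2 * H, 3 * H)).tanh()
        return (1.0 - z) * n + z * h

    def parameters(self):
        return [
            (f"{self.name}.W_ih", self.W_ih),
            (f"{self.name}.W_hh", self.W_hh),
            (f"{self.name}.b_ih", self.b_ih),
            (f"{self.name}.b_hh", self.b_hh),
        ]


class LSTMLayer(Module):
    """Single LSTM layer; gate order (input, forget, cell, output)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, name: str = "lstm"):
        bound = 1.0 / np.sqrt(hidden)
        self.hidden = hidden
        self.name = name
        self.W_ih = _uniform(rng, (d_in, 4 * hidden), bound)
        self.W_hh = _uniform(rng, (hidden, 4 * hidden), bound)
        self.b_ih = _uniform(rng, (4 * hidden,), bound)
        self.b_hh = _uniform(rng, (4 * hidden,), bound)

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden
        g = x @ self.W_ih + self.b_ih + h @ self.W_hh + self.b_hh
        i = g.narrow(0, H).sigmoid()
        f = g.narrow(H, 2 * H).sigmoid()
        cand = g.narrow(2 * H, 3 * H).tanh()
        o = g.narrow(3 * H, 4 * H).sigmoid()
        c_new = f * c + i * cand
        return o * c_new.tanh(), c_new

    def parameters(self):
        return [
            (f"{self.name}.W_ih", self.W_ih),
            (f"{self.name}.W_hh", self.W_hh),
            (f"{self.name}.b_ih", self.b_ih),
            (f"{self.name}.b_hh", self.b_hh),
        ]


class AdditiveAttention(Module):
    """Additive self-attention pooling over encoder step outputs:
    ``score_t = v . tanh(W h_t + b)``, softmax over unmasked steps,
    context = weighted sum of the step outputs."""

    def __init__(self, hidden: int, rng: np.random.Generator, name: str = "attention"):
        self.name = name
        self.proj = Linear(hidden, hidden, rng, name=f"{name}.proj")
        self.v = _uniform(rng, (hidden, 1), 1.0 / np.sqrt(hidden))

    def scores(self, steps: list[Tensor]) -> Tensor:
        cols = [self.proj(h).tanh() @ self.v for h in steps]  # each (B, 1)
        return concat(cols)  # (B, T)

    def parameters(self):
        return self.proj.parameters() + [(f"{self.name}.v", self.v)]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 0.005,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(p.shape) for p in params]
        self.v = [np.zeros(p.shape) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
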