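"""Recurrent layers and the NAdam optimizer used by the adversarial trainer.

The sequence networks here are deliberately small: single-layer LSTMs with
8-64 units, an affine read-out, and optional bidirectionality.  All
parameters live in plain dicts of :class:`~magefc.autodiff.Tensor` so they
serialize trivially to HDF5.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, lstm_cell, stack, unbind_time

__all__ = ["Dense", "LSTM", "BiLSTM", "NAdam", "collect_params"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Dense:
    """Affine map ``x @ W + b`` (the f(.) read-out of each network)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self) -> dict:
        return {"W": self.W, "b": self.b}


class LSTM:
    """Single-layer unidirectional LSTM over (batch, time, features) input.

    Gates are computed with one fused matmul per step; the forget gate
    carries a +1 bias at initialization (standard practice for gradient
    flow through long sequences).
    """

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.n_in = n_in
        self.n_units = n_units
        self.Wx = Tensor(_glorot(rng, n_in, 4 * n_units), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, n_units, 4 * n_units), requires_grad=True)
        b = np.zeros(4 * n_units)
        b[n_units : 2 * n_units] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def params(self) -> dict:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def __call__(self, xs: Tensor, reverse: bool = False) -> Tensor:
        """Run over the time axis; returns hidden states (B, T, units)."""
        B, T, _ = xs.shape
        H = self.n_units
        # project all inputs in one matmul; the loop then only carries the
        # recurrent matmul and the fused cell update
        xproj = (xs.reshape(B * T, self.n_in) @ self.Wx + self.b).reshape(B, T, 4 * H)
        x_slices = unbind_time(xproj)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs: list[Tensor] = []
        times = range(T - 1, -1, -1) if reverse else range(T)
        for t in times:
            gates = x_slices[t] + h @ self.Wh
            h, c = lstm_cell(gates, c)
            outs.append(h)
        if reverse:
            outs = outs[::-1]
        return stack(outs, axis=1)


class BiLSTM:
    """Bidirectional LSTM: forward and backward passes concatenated."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.fwd = LSTM(n_in, n_units, rng)
        self.bwd = LSTM(n_in, n_units, rng)

    def params(self) -> dict:
        out = {}
        for name, layer in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in layer.params().items():
                out[f"{name}_{k}"] = v
        return out

    def __call__(self, xs: Tensor) -> Tensor:
        return concat([self.fwd(xs), self.bwd(xs, reverse=True)], axis=-1)


def collect_params(*modules, extra: dict | None = None) -> dict:
    """Flatten module parameter dicts into one name->Tensor mapping."""
    out: dict[str, Tensor] = {}
    for i, mod in enumerate(modules):
        prefix = getattr(mod, "name", mod.__class__.__name__.lower() + str(i))
        for k, v in mod.params().items():
            out[f"{prefix}.{k}"] = v
    if extra:
        out.update(extra)
    return out


class NAdam:
    """Nesterov-accelerated Adam (Dozat 2016).

    Matches the reference update: m-hat mixes the momentum-extrapolated
    first moment with the current gradient.  Gradient-norm clipping is
    applied across the whole parameter set before the update.
    """

    def __init__(
        self,
        params: dict,
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float | None = 1.0,
    ):
        self.params = dict(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        grads = {k: p.grad for k, p in self.params.items() if p.grad is not None}
        if not grads:
            return
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2, t = self.beta1, self.beta2, self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = b1 * self.m[k] / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1**t)
            v_hat = self.v[k] / (1 - b2**t)
            self.params[k].data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
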