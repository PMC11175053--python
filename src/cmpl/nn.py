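"""Neural-network building blocks: layers, losses, and a plain SGD optimizer.

Layers hold their parameters as :class:`~cmpl._autodiff.Tensor` objects with
``requires_grad=True``; initialization is deterministic given a
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, conv1d, log_softmax, relu

__all__ = [
    "Linear",
    "Conv1d",
    "Module",
    "SGD",
    "cross_entropy",
    "soft_cross_entropy",
    "relu",
]


class Module:
    """Base class: anything with a flat list of parameter tensors."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state/parameter count mismatch")
        for p, s in zip(params, state):
            p.data = s.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Temporal convolution over (batch, time, channels)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ):
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(kernel, c_in, c_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class SGD:
    """Plain stochastic gradient descent with optional classical momentum
    and global gradient-norm clipping."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float,
        momentum: float = 0.0,
        clip_norm: float | None = None,
    ):
        if lr < 0:
            raise ValueError("lr must be >= 0")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in params] if momentum else None

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float(np.sum(p.grad**2)) for p in self.params if p.grad is not None)
            )
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad if scale == 1.0 else p.grad * scale
            if self._velocity is not None:
                self._velocity[i] = self.momentum * self._velocity[i] + g
                p.data -= self.lr * self._velocity[i]
            else:
                p.data -= self.lr * g

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cross_entropy(
    logits: Tensor, labels: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """Mean cross entropy against hard integer labels.

    ``weights`` (optional, per-sample, >= 0) rescale each sample's
    contribution; the mean is taken over the *batch size*, so zero-weight
    samples contribute exactly nothing while keeping the normalization
    stable (used by the exclude noise mode).
    """
    labels = np.asarray(labels, dtype=np.int64)
    lp = log_softmax(logits, axis=-1)
    nll = -lp.take_rows(labels)
    if weights is not None:
        nll = nll * np.asarray(weights, dtype=np.float64)
    return nll.mean()


def soft_cross_entropy(logits: Tensor, target_probs: np.ndarray) -> Tensor:
    """Mean cross entropy H(p, q) with a fixed target distribution ``p``.

    The target is a plain array, i.e. detached from the graph by
    construction — gradients flow only through ``logits``.
    """
    lp = log_softmax(logits, axis=-1)
    per_sample = -(Tensor(np.asarray(target_probs, dtype=np.float64)) * lp).sum(axis=-1)
    return per_sample.mean()
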