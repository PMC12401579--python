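"""Minimal feed-forward neural network core: dense layers, a 1x1 convolution,
Adam, categorical cross-entropy, and early stopping.

The networks here are small multilayer perceptrons with a softmax head,
trained by mini-batch Adam on categorical cross-entropy.  Implemented
directly on numpy so that training is bit-reproducible given a seed on a
single thread, and so the 1x1-convolution benchmark head shares the same
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

EPS = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def cross_entropy(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean categorical cross-entropy  -sum_i y_i log(y_hat_i)  over the batch.

    ``y`` is one-hot, ``y_hat`` row-normalized probabilities (clipped away
    from zero before the log).
    """
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs y_hat {y_hat.shape}")
    p = np.clip(y_hat, EPS, 1.0)
    return float(-(y * np.log(p)).sum(axis=1).mean())


class Dense:
    """Fully connected layer, Glorot-uniform initialized."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []


class Conv1x1:
    """K kernels of size 1x1 with shared weights over all positions.

    Each kernel k maps the single-channel input feature map x (here the
    flattened gene x hallmark tensor) to ``w_k * x + b_k``; 'same' padding is
    trivial for a 1x1 kernel, so the output has K channels of the original
    size, flattened channel-minor to ``n_features * K`` columns.
    """

    def __init__(self, n_kernels: int, rng: np.random.Generator):
        self.K = n_kernels
        self.w = rng.normal(0.0, 1.0, size=n_kernels)
        self.b = np.zeros(n_kernels)
        self._x: np.ndarray | None = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        n, F = x.shape
        out = x[:, :, None] * self.w[None, None, :] + self.b[None, None, :]
        return out.reshape(n, F * self.K)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, FK = grad.shape
        g = grad.reshape(n, FK // self.K, self.K)
        self.dw = np.einsum("nfk,nf->k", g, self._x)
        self.db = g.sum(axis=(0, 1))
        return np.einsum("nfk,k->nf", g, self.w)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Network:
    """A sequence of layers ending in a linear logit layer + softmax head."""

    def __init__(self, layers: Sequence):
        self.layers = list(layers)

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x))

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for (p, _), w in zip(self.params(), weights):
            p[...] = w


class Adam:
    """Adam optimizer with the standard defaults (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p, _ in params]
            self.v = [np.zeros_like(p) for p, _ in params]
        self.t += 1
        for (p, g), m, v in zip(params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class EarlyStopper:
    """Stop when the monitored loss fails to decline for ``patience``
    consecutive epochs.

    Decline is measured against the best loss so far and must exceed
    ``min_delta`` to count (declines below that resolution are treated as
    flat, so training does not grind on through float-precision noise).
    """

    patience: int = 5
    min_delta: float = 0.0
    best: float = np.inf
    wait: int = 0

    def update(self, loss: float) -> bool:
        """Record an epoch loss; return True when training should stop."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.wait = 0
        else:
            self.wait += 1
        return self.wait >= self.patience


@dataclass
class FitResult:
    history: list[float] = field(default_factory=list)
    stopped_early: bool = False
    n_epochs: int = 0


def fit(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_classes: int,
    lr: float = 1e-3,
    batch_size: int = 200,
    max_epochs: int = 200,
    patience: int = 5,
    min_delta: float = 0.0,
    rng: np.random.Generator,
) -> FitResult:
    """Mini-batch Adam training on categorical cross-entropy.

    The monitored quantity is the full-training-set loss evaluated after
    each epoch; training stops at ``max_epochs`` or when that loss has not
    declined for ``patience`` consecutive epochs, whichever comes first.
    Raises on a non-finite loss.
    """
    n = len(X)
    Y = one_hot(y, n_classes)
    opt = Adam(lr=lr)
    stopper = EarlyStopper(patience=patience, min_delta=min_delta)
    result = FitResult()
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], Y[idx]
            probs = softmax(net.logits(xb, train=True))
            batch_loss = cross_entropy(yb, probs)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            net.backward((probs - yb) / len(idx))
            opt.step(net.params())
        epoch_loss = cross_entropy(Y, softmax(net.logits(X)))
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        result.history.append(epoch_loss)
        result.n_epochs = epoch
        if stopper.update(epoch_loss):
            result.stopped_early = True
            break
    return result
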