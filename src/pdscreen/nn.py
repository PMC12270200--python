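"""Minimal feed-forward neural-network engine with Monte-Carlo dropout.

Dense layers, ReLU, inverted dropout, layer normalisation, a numerically
stable sigmoid / binary-cross-entropy head, three optimizers (SGD with
momentum, AdamW, RMSprop) and two learning-rate schedulers, with
reverse-mode gradients written out by hand.

Dropout is *stochastic whenever a generator is supplied* — during training
and during Monte-Carlo inference — and the identity otherwise. This is the
mechanism behind MC-dropout uncertainty: the caller owns the generator, so
every stochastic forward pass is replayable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter", "Dense", "ReLU", "Dropout", "LayerNorm", "MLP",
    "sigmoid", "bce_with_logits",
    "SGD", "AdamW", "RMSprop", "StepLR", "ReduceOnPlateau",
    "make_optimizer", "make_scheduler",
]


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on logits.

    Returns ``(loss, dloss_dlogits)``; the gradient already includes the
    1/B factor so it can be fed straight into ``backward``.
    """
    z = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(targets, dtype=float).ravel()
    if z.shape != y.shape:
        raise ValueError(f"logits shape {z.shape} != targets shape {y.shape}")
    # log(1 + e^-|z|) + max(z, 0) - z*y  is the stable form of
    # -[y log p + (1-y) log(1-p)]
    loss = float(np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Parameter(glorot_uniform(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, rng=None) -> np.ndarray:
        if x.shape[-1] != self.W.value.shape[0]:
            raise ValueError(
                f"input width {x.shape[-1]} != expected {self.W.value.shape[0]}")
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    def parameters(self):
        return [self.W, self.b]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def parameters(self):
        return []


class Dropout:
    """Inverted dropout; active only when a generator is passed to forward."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, rng: np.random.Generator | None = None):
        if rng is None or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask

    def parameters(self):
        return []


class LayerNorm:
    """Row-wise normalisation to mean 0, variance 1 (no learned affine).

    Constant rows (zero pre-normalisation variance, including all-zero
    inputs) map to the zero vector: the centred value is exactly zero, and
    the epsilon in the denominator keeps the division finite.
    """

    def __init__(self, eps: float = 1e-5):
        self.eps = eps
        self._y = None
        self._r = None

    def forward(self, x, rng=None):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        self._r = 1.0 / np.sqrt(var + self.eps)
        self._y = xc * self._r
        return self._y

    def backward(self, g):
        m1 = g.mean(axis=-1, keepdims=True)
        m2 = (g * self._y).mean(axis=-1, keepdims=True)
        return self._r * (g - m1 - self._y * m2)

    def parameters(self):
        return []


class MLP:
    """Dense → ReLU → Dropout stacks with a single-logit output head."""

    def __init__(self, input_dim: int, hidden_dims, dropout_p: float,
                 rng: np.random.Generator):
        self.input_dim = int(input_dim)
        self.layers = []
        d = self.input_dim
        for h in hidden_dims:
            self.layers += [Dense(d, int(h), rng), ReLU(), Dropout(dropout_p)]
            d = int(h)
        self.layers.append(Dense(d, 1, rng))

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Return logits of shape (B,). Dropout is active iff rng is given."""
        out = np.asarray(x, dtype=float)
        if out.ndim == 1:
            out = out[None, :]
        for layer in self.layers:
            out = layer.forward(out, rng=rng) if isinstance(layer, Dropout) \
                else layer.forward(out)
        return out.ravel()

    def backward(self, dlogits: np.ndarray):
        g = np.asarray(dlogits, dtype=float).reshape(-1, 1)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class _Optimizer:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, params, lr, momentum: float = 0.0):
        super().__init__(params, lr)
        self.momentum = float(momentum)
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v


class AdamW(_Optimizer):
    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        bc1 = 1.0 - self.b1 ** self._t
        bc2 = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSprop(_Optimizer):
    def __init__(self, params, lr, alpha=0.99, eps=1e-8, momentum=0.0):
        super().__init__(params, lr)
        self.alpha = alpha
        self.eps = eps
        self.momentum = momentum
        self._sq = [np.zeros_like(p.value) for p in self.params]
        self._buf = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        for p, sq, buf in zip(self.params, self._sq, self._buf):
            sq *= self.alpha
            sq += (1.0 - self.alpha) * p.grad ** 2
            upd = p.grad / (np.sqrt(sq) + self.eps)
            if self.momentum:
                buf *= self.momentum
                buf += upd
                upd = buf
            p.value -= self.lr * upd


class StepLR:
    """Multiply the learning rate by gamma every step_size epochs."""

    def __init__(self, optimizer, step_size: int, gamma: float):
        self.optimizer = optimizer
        self.step_size = max(1, int(step_size))
        self.gamma = float(gamma)
        self._epoch = 0

    def step(self, metric: float | None = None):
        self._epoch += 1
        if self._epoch % self.step_size == 0:
            self.optimizer.lr *= self.gamma


class ReduceOnPlateau:
    """Multiply the learning rate by gamma after `patience` epochs without
    improvement of the monitored loss."""

    def __init__(self, optimizer, patience: int, gamma: float):
        self.optimizer = optimizer
        self.patience = max(1, int(patience))
        self.gamma = float(gamma)
        self._best = np.inf
        self._stale = 0

    def step(self, metric: float):
        if metric < self._best - 1e-12:
            self._best = metric
            self._stale = 0
        else:
            self._stale += 1
            if self._stale >= self.patience:
                self.optimizer.lr *= self.gamma
                self._stale = 0


_OPTIMIZERS = {"sgd": SGD, "adamw": AdamW, "rmsprop": RMSprop}


def make_optimizer(name: str, params, lr: float, momentum: float = 0.9):
    name = name.lower()
    if name not in _OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}")
    if name == "sgd":
        return SGD(params, lr, momentum=momentum)
    if name == "rmsprop":
        return RMSprop(params, lr, momentum=momentum)
    return AdamW(params, lr)


def make_scheduler(name, optimizer, *, step_size=10, patience=5, gamma=0.9):
    if name is None:
        return None
    name = name.lower()
    if name == "step":
        return StepLR(optimizer, step_size, gamma)
    if name == "reduce_on_plateau":
        return ReduceOnPlateau(optimizer, patience, gamma)
    raise ValueError(f"unknown scheduler {name!r}")
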