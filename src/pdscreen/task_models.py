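"""Task-specific shallow classifiers with Monte-Carlo-dropout uncertainty.

Each recording task (finger tapping, smile, speech) gets its own shallow
dense network: one or two hidden ReLU layers with dropout, a sigmoid
output, binary cross-entropy loss.  Dropout stays stochastic at inference:
``mc_predict`` runs T forward passes and summarises the sigmoid outputs
into a mean probability, a sample standard deviation (the task's
"uncertainty"), and an empirical central interval.  The per-pass samples
are retained so any summary can be recomputed downstream.

Hyperparameters are chosen by random search over the published space,
maximising AUROC on a held-out selection set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .evaluation import roc_auc

__all__ = [
    "TaskModelSpec", "MCPrediction", "TaskModel", "train_task_model",
    "mc_predict", "summarize_mc_samples", "search_hyperparameters",
    "default_search_space", "sample_spec",
]

DROPOUT_RANGE = (0.05, 0.50)     # searched range
ETA_RANGE = (0.1, 100.0)


@dataclass
class TaskModelSpec:
    input_dim: int
    hidden_dims: tuple = (32,)
    dropout_p: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 100
    optimizer: str = "adamw"
    momentum: float = 0.9
    scheduler: str | None = None
    step_size: int = 10
    patience: int = 5
    gamma: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if len(self.hidden_dims) > 2:
            raise ValueError("task models are shallow: at most 2 hidden layers")
        if not 0.0 <= self.dropout_p <= DROPOUT_RANGE[1]:
            raise ValueError(
                f"dropout_p must lie in [0, {DROPOUT_RANGE[1]}], got {self.dropout_p}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class MCPrediction:
    """Summary of T stochastic forward passes for one input."""

    mean_p: float
    sd_p: float
    ci_low: float
    ci_high: float
    T: int
    samples: np.ndarray | None = None


def summarize_mc_samples(samples: np.ndarray, ci_level: float = 0.95) -> MCPrediction:
    """Mean / sample sd (n-1) / empirical central interval of the sigmoid
    outputs of T passes.  T = 1 gives a degenerate interval."""
    s = np.asarray(samples, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("no samples")
    if s.size == 1 or np.all(s == s[0]):
        v = float(s[0])   # exactly degenerate when every pass agrees
        return MCPrediction(v, 0.0, v, v, int(s.size), s)
    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(s, [100 * alpha, 100 * (1 - alpha)])
    return MCPrediction(mean, sd, float(lo), float(hi), int(s.size), s)


@dataclass
class TaskModel:
    spec: TaskModelSpec
    net: nn.MLP
    loss_history: list = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout off)."""
        return nn.sigmoid(self.net.forward(np.atleast_2d(np.asarray(X, float))))


def train_task_model(features: np.ndarray, labels: np.ndarray,
                     spec: TaskModelSpec) -> TaskModel:
    """Fit one task model.  Reproducible: all randomness (weight init,
    batch order, dropout masks) flows from ``spec.seed``."""
    spec.validate()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be 2-D and aligned with labels")
    if np.isnan(X).any():
        raise ValueError("features contain NaN; impute or drop first")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class; cannot train a classifier")
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"feature width {X.shape[1]} != spec.input_dim "
                         f"{spec.input_dim}")

    rng = np.random.default_rng(spec.seed)
    net = nn.MLP(spec.input_dim, spec.hidden_dims, spec.dropout_p, rng)
    opt = nn.make_optimizer(spec.optimizer, net.parameters(),
                            spec.learning_rate, spec.momentum)
    sched = nn.make_scheduler(spec.scheduler, opt, step_size=spec.step_size,
                              patience=spec.patience, gamma=spec.gamma)
    n = X.shape[0]
    bs = min(spec.batch_size, n)
    history = []
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            logits = net.forward(X[idx], rng=rng)
            loss, dlog = nn.bce_with_logits(logits, y[idx])
            epoch_loss += loss * idx.size
            opt.zero_grad()
            net.backward(dlog)
            opt.step()
        epoch_loss /= n
        history.append(epoch_loss)
        if sched is not None:
            sched.step(epoch_loss)
    return TaskModel(spec, net, history)


def mc_predict(model: TaskModel, x: np.ndarray, T: int = 30,
               rng: np.random.Generator | None = None,
               ci_level: float = 0.95):
    """T stochastic forward passes with dropout active.

    For a single input returns one :class:`MCPrediction`; for a matrix,
    a list of them (per row).  The caller owns the generator, so MC runs
    are replayable.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    X = np.atleast_2d(np.asarray(x, dtype=float))
    samples = np.empty((T, X.shape[0]))
    for t in range(T):
        samples[t] = nn.sigmoid(net_forward_mc(model, X, rng))
    preds = [summarize_mc_samples(samples[:, i], ci_level)
             for i in range(X.shape[0])]
    return preds[0] if np.asarray(x).ndim == 1 else preds


def net_forward_mc(model: TaskModel, X: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One stochastic pass (dropout on); exposed for fusion-stage reuse."""
    return model.net.forward(X, rng=rng)


def default_search_space(input_dim: int, epochs_range=(1, 300)) -> dict:
    """Random-search space mirroring the published hyperparameter table
    (learning rate and dropout uniform; epochs uniform integer)."""
    return {
        "hidden_dims": [(4,), (8,), (16,), (32,), (64,), (128,)],
        "dropout_p": ("uniform", *DROPOUT_RANGE),
        "learning_rate": ("uniform", 5e-5, 1.0),
        "batch_size": [256, 512, 1024],
        "epochs": ("int", *epochs_range),
        "optimizer": ["sgd", "adamw", "rmsprop"],
        "momentum": ("uniform", 0.1, 1.0),
        "scheduler": [None, "step", "reduce_on_plateau"],
        "step_size": ("int", 1, 30),
        "patience": ("int", 1, 20),
        "gamma": ("uniform", 0.5, 0.95),
    }


def sample_spec(space: dict, input_dim: int, rng: np.random.Generator,
                seed: int) -> TaskModelSpec:
    kwargs = {"input_dim": input_dim, "seed": seed}
    for name, dist in space.items():
        if isinstance(dist, list):                       # categorical choices
            kwargs[name] = dist[int(rng.integers(len(dist)))]
        elif isinstance(dist, tuple) and dist and dist[0] in (
                "uniform", "loguniform", "int"):
            kind, lo, hi = dist
            if kind == "uniform":
                kwargs[name] = float(rng.uniform(lo, hi))
            elif kind == "loguniform":
                kwargs[name] = float(math.exp(rng.uniform(math.log(lo),
                                                          math.log(hi))))
            else:
                kwargs[name] = int(rng.integers(lo, hi + 1))
        else:
            raise ValueError(f"malformed search-space entry for {name!r}")
    return TaskModelSpec(**kwargs)


def search_hyperparameters(space: dict, budget: int, train, dev, seed: int = 0,
                           T: int = 30):
    """Random search: sample ``budget`` configurations, train each, return
    the configuration maximising dev AUROC (ties break toward the earlier
    draw).

    Returns ``(best_spec, best_model, trials)`` where trials is a list of
    ``{"spec": ..., "dev_auroc": ...}`` records.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X_tr, y_tr = train
    X_dev, y_dev = dev
    if len(np.asarray(y_dev)) == 0:
        raise ValueError("empty dev set")
    input_dim = np.asarray(X_tr).shape[1]
    rng = np.random.default_rng(seed)
    best = None
    trials = []
    for trial in range(budget):
        spec = sample_spec(space, input_dim, rng,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        try:
            model = train_task_model(X_tr, y_tr, spec)
            score = roc_auc(y_dev, model.predict_proba(X_dev))
        except (ValueError, FloatingPointError, OverflowError):
            score = float("-inf")
        trials.append({"trial": trial, "spec": spec, "dev_auroc": score})
        if best is None or score > best[0]:
            best = (score, spec, model)
    return best[1], best[2], trials
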