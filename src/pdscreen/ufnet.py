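"""Uncertainty-calibrated multimodal fusion network.

The fusion model combines the three task modalities in an
uncertainty-aware fashion.  Each modality's (preprocessed) feature vector
is projected to a shared width — linear map, ReLU, MC dropout, layer
normalisation — giving three tokens.  The tokens attend to one another
with scaled dot-product self-attention whose post-softmax weight toward
key ``j`` is multiplied by ``exp(-eta * sigma_j)``, where ``sigma_j`` is
task ``j``'s MC-dropout predictive standard deviation, and each row is
renormalised: unreliable modalities are down-weighted, and at ``eta = 0``
(or equal sigmas) the mechanism reduces to ordinary attention.  The three
contextualized vectors are concatenated with the three task-model mean
probabilities and passed through a shallow sigmoid head trained with
binary cross-entropy.

Predictions are made with MC dropout: the task-level uncertainties are
computed once per session and held fixed while the fusion stack runs T
stochastic passes.  A verdict is *withheld* whenever the empirical
confidence interval of the fused probability straddles the decision
threshold — the selective-prediction rule that keeps uncertain cases from
being reported.

The fusion model requires complete sessions (all three blocks present).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .synthetic_cohort import MODALITIES
from .task_models import MCPrediction, mc_predict, summarize_mc_samples
from .evaluation import roc_auc

__all__ = [
    "FusionSpec", "ScreeningDecision", "UFNetModel", "project_modality",
    "calibrated_attention", "train_ufnet", "fuse_predict",
    "fuse_predict_from_stats", "task_level_stats", "decide",
    "count_parameters", "default_fusion_space", "sample_fusion_spec",
    "search_fusion_hyperparameters",
]

PROJECTION_DIMS = (128, 256, 512)
QUERY_DIMS = (32, 64, 128, 256)
HIDDEN_DIMS = (4, 8, 16, 32, 64, 128)
ETA_RANGE = (0.1, 100.0)


@dataclass
class FusionSpec:
    projection_dim: int = 128
    query_dim: int = 64
    hidden_dim: int = 32
    dropout_p: float = 0.25
    eta: float = 1.0
    T: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 100
    optimizer: str = "adamw"
    momentum: float = 0.9
    scheduler: str | None = None
    step_size: int = 10
    patience: int = 5
    gamma: float = 0.9
    decision_threshold: float = 0.5
    ci_level: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if min(self.projection_dim, self.query_dim, self.hidden_dim) < 1:
            raise ValueError("dims must be positive")
        if not 0.0 <= self.dropout_p <= 0.5:
            raise ValueError("dropout_p must lie in [0, 0.5]")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass
class ScreeningDecision:
    verdict: str                # positive | negative | withheld
    mc: MCPrediction


def _softmax(S: np.ndarray) -> np.ndarray:
    e = np.exp(S - S.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def modulate_attention_weights(A: np.ndarray, sigmas: np.ndarray,
                               eta: float) -> np.ndarray:
    """Multiply post-softmax weights toward key j by exp(-eta * sigma_j)
    and renormalise each row to sum 1."""
    sig = np.asarray(sigmas, dtype=float)
    if np.any(sig < 0):
        raise ValueError("sigmas must be nonnegative")
    c = np.exp(-eta * sig)
    M = A * c[..., None, :]
    return M / M.sum(axis=-1, keepdims=True)


class UFNetModel:
    """Parameter container + forward/backward for the fusion network."""

    def __init__(self, spec: FusionSpec, input_dims: dict,
                 rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        self.input_dims = dict(input_dims)
        P, q, H = spec.projection_dim, spec.query_dim, spec.hidden_dim
        self.proj = {m: nn.Dense(self.input_dims[m], P, rng) for m in MODALITIES}
        self.proj_relu = {m: nn.ReLU() for m in MODALITIES}
        self.proj_drop = {m: nn.Dropout(spec.dropout_p) for m in MODALITIES}
        self.proj_ln = {m: nn.LayerNorm() for m in MODALITIES}
        self.q_proj = nn.Dense(P, q, rng)
        self.k_proj = nn.Dense(P, q, rng)
        self.v_proj = nn.Dense(P, P, rng)
        self.head1 = nn.Dense(3 * P + 3, H, rng)
        self.head_relu = nn.ReLU()
        self.head_drop = nn.Dropout(spec.dropout_p)
        self.head2 = nn.Dense(H, 1, rng)
        self._cache = None
        self.loss_history: list = []
        self.task_model_hashes: dict = {}

    # -- forward -----------------------------------------------------------
    def forward(self, features: dict, probs: np.ndarray, sigmas: np.ndarray,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a batch of complete sessions.

        ``features[m]`` is (B, d_m); ``probs`` and ``sigmas`` are (B, 3) in
        modality order.  Dropout active iff ``rng`` is given.
        """
        P = self.spec.projection_dim
        B = np.atleast_2d(features[MODALITIES[0]]).shape[0]
        probs = np.asarray(probs, dtype=float).reshape(B, 3)
        sigmas = np.asarray(sigmas, dtype=float).reshape(B, 3)
        if np.any(sigmas < 0):
            raise ValueError("sigmas must be nonnegative")
        tokens = []
        for m in MODALITIES:
            x = np.atleast_2d(np.asarray(features[m], dtype=float))
            if x.shape[1] != self.input_dims[m]:
                raise ValueError(f"{m} width {x.shape[1]} != expected "
                                 f"{self.input_dims[m]}")
            a = self.proj[m].forward(x)
            r = self.proj_relu[m].forward(a)
            u = self.proj_drop[m].forward(r, rng=rng)
            tokens.append(self.proj_ln[m].forward(u))
        Hm = np.stack(tokens, axis=1)                      # (B, 3, P)
        flat = Hm.reshape(B * 3, P)
        qd = self.spec.query_dim
        Q = self.q_proj.forward(flat).reshape(B, 3, qd)
        K = self.k_proj.forward(flat).reshape(B, 3, qd)
        V = self.v_proj.forward(flat).reshape(B, 3, P)
        S = np.einsum("biq,bjq->bij", Q, K) / math.sqrt(qd)
        A = _softmax(S)
        c = np.exp(-self.spec.eta * sigmas)                # (B, 3)
        M = A * c[:, None, :]
        s = M.sum(axis=-1, keepdims=True)
        R = M / s                                          # (B, 3, 3)
        C = np.einsum("bij,bjp->bip", R, V)                # (B, 3, P)
        z = np.concatenate([C.reshape(B, 3 * P), probs], axis=1)
        g1 = self.head1.forward(z)
        hr = self.head_relu.forward(g1)
        hd = self.head_drop.forward(hr, rng=rng)
        logits = self.head2.forward(hd).ravel()
        self._cache = {"B": B, "R": R, "c": c, "s": s, "A": A,
                       "Q": Q, "K": K, "V": V}
        return logits

    # -- backward ----------------------------------------------------------
    def backward(self, dlogits: np.ndarray) -> None:
        cc = self._cache
        B, P, qd = cc["B"], self.spec.projection_dim, self.spec.query_dim
        g = np.asarray(dlogits, dtype=float).reshape(-1, 1)
        g = self.head2.backward(g)
        g = self.head_drop.backward(g)
        g = self.head_relu.backward(g)
        dz = self.head1.backward(g)
        dC = dz[:, :3 * P].reshape(B, 3, P)
        R, c, s, A, Q, K, V = (cc[k] for k in ("R", "c", "s", "A", "Q", "K", "V"))
        dR = np.einsum("bip,bjp->bij", dC, V)
        dV = np.einsum("bij,bip->bjp", R, dC)
        dM = (dR - (dR * R).sum(axis=-1, keepdims=True)) / s
        dA = dM * c[:, None, :]
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = np.einsum("bij,bjq->biq", dS, K) / math.sqrt(qd)
        dK = np.einsum("bij,biq->bjq", dS, Q) / math.sqrt(qd)
        dflat = (self.q_proj.backward(dQ.reshape(B * 3, qd))
                 + self.k_proj.backward(dK.reshape(B * 3, qd))
                 + self.v_proj.backward(dV.reshape(B * 3, P)))
        dH = dflat.reshape(B, 3, P)
        for mi, m in enumerate(MODALITIES):
            dh = self.proj_ln[m].backward(dH[:, mi, :])
            dh = self.proj_drop[m].backward(dh)
            dh = self.proj_relu[m].backward(dh)
            self.proj[m].backward(dh)

    def parameters(self):
        params = []
        for m in MODALITIES:
            params += self.proj[m].parameters()
        for layer in (self.q_proj, self.k_proj, self.v_proj,
                      self.head1, self.head2):
            params += layer.parameters()
        return params


def project_modality(x: np.ndarray, W: np.ndarray, b: np.ndarray,
                     dropout_p: float = 0.0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Standalone projection: linear, ReLU, MC dropout, layer norm.

    After normalisation each row has mean 0 and variance 1, except rows
    that are constant before normalisation (e.g. under zero weights and
    bias), which map to the zero vector.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    W = np.asarray(W, dtype=float)
    if x.shape[1] != W.shape[0]:
        raise ValueError(f"input width {x.shape[1]} != weight rows {W.shape[0]}")
    a = np.maximum(x @ W + b, 0.0)
    a = nn.Dropout(dropout_p).forward(a, rng=rng)
    out = nn.LayerNorm().forward(a)
    return out[0] if np.asarray(x).ndim == 1 else out


def calibrated_attention(projections: np.ndarray, sigmas: np.ndarray,
                         model_or_spec, attn=None):
    """Uncertainty-modulated self-attention over the three modality tokens.

    ``projections`` is (3, P) or (B, 3, P); ``sigmas`` the matching task
    uncertainties.  Pass a trained/initialised :class:`UFNetModel` (whose
    q/k/v maps are used), or a :class:`FusionSpec` together with ``attn``,
    a dict with keys wq, bq, wk, bk, wv, bv.  Returns
    ``(contextualized vectors, attention weight matrix)``.
    """
    Hm = np.asarray(projections, dtype=float)
    single = Hm.ndim == 2
    if single:
        Hm = Hm[None]
    B, n_tok, P = Hm.shape
    if isinstance(model_or_spec, UFNetModel):
        model = model_or_spec
        eta = model.spec.eta
        qd = model.spec.query_dim
        wq, bq = model.q_proj.W.value, model.q_proj.b.value
        wk, bk = model.k_proj.W.value, model.k_proj.b.value
        wv, bv = model.v_proj.W.value, model.v_proj.b.value
    else:
        spec = model_or_spec
        eta = spec.eta
        wq, bq, wk, bk = attn["wq"], attn["bq"], attn["wk"], attn["bk"]
        wv, bv = attn["wv"], attn["bv"]
        qd = wq.shape[1]
    Q = Hm @ wq + bq
    K = Hm @ wk + bk
    V = Hm @ wv + bv
    S = np.einsum("biq,bjq->bij", Q, K) / math.sqrt(qd)
    A = _softmax(S)
    sig = np.asarray(sigmas, dtype=float).reshape(B, n_tok)
    R = modulate_attention_weights(A, sig, eta)
    C = np.einsum("bij,bjp->bip", R, V)
    if single:
        return C[0], R[0]
    return C, R


class IncompleteSessionError(ValueError):
    """A fusion-stage input is missing one or more modality blocks."""


def _check_complete(features: dict, session_ids=None):
    B = np.atleast_2d(features[MODALITIES[0]]).shape[0]
    for m in MODALITIES:
        x = np.atleast_2d(np.asarray(features[m], dtype=float))
        if x.shape[0] != B:
            raise IncompleteSessionError(
                f"modality {m} has {x.shape[0]} rows, expected {B}")
        bad = np.isnan(x).any(axis=1)
        if bad.any():
            i = int(np.argmax(bad))
            name = session_ids[i] if session_ids is not None else f"row {i}"
            raise IncompleteSessionError(
                f"session {name} is missing (or has NaN in) its {m} block; "
                f"the fusion model requires complete sessions")


def task_level_stats(features: dict, task_models: dict, T: int,
                     rng: np.random.Generator, ci_level: float = 0.95):
    """Per-session task-model MC summaries: mean probabilities and
    predictive standard deviations, (B, 3) each in modality order."""
    B = np.atleast_2d(features[MODALITIES[0]]).shape[0]
    probs = np.empty((B, 3))
    sigmas = np.empty((B, 3))
    for mi, m in enumerate(MODALITIES):
        preds = mc_predict(task_models[m],
                           np.atleast_2d(features[m]), T, rng, ci_level)
        probs[:, mi] = [p.mean_p for p in preds]
        sigmas[:, mi] = [p.sd_p for p in preds]
    return probs, sigmas


def train_ufnet(features: dict, labels, task_probs, task_sigmas,
                spec: FusionSpec, session_ids=None) -> UFNetModel:
    """Train the fusion network on complete sessions.

    ``task_probs`` / ``task_sigmas`` are the locked task models' MC mean
    probabilities and uncertainties for the same sessions (the task models
    themselves are not updated).  Reproducible via ``spec.seed``.
    """
    spec.validate()
    _check_complete(features, session_ids)
    y = np.asarray(labels, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class; cannot train")
    feats = {m: np.atleast_2d(np.asarray(features[m], dtype=float))
             for m in MODALITIES}
    n = y.size
    probs = np.asarray(task_probs, dtype=float).reshape(n, 3)
    sigmas = np.asarray(task_sigmas, dtype=float).reshape(n, 3)
    rng = np.random.default_rng(spec.seed)
    model = UFNetModel(spec, {m: feats[m].shape[1] for m in MODALITIES}, rng)
    opt = nn.make_optimizer(spec.optimizer, model.parameters(),
                            spec.learning_rate, spec.momentum)
    sched = nn.make_scheduler(spec.scheduler, opt, step_size=spec.step_size,
                              patience=spec.patience, gamma=spec.gamma)
    bs = min(spec.batch_size, n)
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            logits = model.forward({m: feats[m][idx] for m in MODALITIES},
                                   probs[idx], sigmas[idx], rng=rng)
            loss, dlog = nn.bce_with_logits(logits, y[idx])
            epoch_loss += loss * idx.size
            opt.zero_grad()
            model.backward(dlog)
            opt.step()
        epoch_loss /= n
        model.loss_history.append(epoch_loss)
        if sched is not None:
            sched.step(epoch_loss)
    return model


def fuse_predict_from_stats(model: UFNetModel, features: dict, probs, sigmas,
                            T: int, rng: np.random.Generator,
                            ci_level: float | None = None):
    """T stochastic fusion passes with the task-level statistics held
    fixed; returns one MCPrediction per session."""
    if T < 1:
        raise ValueError("T must be >= 1")
    level = model.spec.ci_level if ci_level is None else ci_level
    _check_complete(features)
    feats = {m: np.atleast_2d(np.asarray(features[m], dtype=float))
             for m in MODALITIES}
    B = feats[MODALITIES[0]].shape[0]
    samples = np.empty((T, B))
    for t in range(T):
        samples[t] = nn.sigmoid(model.forward(feats, probs, sigmas, rng=rng))
    return [summarize_mc_samples(samples[:, i], level) for i in range(B)]


def fuse_predict(model: UFNetModel, features: dict, task_models: dict,
                 T: int | None = None, rng: np.random.Generator | None = None,
                 ci_level: float | None = None):
    """End-to-end fused MC prediction for complete sessions.

    Task-model uncertainties are computed once per session (T task-level
    passes) and held fixed across the T fusion-level passes.
    """
    if rng is None:
        rng = np.random.default_rng()
    T = model.spec.T if T is None else T
    single = np.asarray(features[MODALITIES[0]]).ndim == 1
    feats = {m: np.atleast_2d(np.asarray(features[m], dtype=float))
             for m in MODALITIES}
    _check_complete(feats)
    probs, sigmas = task_level_stats(feats, task_models, T, rng)
    preds = fuse_predict_from_stats(model, feats, probs, sigmas, T, rng,
                                    ci_level)
    return preds[0] if single else preds


def decide(mc: MCPrediction, threshold: float = 0.5,
           ci_level: float | None = None) -> ScreeningDecision:
    """Selective-prediction rule: withhold iff the confidence interval
    contains the threshold; otherwise positive iff mean_p > threshold."""
    lo, hi = mc.ci_low, mc.ci_high
    if ci_level is not None:
        if mc.samples is None:
            raise ValueError("cannot re-level a prediction without samples")
        redone = summarize_mc_samples(mc.samples, ci_level)
        lo, hi = redone.ci_low, redone.ci_high
        mc = redone
    if lo <= threshold <= hi:
        return ScreeningDecision("withheld", mc)
    return ScreeningDecision("positive" if mc.mean_p > threshold else "negative",
                             mc)


def count_parameters(model: UFNetModel):
    """Exact count of trainable scalars, itemised per layer."""
    items = {}
    for m in MODALITIES:
        d = model.proj[m]
        items[f"projection[{m}]"] = d.W.value.size + d.b.value.size
    for name, layer in (("query", model.q_proj), ("key", model.k_proj),
                        ("value", model.v_proj), ("head_hidden", model.head1),
                        ("head_out", model.head2)):
        items[name] = layer.W.value.size + layer.b.value.size
    return sum(items.values()), items


def default_fusion_space() -> dict:
    """Published fusion search space (dims categorical; dropout, eta,
    learning rate, momentum uniform; epochs uniform integer)."""
    return {
        "projection_dim": list(PROJECTION_DIMS),
        "query_dim": list(QUERY_DIMS),
        "hidden_dim": list(HIDDEN_DIMS),
        "dropout_p": ("uniform", 0.05, 0.50),
        "eta": ("uniform", *ETA_RANGE),
        "learning_rate": ("uniform", 5e-5, 1.0),
        "batch_size": [256, 512, 1024],
        "epochs": ("int", 1, 300),
        "optimizer": ["sgd", "adamw", "rmsprop"],
        "momentum": ("uniform", 0.1, 1.0),
        "scheduler": [None, "step", "reduce_on_plateau"],
        "step_size": ("int", 1, 30),
        "patience": ("int", 1, 20),
        "gamma": ("uniform", 0.5, 0.95),
    }


def sample_fusion_spec(space: dict, rng: np.random.Generator,
                       seed: int, T: int = 30) -> FusionSpec:
    kwargs = {"seed": seed, "T": T}
    for name, dist in space.items():
        if isinstance(dist, list):
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
    return FusionSpec(**kwargs)


def search_fusion_hyperparameters(space: dict, budget: int, train, dev,
                                  seed: int = 0):
    """Random search over fusion hyperparameters maximising dev AUROC.

    ``train`` and ``dev`` are tuples ``(features, labels, probs, sigmas)``.
    Returns ``(best_spec, best_model, trials)``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    feats_tr, y_tr, probs_tr, sig_tr = train
    feats_dev, y_dev, probs_dev, sig_dev = dev
    if len(np.asarray(y_dev)) == 0:
        raise ValueError("empty dev set")
    rng = np.random.default_rng(seed)
    best, trials = None, []
    for trial in range(budget):
        spec = sample_fusion_spec(space, rng,
                                  seed=int(rng.integers(0, 2 ** 31 - 1)))
        try:
            model = train_ufnet(feats_tr, y_tr, probs_tr, sig_tr, spec)
            dets = model.forward(feats_dev, probs_dev, sig_dev, rng=None)
            score = roc_auc(y_dev, nn.sigmoid(dets))
        except (ValueError, FloatingPointError, OverflowError):
            score = float("-inf")
        trials.append({"trial": trial, "spec": spec, "dev_auroc": score})
        if best is None or score > best[0]:
            best = (score, spec, model)
    return best[1], best[2], trials
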