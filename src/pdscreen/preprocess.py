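"""Data hygiene and feature conditioning.

Four steps sit between raw session tables and model training: exclusion of
recordings with abnormal durations (beyond three standard deviations of
the task's mean duration), feature scaling fitted on training rows only,
greedy correlation-based feature selection, and classic SMOTE minority
oversampling for class imbalance.

Sample statistics use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .synthetic_cohort import (MODALITIES, duration_column, feature_columns,
                               session_id)

__all__ = [
    "FilterReport", "filter_sessions_by_duration",
    "ScalerState", "fit_scaler", "apply_scaler", "invert_scaler",
    "select_features_by_correlation", "smote_oversample",
]

_EPS = 1e-12


@dataclass
class FilterReport:
    """Outcome of duration filtering.

    ``flags`` lists per-(session, task) exclusions with reasons
    (duration_low / duration_high / missing_block); ``excluded`` holds
    sessions that retain no usable block at all, ``kept`` the rest.
    """

    kept: list = field(default_factory=list)
    excluded: list = field(default_factory=list)
    flags: list = field(default_factory=list)       # (session_id, task, reason)
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags, columns=["session_id", "task", "reason"])


def filter_sessions_by_duration(df: pd.DataFrame, n_sd: float = 3.0):
    """Flag tasks whose recording duration is > ``n_sd`` sample standard
    deviations from that task's mean duration.

    Statistics are computed per task over all non-missing durations of the
    incoming table.  Flagged task blocks are blanked (treated as missing
    downstream).  Returns ``(filtered_df, FilterReport)``.
    """
    out = df.copy()
    report = FilterReport()
    sids = [session_id(p, i) for p, i in
            zip(df["participant_id"], df["session_index"])]
    for m in MODALITIES:
        dcol = duration_column(m)
        durs = out[dcol]
        present = durs.notna()
        for sid, has in zip(sids, present):
            if not has:
                report.flags.append((sid, m, "missing_block"))
        vals = durs[present]
        if len(vals) == 0:
            report.warnings.append(f"no recorded durations for task {m}; skipped")
            continue
        if len(vals) < 2:
            report.warnings.append(f"fewer than 2 durations for task {m}; skipped")
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        dev = durs - mean
        low = present & (dev < -n_sd * sd)
        high = present & (dev > n_sd * sd)
        for mask, reason in ((low, "duration_low"), (high, "duration_high")):
            for idx in out.index[mask]:
                report.flags.append((sids[out.index.get_loc(idx)], m, reason))
            out.loc[mask, feature_columns(m)] = np.nan
            out.loc[mask, dcol] = np.nan
    # a session is excluded outright only if no block survives
    fc = {m: feature_columns(m)[0] for m in MODALITIES}
    any_block = np.column_stack([out[fc[m]].notna() for m in MODALITIES]).any(axis=1)
    for sid, ok in zip(sids, any_block):
        (report.kept if ok else report.excluded).append(sid)
    return out, report


@dataclass
class ScalerState:
    kind: str                 # standardize | minmax
    loc: np.ndarray
    scale: np.ndarray

    @property
    def n_features(self) -> int:
        return self.loc.shape[0]


def fit_scaler(X: np.ndarray, kind: str = "standardize") -> ScalerState:
    """Fit per-column location/scale on training rows only.

    Constant columns get scale 1 so they map to 0 under either kind.
    """
    X = np.asarray(X, dtype=float)
    if kind == "standardize":
        loc = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    elif kind == "minmax":
        loc = X.min(axis=0)
        scale = X.max(axis=0) - loc
    else:
        raise ValueError(f"unknown scaler kind {kind!r}")
    scale = np.where(np.abs(scale) < _EPS, 1.0, scale)
    return ScalerState(kind, np.asarray(loc), np.asarray(scale))


def apply_scaler(state: ScalerState, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != state.n_features:
        raise ValueError(f"matrix width {X.shape[-1]} != scaler width "
                         f"{state.n_features}")
    return (X - state.loc) / state.scale


def invert_scaler(state: ScalerState, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != state.n_features:
        raise ValueError(f"matrix width {X.shape[-1]} != scaler width "
                         f"{state.n_features}")
    return X * state.scale + state.loc


def select_features_by_correlation(X: np.ndarray, threshold: float) -> list[int]:
    """Greedy scan in column order; drop a column iff its absolute Pearson
    correlation with an already-kept column exceeds ``threshold``.

    Zero-variance columns correlate 0 with everything except an identical
    constant column (treated as |r| = 1 so exact duplicates still drop).
    Deterministic for a fixed column order, and idempotent.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
    const = np.abs(sd) < _EPS
    Z = np.where(const, 0.0, (X - X.mean(axis=0)) / np.where(const, 1.0, sd))
    kept: list[int] = []
    for j in range(p):
        drop = False
        for k in kept:
            if const[j] or const[k]:
                r = 1.0 if (const[j] and const[k]
                            and np.allclose(X[:, j], X[:, k])) else 0.0
            else:
                r = abs(float(Z[:, j] @ Z[:, k]) / (n - 1))
            if r > threshold:
                drop = True
                break
        if not drop:
            kept.append(j)
    return kept


def smote_oversample(X: np.ndarray, y: np.ndarray, k: int = 5,
                     target_ratio: float = 1.0,
                     rng: np.random.Generator | None = None):
    """Classic SMOTE: interpolate new minority rows between existing
    minority rows and their k nearest minority neighbours.

    ``target_ratio`` is the desired minority/majority count ratio; the
    output ratio matches it within one sample.  Majority rows are never
    touched.  A no-op when the data already meet the target.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"SMOTE needs exactly 2 classes, found {len(classes)}")
    mi = int(np.argmin(counts))
    minority, majority = classes[mi], classes[1 - mi]
    n_min, n_maj = int(counts[mi]), int(counts[1 - mi])
    n_needed = int(round(target_ratio * n_maj)) - n_min
    if n_needed <= 0:
        return X.copy(), y.copy()
    if n_min < k + 1:
        raise ValueError(
            f"minority class has {n_min} members but k={k} neighbours were "
            f"requested; lower k to at most {n_min - 1}")
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)   # column 0 is the point itself
    base = rng.integers(0, n_min, size=n_needed)
    pick = rng.integers(1, k + 1, size=n_needed)
    u = rng.random(n_needed)
    neigh = idx[base, pick]
    synth = Xm[base] + u[:, None] * (Xm[neigh] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out
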