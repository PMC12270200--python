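"""Synthetic multimodal screening cohorts.

Real at-home screening recordings are protected health information, so the
pipeline is exercised on synthetic cohorts that reproduce the *statistical
shape* of such a study: a latent per-participant disease-severity factor
driving three fixed-width modality feature blocks (finger tapping: 130
features, smile: 42, speech: 1024), demographic subgroups with explicit
"unknown" categories, multi-session participants, per-task recording
durations with occasional extreme outliers, task-level missingness, and a
Hoehn–Yahr stage recorded for only a fraction of affected participants.

Generative model
----------------
Each participant carries a latent severity ``s ~ Normal(+1, 1)`` if they
have PD and ``Normal(-1, 1)`` otherwise.  Sessions of the same participant
share ``s`` plus independent Gaussian session jitter (sd 0.25), giving
within-participant correlation.  For modality ``m`` with effect
size ``delta_m``, the first ``n_informative[m]`` coordinates of the
feature vector are ``s * delta_m`` plus independent Gaussian noise; the
remaining coordinates are pure noise.  The between-class mean difference
of an informative coordinate is therefore ``2 * delta_m`` (the class means
of ``s`` are +1 and -1).

Randomness is rooted in a single seed, but every participant draws from a
child stream keyed by a stable hash of their identifier, so insertion
order never changes anyone's data.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MODALITIES", "MODALITY_DIMS", "CohortConfig", "ParticipantRecord",
    "Session", "generate_cohort", "simulate_modality_vector",
    "inject_missingness", "cohort_to_frame", "write_cohort_csv",
    "read_cohort_csv", "feature_columns", "duration_column", "session_id",
]

MODALITIES = ("finger_tapping", "smile", "speech")
MODALITY_DIMS = {"finger_tapping": 130, "smile": 42, "speech": 1024}

# CSV column prefixes / duration columns for each modality block
_PREFIX = {"finger_tapping": "tap", "smile": "smile", "speech": "speech"}
_PAD = {"finger_tapping": 3, "smile": 3, "speech": 4}
_DURCOL = {"finger_tapping": "dur_tap_s", "smile": "dur_smile_s",
           "speech": "dur_speech_s"}

SEXES = ("male", "female", "unknown")
ETHNICITIES = ("white", "non_white", "unknown")
AGE_BINS = ("below_50", "above_50", "unknown")


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


class EmptyCohortError(ValueError):
    """Raised when a configuration would produce zero participants."""


def feature_columns(modality: str) -> list[str]:
    """Column names of one modality block in the cohort CSV dialect."""
    dim = MODALITY_DIMS[modality]
    return [f"{_PREFIX[modality]}_{i:0{_PAD[modality]}d}" for i in range(dim)]


def duration_column(modality: str) -> str:
    return _DURCOL[modality]


def session_id(participant_id: str, session_index: int) -> str:
    return f"{participant_id}#{session_index}"


def _default_subgroup_targets():
    # Roughly the composition of a large remote screening cohort: a small
    # excess of women, ~11% identifying as non-white with many missing
    # ethnicity entries, and an older skew (median age in the 60s).
    # Sex carries no unknown bin because the balancer's expected
    # distribution scores only male/female.
    return {
        "sex": {"male": 0.48, "female": 0.52},
        "ethnicity": {"white": 0.66, "non_white": 0.11, "unknown": 0.23},
        "age": {"below_50": 0.20, "above_50": 0.70, "unknown": 0.10},
    }


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort; see the module docstring."""

    n_participants: int = 300
    pd_fraction: float = 0.36
    subgroup_targets: dict = field(default_factory=_default_subgroup_targets)
    sessions_per_participant: tuple = (1, 4)
    modality_signal: dict = field(default_factory=lambda: {
        "finger_tapping": 1.0, "smile": 0.5, "speech": 1.5})
    # Informative-subspace sizes: the tapping and smile blocks are curated
    # clinical features (roughly half carry disease signal); the speech
    # block is a distributed self-supervised embedding (signal spread over
    # about a quarter of its dimensions).
    n_informative: dict = field(default_factory=lambda: {
        "finger_tapping": 65, "smile": 21, "speech": 256})
    noise_sd: float = 1.0
    missing_rate: dict = field(default_factory=lambda: {
        "finger_tapping": 0.0, "smile": 0.0, "speech": 0.0})
    duration_outlier_rate: float = 0.02
    # quantile cutpoints of severity among PD participants for H&Y 1/2/3
    stage_thresholds: tuple = (1.0 / 3.0, 2.0 / 3.0)
    stage_documented_fraction: float = 0.31
    confirmed_fraction: float = 0.57
    session_jitter_sd: float = 0.25
    duration_mean_s: float = 30.0
    duration_sd_s: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.n_participants <= 0:
            raise EmptyCohortError("n_participants must be positive")
        if not 0.0 <= self.pd_fraction <= 1.0:
            errs.append(f"pd_fraction {self.pd_fraction} outside [0, 1]")
        for attr, groups in self.subgroup_targets.items():
            total = sum(groups.values())
            if abs(total - 1.0) > 1e-9:
                errs.append(f"subgroup proportions for {attr!r} sum to {total}, not 1")
            if any(p < 0 for p in groups.values()):
                errs.append(f"negative proportion in attribute {attr!r}")
        for m in MODALITIES:
            if self.n_informative.get(m, 0) > MODALITY_DIMS[m]:
                errs.append(f"n_informative[{m}] exceeds dimension {MODALITY_DIMS[m]}")
            if self.modality_signal.get(m, 0.0) < 0:
                errs.append(f"modality_signal[{m}] must be >= 0")
            rate = self.missing_rate.get(m, 0.0)
            if not 0.0 <= rate <= 1.0:
                errs.append(f"missing_rate[{m}] outside [0, 1]")
        if self.noise_sd < 0:
            errs.append("noise_sd must be nonnegative")
        if not 0.0 <= self.duration_outlier_rate <= 1.0:
            errs.append("duration_outlier_rate outside [0, 1]")
        lo, hi = self.sessions_per_participant
        if not (1 <= lo <= hi):
            errs.append(f"invalid sessions_per_participant range ({lo}, {hi})")
        if list(self.stage_thresholds) != sorted(self.stage_thresholds):
            errs.append("stage_thresholds must be ordered")
        if errs:
            raise ConfigurationError("; ".join(errs))


@dataclass
class ParticipantRecord:
    participant_id: str
    pd_status: int
    label_provenance: str  # clinically_confirmed | self_reported
    sex: str
    ethnicity: str
    age_years: float  # NaN when unknown
    hy_stage: int | None = None
    severity: float = 0.0  # latent factor (kept for oracle checks)


@dataclass
class Session:
    participant_id: str
    session_index: int
    label_at_session: int
    features: dict = field(default_factory=dict)    # modality -> ndarray | None
    durations_s: dict = field(default_factory=dict)  # modality -> float | None

    @property
    def session_id(self) -> str:
        return session_id(self.participant_id, self.session_index)

    def is_complete(self) -> bool:
        return all(self.features.get(m) is not None for m in MODALITIES)


def _child_rng(seed: int, participant_id: str) -> np.random.Generator:
    """Deterministic per-participant stream, independent of insertion order."""
    digest = hashlib.sha256(f"{seed}:{participant_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def simulate_modality_vector(severity: float, modality: str,
                             config: CohortConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """One modality feature block given the session-level severity.

    First ``n_informative`` coordinates have mean ``severity * effect``;
    the rest are pure noise with sd ``noise_sd``.
    """
    if modality not in MODALITY_DIMS:
        raise ValueError(f"unknown modality {modality!r}")
    dim = MODALITY_DIMS[modality]
    k = int(config.n_informative.get(modality, 0))
    effect = float(config.modality_signal.get(modality, 0.0))
    vec = np.zeros(dim)
    if config.noise_sd > 0:
        vec += rng.normal(0.0, config.noise_sd, size=dim)
    vec[:k] += severity * effect
    return vec


def _draw_categorical(rng, groups: dict) -> str:
    names = list(groups)
    probs = np.asarray([groups[g] for g in names], dtype=float)
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def _draw_duration(rng, config: CohortConfig) -> float:
    if rng.random() < config.duration_outlier_rate:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return max(0.1, config.duration_mean_s + sign * 5.0 * config.duration_sd_s)
    return max(0.1, rng.normal(config.duration_mean_s, config.duration_sd_s))


def generate_cohort(config: CohortConfig):
    """Draw a full synthetic cohort.

    Returns ``(participants, sessions)``.  Exactly
    ``round(n_participants * pd_fraction)`` participants are PD-positive.
    Identical config + seed reproduces byte-identical output.
    """
    config.validate()
    n = config.n_participants
    n_pd = int(round(n * config.pd_fraction))
    root = np.random.default_rng(config.seed)
    order = root.permutation(n)
    pd_flags = np.zeros(n, dtype=int)
    pd_flags[order[:n_pd]] = 1

    participants: list[ParticipantRecord] = []
    sessions: list[Session] = []
    lo, hi = config.sessions_per_participant
    for i in range(n):
        pid = f"P{i:05d}"
        crng = _child_rng(config.seed, pid)
        is_pd = int(pd_flags[i])
        sex = _draw_categorical(crng, config.subgroup_targets["sex"])
        ethnicity = _draw_categorical(crng, config.subgroup_targets["ethnicity"])
        age_bin = _draw_categorical(crng, config.subgroup_targets["age"])
        if age_bin == "below_50":
            age = float(crng.uniform(18.0, 50.0))
        elif age_bin == "above_50":
            age = float(crng.uniform(50.0, 90.0))
        else:
            age = float("nan")
        severity = float(crng.normal(1.0 if is_pd else -1.0, 1.0))
        if is_pd:
            provenance = ("clinically_confirmed"
                          if crng.random() < config.confirmed_fraction
                          else "self_reported")
        else:
            provenance = "self_reported"
        stage_documented = bool(crng.random() < config.stage_documented_fraction)
        rec = ParticipantRecord(pid, is_pd, provenance, sex, ethnicity, age,
                                hy_stage=None, severity=severity)
        rec._stage_documented = stage_documented  # resolved below
        participants.append(rec)

        n_sessions = int(crng.integers(lo, hi + 1))
        for j in range(n_sessions):
            s_sess = severity + float(crng.normal(0.0, config.session_jitter_sd))
            feats = {m: simulate_modality_vector(s_sess, m, config, crng)
                     for m in MODALITIES}
            durs = {m: _draw_duration(crng, config) for m in MODALITIES}
            sessions.append(Session(pid, j, is_pd, feats, durs))

    # H&Y stage: quantile bins of severity among PD participants; recorded
    # only for the documented fraction.
    pd_recs = [r for r in participants if r.pd_status == 1]
    if pd_recs:
        sev = np.array([r.severity for r in pd_recs])
        cuts = np.quantile(sev, config.stage_thresholds)
        for r in pd_recs:
            if r._stage_documented:
                r.hy_stage = 1 + int(np.searchsorted(cuts, r.severity, side="right"))
    for r in participants:
        del r._stage_documented
    return participants, sessions


def inject_missingness(sessions, config: CohortConfig,
                       rng: np.random.Generator):
    """Independently delete modality blocks at the configured rates.

    Deleting a block also removes its duration.  A session never loses all
    three blocks: the deletion pattern is redrawn until at least one block
    survives (only possible when every rate is 1, which is rejected).
    """
    rates = {m: float(config.missing_rate.get(m, 0.0)) for m in MODALITIES}
    if all(r >= 1.0 for r in rates.values()):
        raise ConfigurationError("all modality missing rates are 1; a session "
                                 "must retain at least one block")
    out = []
    for s in sessions:
        if all(r == 0.0 for r in rates.values()):
            out.append(s)
            continue
        while True:
            drop = {m: rng.random() < rates[m] for m in MODALITIES}
            if not all(drop.values()):
                break
        feats = {m: (None if drop[m] else s.features[m]) for m in MODALITIES}
        durs = {m: (None if drop[m] else s.durations_s[m]) for m in MODALITIES}
        out.append(Session(s.participant_id, s.session_index,
                           s.label_at_session, feats, durs))
    return out


# ---------------------------------------------------------------------------
# CSV dialect

def cohort_to_frame(participants, sessions) -> pd.DataFrame:
    """Single wide table: one row per session, demographics repeated."""
    recs = {r.participant_id: r for r in participants}
    base_cols = ["participant_id", "session_index", "pd_status",
                 "label_provenance", "sex", "ethnicity", "age_years", "hy_stage",
                 "dur_tap_s", "dur_smile_s", "dur_speech_s"]
    feat_cols = [c for m in MODALITIES for c in feature_columns(m)]
    rows = []
    for s in sorted(sessions, key=lambda s: (s.participant_id, s.session_index)):
        r = recs[s.participant_id]
        row = [s.participant_id, s.session_index, s.label_at_session,
               r.label_provenance, r.sex, r.ethnicity, r.age_years,
               r.hy_stage if r.hy_stage is not None else np.nan]
        for m in MODALITIES:
            d = s.durations_s.get(m)
            row.append(np.nan if d is None else d)
        for m in MODALITIES:
            v = s.features.get(m)
            if v is None:
                row.extend([np.nan] * MODALITY_DIMS[m])
            else:
                row.extend(v.tolist())
        rows.append(row)
    return pd.DataFrame(rows, columns=base_cols + feat_cols)


def write_cohort_csv(path, participants, sessions,
                     config: CohortConfig | None = None) -> pd.DataFrame:
    """Write the cohort table plus a ``<path>.meta`` sidecar with the
    generating configuration."""
    df = cohort_to_frame(participants, sessions)
    df.to_csv(path, index=False)
    if config is not None:
        lines = []
        for f in dataclasses.fields(config):
            lines.append(f"{f.name} = {getattr(config, f.name)!r}")
        with open(f"{path}.meta", "w") as fh:
            fh.write("\n".join(lines) + "\n")
    return df


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["participant_id", "session_index", "pd_status"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"not a cohort table; missing columns {missing}")
    return df


def frame_to_sessions(df: pd.DataFrame) -> list[Session]:
    """Rehydrate Session objects (feature blocks with any NaN -> missing)."""
    sessions = []
    cols = {m: feature_columns(m) for m in MODALITIES}
    for _, row in df.iterrows():
        feats, durs = {}, {}
        for m in MODALITIES:
            block = row[cols[m]].to_numpy(dtype=float)
            if np.isnan(block).any():
                feats[m], durs[m] = None, None
            else:
                feats[m] = block
                d = row[_DURCOL[m]]
                durs[m] = None if pd.isna(d) else float(d)
        sessions.append(Session(str(row["participant_id"]),
                                int(row["session_index"]),
                                int(row["pd_status"]), feats, durs))
    return sessions


def participants_frame(df: pd.DataFrame) -> pd.DataFrame:
    """One row per participant with demographics (first session's row)."""
    cols = ["participant_id", "pd_status", "label_provenance", "sex",
            "ethnicity", "age_years", "hy_stage"]
    return (df[cols].drop_duplicates("participant_id")
            .reset_index(drop=True))
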