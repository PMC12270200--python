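"""Demographically balanced cohort selection and leak-free splits.

A candidate selection of participants is scored against an expected
demographic distribution with a chi-square-style diversity loss

    L = sum over attributes a, subgroups i of (E_i - O_i)^2 / E_i

where ``E_i`` is the expected count (target proportion x selection size)
and ``O_i`` the observed count.  A simple genetic algorithm minimises this
loss: start from a random selection with exact PD / non-PD class counts,
repeatedly swap a random selected participant for a random unselected one
of the same class, accept the swap only if the loss strictly decreases,
and stop after a run of consecutive rejections.  The best of several
restarts is kept.  Selecting the test set first, removing it, then
selecting the development set from the remainder yields participant-
disjoint train/dev/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiversityTargets", "default_targets", "age_bin", "participant_attributes",
    "diversity_loss", "genetic_balance", "make_splits", "SplitAssignment",
]

ATTRIBUTES = ("sex", "ethnicity", "age")


def default_targets() -> dict:
    """Expected subgroup distribution for a balanced evaluation cohort:
    sex 50/50; ethnicity 45% white / 45% non-white / 10% unknown;
    age 45% below 50 / 45% above 50 / 10% unknown."""
    return {
        "sex": {"male": 0.50, "female": 0.50},
        "ethnicity": {"white": 0.45, "non_white": 0.45, "unknown": 0.10},
        "age": {"below_50": 0.45, "above_50": 0.45, "unknown": 0.10},
    }


@dataclass
class DiversityTargets:
    """Per-attribute subgroup target proportions."""

    targets: dict = field(default_factory=default_targets)

    def validate(self) -> None:
        for attr, groups in self.targets.items():
            total = sum(groups.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"target proportions for {attr!r} sum to {total}, not 1")


def age_bin(age_years: float, cut: float = 50.0) -> str:
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "unknown"
    return "below_50" if age_years < cut else "above_50"


def participant_attributes(participants: pd.DataFrame,
                           age_cut: float = 50.0) -> pd.DataFrame:
    """Attribute table (sex, ethnicity, age bin) indexed by participant."""
    df = pd.DataFrame({
        "participant_id": participants["participant_id"].astype(str),
        "pd_status": participants["pd_status"].astype(int),
        "sex": participants["sex"].fillna("unknown").astype(str),
        "ethnicity": participants["ethnicity"].fillna("unknown").astype(str),
        "age": [age_bin(a, age_cut) for a in participants["age_years"]],
    })
    return df.reset_index(drop=True)


def _counts(attrs: pd.DataFrame, targets: dict) -> dict:
    out = {}
    for attr, groups in targets.items():
        vc = attrs[attr].value_counts()
        out[attr] = {g: int(vc.get(g, 0)) for g in groups}
        extra = set(vc.index) - set(groups)
        for g in extra:
            out[attr][g] = int(vc[g])
    return out


def _loss_from_counts(counts: dict, targets: dict, n: int) -> float:
    loss = 0.0
    for attr, groups in targets.items():
        observed = counts.get(attr, {})
        for g, count in observed.items():
            prop = groups.get(g, 0.0)
            expected = prop * n
            if expected <= 0.0:
                if count > 0:
                    raise ValueError(
                        f"subgroup {attr}={g!r} is populated (O={count}) but has "
                        f"expected count 0; give it a positive target proportion")
                continue
            loss += (expected - count) ** 2 / expected
        # subgroups with zero observed count still contribute E_i
        for g, prop in groups.items():
            if g not in observed and prop > 0:
                loss += prop * n
    return loss


def diversity_loss(selection: pd.DataFrame,
                   targets: DiversityTargets | dict) -> float:
    """Evaluate the diversity loss of a candidate selection.

    ``selection`` is an attribute table as produced by
    :func:`participant_attributes` (only the attribute columns named in
    the targets are consulted).
    """
    tg = targets.targets if isinstance(targets, DiversityTargets) else targets
    n = len(selection)
    if n == 0:
        raise ValueError("empty selection")
    return _loss_from_counts(_counts(selection, tg), tg, n)


def genetic_balance(pool: pd.DataFrame, n_select: int,
                    targets: DiversityTargets | dict | None = None,
                    pd_fraction: float = 0.5, restarts: int = 500,
                    max_stale: int = 2000, seed: int = 0,
                    age_cut: float = 50.0):
    """Select ``n_select`` participants from ``pool`` minimising the
    diversity loss under exact PD / non-PD class counts.

    ``pool`` is a participant table (participant_id, pd_status, sex,
    ethnicity, age_years) or a prebuilt attribute table.  Returns
    ``(selected_ids, log)`` where ``log`` has one record per restart with
    its initial loss, final loss, accepted-loss trace and iteration count.
    """
    if targets is None:
        targets = DiversityTargets()
    if isinstance(targets, dict):
        targets = DiversityTargets(targets)
    targets.validate()
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    attrs = (pool if "age" in pool.columns and "age_years" not in pool.columns
             else participant_attributes(pool, age_cut))
    tg = targets.targets

    n_pd = int(round(n_select * pd_fraction))
    n_non = n_select - n_pd
    idx_pd = attrs.index[attrs["pd_status"] == 1].to_numpy()
    idx_non = attrs.index[attrs["pd_status"] == 0].to_numpy()
    if len(idx_pd) < n_pd or len(idx_non) < n_non:
        raise ValueError(
            f"infeasible selection: need {n_pd} PD of {len(idx_pd)} and "
            f"{n_non} non-PD of {len(idx_non)}")

    # attribute values as arrays for fast count updates
    values = {a: attrs[a].to_numpy() for a in tg}

    best_ids, best_loss, log = None, np.inf, []
    ss = np.random.SeedSequence(seed)
    for r, child in enumerate(ss.spawn(restarts)):
        rng = np.random.default_rng(child)
        sel_pd = list(rng.choice(idx_pd, size=n_pd, replace=False))
        sel_non = list(rng.choice(idx_non, size=n_non, replace=False))
        selected = set(sel_pd) | set(sel_non)
        counts = {a: {} for a in tg}
        for i in selected:
            for a in tg:
                v = values[a][i]
                counts[a][v] = counts[a].get(v, 0) + 1
        loss = _loss_from_counts(counts, tg, n_select)
        trace = [loss]
        out_pd = [i for i in idx_pd if i not in selected]
        out_non = [i for i in idx_non if i not in selected]
        stale, iters = 0, 0
        can_pd, can_non = bool(out_pd) and n_pd > 0, bool(out_non) and n_non > 0
        while stale < max_stale and (can_pd or can_non):
            iters += 1
            if can_pd and can_non:
                use_pd = rng.random() < n_pd / n_select
            else:
                use_pd = can_pd
            sel_list, out_list = (sel_pd, out_pd) if use_pd else (sel_non, out_non)
            ai = int(rng.integers(len(sel_list)))
            bi = int(rng.integers(len(out_list)))
            a, b = sel_list[ai], out_list[bi]
            for attr in tg:
                va, vb = values[attr][a], values[attr][b]
                counts[attr][va] -= 1
                counts[attr][vb] = counts[attr].get(vb, 0) + 1
            new_loss = _loss_from_counts(counts, tg, n_select)
            if new_loss < loss:                       # strict decrease only
                loss = new_loss
                trace.append(loss)
                sel_list[ai], out_list[bi] = b, a
                stale = 0
            else:
                for attr in tg:                       # revert
                    va, vb = values[attr][a], values[attr][b]
                    counts[attr][va] += 1
                    counts[attr][vb] -= 1
                stale += 1
        log.append({"restart": r, "initial_loss": trace[0], "final_loss": loss,
                    "iterations": iters, "trace": trace})
        if loss < best_loss:
            best_loss = loss
            best_ids = [attrs["participant_id"].iloc[i]
                        for i in sorted(sel_pd + sel_non)]
    return best_ids, log


@dataclass
class SplitAssignment:
    assignment: dict            # participant_id -> train | dev | test
    logs: dict = field(default_factory=dict)

    def ids(self, split: str) -> list:
        return sorted(p for p, s in self.assignment.items() if s == split)

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.assignment.items())
        return pd.DataFrame(items, columns=["participant_id", "split"])


def make_splits(pool: pd.DataFrame, test_size: int, dev_size: int,
                targets: DiversityTargets | dict | None = None,
                seed: int = 0, restarts: int = 50, max_stale: int = 2000,
                pd_fraction: float = 0.5) -> SplitAssignment:
    """Sequentially select a balanced test set, then a balanced dev set
    from the remainder; everyone else trains.  No participant overlap."""
    if len(pool) < test_size + dev_size:
        raise ValueError(f"pool of {len(pool)} cannot supply test {test_size} "
                         f"+ dev {dev_size}")
    attrs = participant_attributes(pool)
    try:
        test_ids, log_test = genetic_balance(
            attrs, test_size, targets, pd_fraction, restarts, max_stale,
            seed=seed * 2 + 1)
    except ValueError as e:
        raise ValueError(f"test-stage selection infeasible: {e}") from e
    remainder = attrs[~attrs["participant_id"].isin(test_ids)].reset_index(drop=True)
    try:
        dev_ids, log_dev = genetic_balance(
            remainder, dev_size, targets, pd_fraction, restarts, max_stale,
            seed=seed * 2 + 2)
    except ValueError as e:
        raise ValueError(f"dev-stage selection infeasible: {e}") from e
    assignment = {}
    test_set, dev_set = set(test_ids), set(dev_ids)
    for p in attrs["participant_id"]:
        assignment[p] = ("test" if p in test_set
                         else "dev" if p in dev_set else "train")
    return SplitAssignment(assignment, {"test": log_test, "dev": log_dev})
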