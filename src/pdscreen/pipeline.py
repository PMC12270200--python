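"""End-to-end experiment orchestration.

``run_experiment`` executes the whole screening pipeline on a synthetic
cohort: simulate -> duration filter -> demographically balanced splits ->
per-modality preprocessing -> task-model training (or random search) ->
fusion training -> selective prediction on the test split -> metric
report.  Every stage reads and writes files in the output directory, and
a manifest records the SHA-256 of each artifact so that a rerun with the
same configuration and seed can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import preprocess as pp
from . import synthetic_cohort as sc
from .cohort_sampler import make_splits
from .config import ExperimentConfig, save_config
from .task_models import (TaskModel, TaskModelSpec, default_search_space,
                          search_hyperparameters, train_task_model)
from .ufnet import (FusionSpec, decide, default_fusion_space, fuse_predict_from_stats,
                    search_fusion_hyperparameters, task_level_stats, train_ufnet)

log = logging.getLogger("pdscreen")

__all__ = ["run_experiment", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _modality_matrix(df: pd.DataFrame, modality: str) -> np.ndarray:
    return df[sc.feature_columns(modality)].to_numpy(dtype=float)


def _stage(manifest, outdir, name):
    """Record an artifact hash after its stage writes it."""
    p = outdir / name
    manifest["artifacts"][name] = _sha256(p)


def run_experiment(config: ExperimentConfig, outdir) -> Path:
    """Run the full pipeline; returns the report directory.

    Deterministic: identical config + seed produce byte-identical
    artifacts and manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = int(config.seed)
    cfg_path = outdir / "config.yaml"
    save_config(config, cfg_path)
    manifest = {"seed": base, "artifacts": {},
                "config_sha256": _sha256(cfg_path)}

    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=base)
        participants, sessions = sc.generate_cohort(cohort_cfg)
        sessions = sc.inject_missingness(
            sessions, cohort_cfg, np.random.default_rng(base + 11))
        df = sc.write_cohort_csv(outdir / "cohort.csv", participants, sessions,
                                 cohort_cfg)
        _stage(manifest, outdir, "cohort.csv")
        log.info("simulate: %d participants, %d sessions, seed=%d",
                 len(participants), len(sessions), base)

        stage = "duration_filter"
        fdf, report = pp.filter_sessions_by_duration(
            df, n_sd=config.preprocess.duration_sd_limit)
        fdf.to_csv(outdir / "filtered.csv", index=False)
        report.to_frame().to_csv(outdir / "filter_report.csv", index=False)
        _stage(manifest, outdir, "filtered.csv")
        _stage(manifest, outdir, "filter_report.csv")
        log.info("duration_filter: %d flags, %d sessions fully excluded",
                 len(report.flags), len(report.excluded))

        stage = "split"
        parts = sc.participants_frame(fdf)
        sp = config.split
        split = make_splits(parts, sp.test_size, sp.dev_size, seed=base + 21,
                            restarts=sp.restarts, max_stale=sp.max_stale,
                            pd_fraction=sp.pd_fraction)
        split.to_frame().to_csv(outdir / "splits.csv", index=False)
        ga_rows = [{"stage": st, "restart": r["restart"],
                    "iterations": r["iterations"],
                    "initial_loss": r["initial_loss"],
                    "final_loss": r["final_loss"]}
                   for st, lg in split.logs.items() for r in lg]
        pd.DataFrame(ga_rows).to_csv(outdir / "ga_log.csv", index=False)
        _stage(manifest, outdir, "splits.csv")
        _stage(manifest, outdir, "ga_log.csv")

        split_of = split.assignment
        fdf = fdf.assign(split=[split_of[p] for p in fdf["participant_id"]])

        stage = "task_models"
        tk = config.task
        task_models: dict[str, TaskModel] = {}
        scalers, kept_idx = {}, {}
        trial_rows = []
        for mi, m in enumerate(sc.MODALITIES):
            cols = sc.feature_columns(m)
            present = fdf[cols[0]].notna()
            d_tr = fdf[present & (fdf["split"] == "train")]
            d_dev = fdf[present & (fdf["split"] == "dev")]
            X_tr_raw = _modality_matrix(d_tr, m)
            scaler = pp.fit_scaler(X_tr_raw, config.preprocess.scaler)
            X_tr = pp.apply_scaler(scaler, X_tr_raw)
            if config.preprocess.corr_threshold is not None:
                keep = pp.select_features_by_correlation(
                    X_tr, config.preprocess.corr_threshold)
            else:
                keep = list(range(X_tr.shape[1]))
            X_tr = X_tr[:, keep]
            y_tr = d_tr["pd_status"].to_numpy(dtype=int)
            if config.preprocess.smote_ratio is not None:
                X_tr, y_tr = pp.smote_oversample(
                    X_tr, y_tr, k=config.preprocess.smote_k,
                    target_ratio=config.preprocess.smote_ratio,
                    rng=np.random.default_rng(base + 31 + mi))
            X_dev = pp.apply_scaler(scaler, _modality_matrix(d_dev, m))[:, keep]
            y_dev = d_dev["pd_status"].to_numpy(dtype=int)
            if tk.budget <= 1:
                spec = TaskModelSpec(
                    input_dim=X_tr.shape[1], hidden_dims=tuple(tk.hidden_dims),
                    dropout_p=tk.dropout_p, learning_rate=tk.learning_rate,
                    batch_size=tk.batch_size, epochs=tk.epochs,
                    optimizer=tk.optimizer, momentum=tk.momentum,
                    seed=base + 41 + mi)
                model = train_task_model(X_tr, y_tr, spec)
            else:
                space = default_search_space(X_tr.shape[1],
                                             epochs_range=(5, tk.epochs))
                _, model, trials = search_hyperparameters(
                    space, tk.budget, (X_tr, y_tr), (X_dev, y_dev),
                    seed=base + 41 + mi)
                trial_rows += [{"modality": m, "trial": t["trial"],
                                "dev_auroc": t["dev_auroc"]} for t in trials]
            task_models[m] = model
            scalers[m] = scaler
            kept_idx[m] = keep
            dev_auc = ev.roc_auc(y_dev, model.predict_proba(X_dev)) \
                if len(np.unique(y_dev)) == 2 else float("nan")
            log.info("task_models[%s]: n_train=%d dev AUROC=%.3f",
                     m, X_tr.shape[0], dev_auc)
        if trial_rows:
            pd.DataFrame(trial_rows).to_csv(outdir / "task_trials.csv",
                                            index=False)
            _stage(manifest, outdir, "task_trials.csv")

        stage = "fusion"
        fz = config.fusion
        complete = np.ones(len(fdf), dtype=bool)
        for m in sc.MODALITIES:
            complete &= fdf[sc.feature_columns(m)[0]].notna().to_numpy()

        def feats_for(mask):
            sub = fdf[mask]
            return ({m: pp.apply_scaler(scalers[m], _modality_matrix(sub, m))
                     [:, kept_idx[m]] for m in sc.MODALITIES},
                    sub["pd_status"].to_numpy(dtype=int),
                    [sc.session_id(p, i) for p, i in
                     zip(sub["participant_id"], sub["session_index"])])

        tr_mask = complete & (fdf["split"] == "train").to_numpy()
        dev_mask = complete & (fdf["split"] == "dev").to_numpy()
        te_mask = complete & (fdf["split"] == "test").to_numpy()
        f_tr, y_tr, _ = feats_for(tr_mask)
        f_dev, y_dev, _ = feats_for(dev_mask)
        f_te, y_te, sid_te = feats_for(te_mask)
        stats_rng = np.random.default_rng(base + 51)
        p_tr, s_tr = task_level_stats(f_tr, task_models, fz.T, stats_rng)
        p_dev, s_dev = task_level_stats(f_dev, task_models, fz.T, stats_rng)
        p_te, s_te = task_level_stats(f_te, task_models, fz.T, stats_rng)
        if fz.budget <= 1:
            fspec = FusionSpec(
                projection_dim=fz.projection_dim, query_dim=fz.query_dim,
                hidden_dim=fz.hidden_dim, dropout_p=fz.dropout_p, eta=fz.eta,
                T=fz.T, learning_rate=fz.learning_rate,
                batch_size=fz.batch_size, epochs=fz.epochs,
                optimizer=fz.optimizer, momentum=fz.momentum,
                decision_threshold=fz.decision_threshold,
                ci_level=fz.ci_level, seed=base + 61)
            fusion = train_ufnet(f_tr, y_tr, p_tr, s_tr, fspec)
        else:
            _, fusion, _ = search_fusion_hyperparameters(
                default_fusion_space(), fz.budget,
                (f_tr, y_tr, p_tr, s_tr), (f_dev, y_dev, p_dev, s_dev),
                seed=base + 61)
        log.info("fusion: trained on %d complete sessions", len(y_tr))

        stage = "predict"
        preds = fuse_predict_from_stats(fusion, f_te, p_te, s_te, fz.T,
                                        np.random.default_rng(base + 71))
        decisions = [decide(p, fusion.spec.decision_threshold) for p in preds]
        pred_df = pd.DataFrame({
            "session_id": sid_te,
            "truth": y_te,
            "mean_p": [p.mean_p for p in preds],
            "sd_p": [p.sd_p for p in preds],
            "ci_low": [p.ci_low for p in preds],
            "ci_high": [p.ci_high for p in preds],
            "verdict": [d.verdict for d in decisions],
            "tap_p": p_te[:, 0], "smile_p": p_te[:, 1], "speech_p": p_te[:, 2],
        })
        pred_df.to_csv(outdir / "predictions.csv", index=False)
        _stage(manifest, outdir, "predictions.csv")

        stage = "evaluate"
        evc = config.evaluation
        report = ev.evaluate_predictions(
            y_te, pred_df["mean_p"].to_numpy(),
            pred_df["verdict"].to_numpy(), fusion.spec.decision_threshold,
            B=evc.bootstrap_B, level=evc.ci_level, seed=base + 81,
            ece_bins=evc.ece_bins)
        (outdir / "metrics.json").write_text(
            json.dumps(report.to_dict(), sort_keys=True, indent=1))
        _stage(manifest, outdir, "metrics.json")
        curve = ev.calibration_curve(pred_df["mean_p"].to_numpy(), y_te,
                                     evc.ece_bins)
        pd.DataFrame(curve, columns=["mean_prob", "observed_rate", "n"]) \
            .to_csv(outdir / "calibration.csv", index=False)
        _stage(manifest, outdir, "calibration.csv")
        task_verdicts = {m: (p_te[:, i] > 0.5).astype(int)
                         for i, m in enumerate(sc.MODALITIES)}
        fused_bin = (pred_df["mean_p"].to_numpy() > fusion.spec.decision_threshold
                     ).astype(int)
        ev.accuracy_by_agreement(task_verdicts, fused_bin, y_te) \
            .to_csv(outdir / "accuracy_by_agreement.csv", index=False)
        _stage(manifest, outdir, "accuracy_by_agreement.csv")
        log.info("evaluate: coverage=%.3f accuracy=%.3f",
                 report.coverage, report.metrics["accuracy"][0])
    except Exception as e:  # noqa: BLE001 - annotate and re-raise
        if isinstance(e, PipelineError):
            raise
        raise PipelineError(stage, e) from e

    manifest["artifacts"]["config.yaml"] = manifest.pop("config_sha256")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return outdir
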