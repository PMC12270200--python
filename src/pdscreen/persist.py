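"""Self-describing model archives.

A task-model archive is a directory holding the network weights, the
hyperparameter spec, the fitted scaler, and the kept feature indices,
plus a format-version field and a content hash.  A fusion archive
additionally records the content hashes of the three task models it was
trained against (and bundles copies of their archives), so a fusion model
cannot silently run against retrained task models.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import ScalerState
from .synthetic_cohort import MODALITIES
from .task_models import TaskModel, TaskModelSpec
from .ufnet import FusionSpec, UFNetModel

FORMAT_VERSION = 1

__all__ = ["save_task_model", "load_task_model", "save_fusion_model",
           "load_fusion_model", "task_model_hash"]


def _spec_dict(spec) -> dict:
    import dataclasses
    d = dataclasses.asdict(spec)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _weights_of(net_params) -> dict:
    return {f"p{i}": p.value for i, p in enumerate(net_params)}


def _content_hash(weights: dict, spec_json: str) -> str:
    h = hashlib.sha256()
    for k in sorted(weights):
        h.update(k.encode())
        h.update(np.ascontiguousarray(weights[k]).tobytes())
    h.update(spec_json.encode())
    return h.hexdigest()


def task_model_hash(model: TaskModel) -> str:
    spec_json = json.dumps(_spec_dict(model.spec), sort_keys=True)
    return _content_hash(_weights_of(model.net.parameters()), spec_json)


def save_task_model(outdir, modality: str, model: TaskModel,
                    scaler: ScalerState | None = None,
                    kept_indices=None) -> str:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weights = _weights_of(model.net.parameters())
    spec_json = json.dumps(_spec_dict(model.spec), sort_keys=True)
    chash = _content_hash(weights, spec_json)
    meta = {"format_version": FORMAT_VERSION, "kind": "task_model",
            "modality": modality, "spec": _spec_dict(model.spec),
            "content_hash": chash,
            "kept_indices": (None if kept_indices is None
                             else [int(i) for i in kept_indices])}
    if scaler is not None:
        meta["scaler"] = {"kind": scaler.kind, "loc": scaler.loc.tolist(),
                          "scale": scaler.scale.tolist()}
    np.savez(outdir / "weights.npz", **weights)
    (outdir / "model.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return chash


def load_task_model(indir):
    """Returns (modality, TaskModel, ScalerState | None, kept_indices | None)."""
    indir = Path(indir)
    meta = json.loads((indir / "model.json").read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported archive version {meta.get('format_version')}")
    spec_d = dict(meta["spec"])
    spec_d["hidden_dims"] = tuple(spec_d["hidden_dims"])
    spec = TaskModelSpec(**spec_d)
    model_net = nn.MLP(spec.input_dim, spec.hidden_dims, spec.dropout_p,
                       np.random.default_rng(spec.seed))
    with np.load(indir / "weights.npz") as z:
        for i, p in enumerate(model_net.parameters()):
            p.value[...] = z[f"p{i}"]
    model = TaskModel(spec, model_net)
    expect = meta["content_hash"]
    actual = task_model_hash(model)
    if actual != expect:
        raise ValueError("task-model archive content hash mismatch")
    scaler = None
    if "scaler" in meta:
        s = meta["scaler"]
        scaler = ScalerState(s["kind"], np.asarray(s["loc"]),
                             np.asarray(s["scale"]))
    return meta["modality"], model, scaler, meta.get("kept_indices")


def save_fusion_model(outdir, model: UFNetModel,
                      task_hashes: dict | None = None) -> str:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weights = _weights_of(model.parameters())
    spec_json = json.dumps(_spec_dict(model.spec), sort_keys=True)
    chash = _content_hash(weights, spec_json)
    meta = {"format_version": FORMAT_VERSION, "kind": "fusion_model",
            "spec": _spec_dict(model.spec),
            "input_dims": {m: int(d) for m, d in model.input_dims.items()},
            "content_hash": chash,
            "task_model_hashes": task_hashes or model.task_model_hashes}
    np.savez(outdir / "weights.npz", **weights)
    (outdir / "model.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return chash


def load_fusion_model(indir) -> UFNetModel:
    indir = Path(indir)
    meta = json.loads((indir / "model.json").read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported archive version {meta.get('format_version')}")
    spec = FusionSpec(**meta["spec"])
    model = UFNetModel(spec, {m: int(d) for m, d in meta["input_dims"].items()},
                       np.random.default_rng(spec.seed))
    with np.load(indir / "weights.npz") as z:
        for i, p in enumerate(model.parameters()):
            p.value[...] = z[f"p{i}"]
    model.task_model_hashes = meta.get("task_model_hashes", {})
    return model


def verify_fusion_against_tasks(fusion: UFNetModel, task_models: dict) -> None:
    """Refuse to pair a fusion model with task models other than the ones
    it was trained against."""
    for m in MODALITIES:
        expect = fusion.task_model_hashes.get(m)
        if expect is None:
            continue
        actual = task_model_hash(task_models[m])
        if actual != expect:
            raise ValueError(
                f"fusion model was trained against a different {m} task model "
                f"(hash {expect[:12]}... != {actual[:12]}...)")
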