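"""Portable model serialization: a JSON description plus binary weight shards.

``model.json`` holds the layer list (types, shapes, trainable flags), the
class names, the training config, the epoch history, and a shard manifest
listing every tensor (name, shape, dtype, byte count) in order.  Weights and
optimizer velocities are concatenated little-endian float64 in
``weights-00001.bin``; a length mismatch between manifest and shard is
rejected before anything is loaded.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np

from ..classifier import ClassifierConfig, TrainingState, build_model
from ..errors import ValidationError

SHARD_NAME = "weights-00001.bin"


def export_model(state: TrainingState, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    tensors: list[tuple[str, np.ndarray]] = []
    for name, _layer, _pname, arr in state.network.named_params():
        tensors.append((f"param/{name}", arr))
    for name in sorted(state.optimizer_state):
        tensors.append((f"optimizer/{name}", state.optimizer_state[name]))

    manifest = [
        {"name": n, "shape": list(a.shape), "dtype": "<f8", "nbytes": a.size * 8}
        for n, a in tensors
    ]
    description = {
        "format": "pixikit-model",
        "version": 1,
        "config": dataclasses.asdict(state.config),
        "class_names": list(state.class_names) if state.class_names else None,
        "epochs_completed": state.epochs_completed,
        "history": state.history,
        "layers": state.network.describe(),
        "weight_shards": [{"file": SHARD_NAME, "tensors": manifest}],
    }
    with open(os.path.join(out_dir, "model.json"), "w") as fh:
        json.dump(description, fh, indent=1)
    with open(os.path.join(out_dir, SHARD_NAME), "wb") as fh:
        for _, arr in tensors:
            fh.write(np.ascontiguousarray(arr, dtype="<f8").tobytes())


def import_model(in_dir) -> TrainingState:
    with open(os.path.join(in_dir, "model.json")) as fh:
        description = json.load(fh)
    if description.get("format") != "pixikit-model":
        raise ValidationError("not a pixikit model directory")
    cfg_dict = dict(description["config"])
    cfg_dict["input_extent"] = tuple(cfg_dict["input_extent"])
    config = ClassifierConfig(**cfg_dict)
    head = next(l for l in description["layers"] if l["name"] == "head")
    state = build_model(config, head["out_features"], description["class_names"])
    state.epochs_completed = description["epochs_completed"]
    state.history = list(description["history"])

    shard = description["weight_shards"][0]
    path = os.path.join(in_dir, shard["file"])
    expected = sum(t["nbytes"] for t in shard["tensors"])
    actual = os.path.getsize(path)
    if actual != expected:
        raise ValidationError(
            f"weight shard {shard['file']} has {actual} bytes, manifest "
            f"declares {expected}: shape mismatch"
        )
    blob = np.fromfile(path, dtype="<f8")
    params = {f"param/{n}": (layer, pname) for n, layer, pname, _ in state.network.named_params()}
    offset = 0
    for entry in shard["tensors"]:
        size = int(np.prod(entry["shape"])) if entry["shape"] else 1
        arr = blob[offset : offset + size].reshape(entry["shape"])
        offset += size
        name = entry["name"]
        if name.startswith("param/"):
            if name not in params:
                raise ValidationError(f"unknown tensor {name!r} in shard")
            layer, pname = params[name]
            if layer.params[pname].shape != arr.shape:
                raise ValidationError(f"shape mismatch for tensor {name!r}")
            layer.params[pname] = arr.copy()
        elif name.startswith("optimizer/"):
            state.optimizer_state[name[len("optimizer/"):]] = arr.copy()
    return state
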