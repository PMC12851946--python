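"""Save/load the MIL model as a versioned npz archive with embedded config."""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .net import AttentionMILModel, MILConfig

FORMAT_VERSION = 1


def save_model(model: AttentionMILModel, path) -> None:
    arrays = {}
    for key, obj, pname, _ in model._params():
        arrays[key] = getattr(obj, pname)
    meta = {
        "format_version": FORMAT_VERSION,
        "config": dataclasses.asdict(model.config),
        "trained": bool(model.trained),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> AttentionMILModel:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    if meta["format_version"] != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {meta['format_version']}")
    cfg_raw = meta["config"]
    for k in ("channels", "class_weights"):
        if cfg_raw.get(k) is not None:
            cfg_raw[k] = tuple(cfg_raw[k])
    model = AttentionMILModel(MILConfig(**cfg_raw))
    for key, obj, pname, _ in model._params():
        setattr(obj, pname, data[key])
    model.trained = meta["trained"]
    return model
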