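"""Model persistence: network weights plus their stage config, with a hash.

Models are stored as a single ``.npz`` containing the weight arrays, the
dataclass config as JSON, a kind tag ('loc' or 'seg') and a SHA-256 hash
of the config JSON so a mismatched config/weights pair is detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np

from . import locnet, nn, segnet


def _config_json(cfg) -> str:
    return json.dumps(dataclasses.asdict(cfg), sort_keys=True)


def config_hash(cfg) -> str:
    return hashlib.sha256(_config_json(cfg).encode()).hexdigest()[:16]


def save_model(model, path) -> None:
    if isinstance(model, locnet.LocModel):
        kind = "loc"
    elif isinstance(model, segnet.SegModel):
        kind = "seg"
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    state = model.net.state_dict()
    np.savez_compressed(
        path,
        __kind__=np.array(kind),
        __config__=np.array(_config_json(model.config)),
        __hash__=np.array(config_hash(model.config)),
        **state,
    )


def load_model(path):
    with np.load(path, allow_pickle=False) as z:
        kind = str(z["__kind__"])
        cfg_json = json.loads(str(z["__config__"]))
        stored_hash = str(z["__hash__"])
        state = {k: z[k] for k in z.files if not k.startswith("__")}
    def _detuple(d):
        return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

    if kind == "loc":
        cfg = locnet.LocConfig(**_detuple(cfg_json))
    elif kind == "seg":
        cfg = segnet.SegConfig(**_detuple(cfg_json))
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    if config_hash(cfg) != stored_hash:
        raise ValueError("config hash mismatch: corrupted model file")
    net = nn.UNet3d(
        levels=cfg.levels,
        base_filters=cfg.base_filters,
        dropout=cfg.dropout,
        bottleneck_feature_reduction=cfg.bottleneck_feature_reduction,
        seed=cfg.seed,
    )
    net.load_state_dict(state)
    if kind == "loc":
        return locnet.LocModel(config=cfg, net=net)
    return segnet.SegModel(config=cfg, net=net)
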