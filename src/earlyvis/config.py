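"""Run configuration: defaults, YAML loading, validation, hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

#: Full-scale defaults mirror the study conditions: 20x20 deg images at
#: 5 px/deg, 1e5 training patches of 3x3 deg, 225 SC units, 150 ICA units,
#: 225 STDP neurons, gratings at 1.25 cycles/deg with SNR -6..6 dB.
DEFAULTS: dict = {
    "data": {
        "source": "synthetic",          # synthetic | image-directory
        "image_dir": None,
        "n_images": 139,
        "field_deg": 20.0,
        "px_per_deg": 5.0,
        "spectral_exponent": 1.0,
        "structure": "gabors",          # gabors (sparse components) | none (pure 1/f)
        "n_patches": 100_000,
        "patch_deg": 3.0,
    },
    "sc": {"n_units": 225, "epochs": 10, "batch": 100, "infer_iters": 80},
    "ica": {"d": 150, "tol": 1e-4, "max_iter": 200, "contrast": "logcosh"},
    "stdp": {
        "n_neurons": 225,
        "mode": "merged",               # merged | split polarity afferents
        "top_fraction": 0.1,
        "sigma_c_deg": 0.2,
        "surround_ratio": 3.0,
        "theta": None,                  # None -> calibrated default
    },
    "probe": {
        "frequency": 1.25,
        "orient_step_deg": 4.0,
        "otc_orient_step_deg": 2.0,
        "otc_phase_step_deg": 5.0,
        "n_phases": 8,
        "reps": 100,
        "snr_db_grid": list(range(-6, 7)),
        "threshold_scales": [-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75],
        "r2_min": 0.5,
        "sparsity_patches": 10_000,
    },
    "seed": 0,
}

_SCALABLE = [("data", "n_patches"), ("probe", "reps"), ("probe", "sparsity_patches")]


def load_config(path: str | Path | None = None, scale: float = 1.0,
                seed: int | None = None) -> dict:
    """Merge a YAML config over the defaults; optionally rescale workloads.

    ``scale`` < 1 shrinks patch counts and repetition counts proportionally
    (floored at usable minimums) for reduced-scale runs.
    """
    cfg = json.loads(json.dumps(DEFAULTS))
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        _merge(cfg, user)
    if seed is not None:
        cfg["seed"] = int(seed)
    if scale != 1.0:
        if not (0 < scale <= 1):
            raise ValueError("scale must be in (0, 1]")
        for sec, key in _SCALABLE:
            cfg[sec][key] = max(10, int(round(cfg[sec][key] * scale)))
    _validate(cfg)
    return cfg


def _merge(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if k not in base:
            raise KeyError(f"unknown config key: {k}")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise TypeError(f"config section {k} must be a mapping")
            _merge(base[k], v)
        else:
            base[k] = v


def _validate(cfg: dict) -> None:
    d = cfg["data"]
    if d["source"] not in ("synthetic", "image-directory"):
        raise ValueError("data.source must be 'synthetic' or 'image-directory'")
    if d["source"] == "image-directory" and not d["image_dir"]:
        raise ValueError("data.source=image-directory requires data.image_dir")
    if d["n_patches"] < 1:
        raise ValueError("data.n_patches must be >= 1")
    if cfg["stdp"]["mode"] not in ("merged", "split"):
        raise ValueError("stdp.mode must be 'merged' or 'split'")
    if not (0 < cfg["stdp"]["top_fraction"] <= 1):
        raise ValueError("stdp.top_fraction must be in (0, 1]")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
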