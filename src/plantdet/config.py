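"""Run configuration: defaults, YAML loading, validation and overrides."""
from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "ConfigError", "parse_config", "resolve_config",
           "dump_config"]

DEFAULT_CONFIG = {
    "seed": 0,
    "train": {
        "input_size": 600,
        "learning_rate": 1.0e-4,
        "batch_size": 4,
        "epochs": 100,
        "optimizer": "adam",
        "momentum": 0.9,
        "weight_decay": 5.0e-4,
        "max_steps": None,
    },
    "rpn": {
        "ratios": [0.5, 1.0, 2.0],
        "anchor_scales": [8, 16, 32],
        "feat_stride": 16,
        "nms_iou": 0.7,
        "pre_nms_top_n": 3000,
        "post_nms_top_n": 300,
    },
    "backbone": {
        "light": True,
        "stage_blocks": [3, 4, 6, 3],
        "stage_mid_channels": [64, 128, 256, 512],
        "stem_channels": 64,
        "sam_stages": [False, False, False, False],
    },
    "sam": {
        "groups": 1,
        "kernel": 7,
    },
    "enhance": {
        "method": "unsharp_mask",
        "k": 1.5,
        "sigma": 2.0,
        "kernel_size": 13,
        "enabled": True,
    },
    "eval": {
        "iou": 0.5,
        "score_thr": 0.5,
        "test_nms_iou": 0.3,
    },
    "synth": {
        "n_images": 50,
        "occlusion_prob": 0.2,
        "clutter_level": 0.3,
    },
    "split": {
        "ratios": [0.8, 0.1, 0.1],
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = ""):
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here}: expected a mapping, got {type(value).__name__}")
            _merge(base[key], value, here)
        else:
            if base[key] is not None and value is not None:
                expected = type(base[key])
                if expected is float and isinstance(value, int):
                    value = float(value)
                elif expected is not bool and isinstance(value, bool):
                    raise ConfigError(f"{here}: expected {expected.__name__}, got bool")
                elif not isinstance(value, expected):
                    raise ConfigError(
                        f"{here}: expected {expected.__name__}, "
                        f"got {type(value).__name__}")
            base[key] = value


def parse_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults + optional YAML file + optional flag overrides, validated."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        _merge(cfg, loaded)
    if overrides:
        _merge(cfg, overrides)
    return cfg


resolve_config = parse_config


def dump_config(cfg: dict, out_dir) -> Path:
    """Write the resolved config beside the run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
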