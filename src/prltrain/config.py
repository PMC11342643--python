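"""Configuration defaults and YAML/JSON loading.

A single nested dict with sections ``grid``, ``amsler``, ``exercises``,
``recommender`` and ``simulator``.  User files (YAML or JSON — JSON is valid
YAML) are deep-merged over the defaults, so a file only needs the keys it
overrides.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict = {
    "grid": {
        "width_cm": 10.0,
        "height_cm": 10.0,
        "spacing_cm": 0.5,
        "working_distance_cm": 30.0,
        "diagonal_lines": False,
        "thick_center": False,
    },
    "amsler": {
        # 50 red-dot stimuli, 3 s display + 3 s to respond before the next one
        "n_stimuli_full": 50,
        "display_s": 3.0,
        "response_window_s": 3.0,
        # follow-up tests halve the stimulus count (rounded up) and restrict
        # placement to the environment of the known scotoma
        "followup_fraction": 0.5,
        "environment_chebyshev": 2,
    },
    "exercises": {
        "default_n_stimuli": 10,
        "target_fraction": 0.5,
        "fixation_separation_cm": 4.0,
    },
    "recommender": {
        "alpha": 0.3,                 # ability EWMA learning rate
        "band": [0.6, 0.8],           # target per-session success band
        "delta": 0.1,                 # difficulty margin above ability
        "step_factor": 1.5,           # one self-adjustment step on size/interval
        "rolling_window": 10,         # sessions in the rolling success rate
        "ability_prior": 0.5,
    },
    "simulator": {
        "scotoma": {"kind": "block", "row0": 5, "col0": 11, "n_rows": 3, "n_cols": 3},
        "p_detect_inside": 0.05,
        "p_detect_outside": 0.98,
        "edge_softness_cm": 0.0,
        "ability": 0.6,
        "logistic_slope": 8.0,
        "false_alarm_prob": 0.02,
        "rt_mean_s": 0.9,
        "rt_sd_s": 0.3,
        "rt_floor_s": 0.2,
        "compliance_prob": 1.0,
    },
}


def merge_config(base: dict, override: dict) -> dict:
    """Recursively merge ``override`` into a deep copy of ``base``."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML/JSON config file merged over :data:`DEFAULTS`."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        loaded = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(loaded, dict):
        raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
    return merge_config(DEFAULTS, loaded)
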