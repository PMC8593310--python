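"""YAML run-configuration loading.

A configuration file uses plain key-value blocks; every key is optional
and falls back to the package default, e.g.::

    driving:
      speed_kmh: 120
      sigma_d: 0.05
      p_obs_correct: 0.9
    search:
      n_items: 9
      reward_found: 10
    learning:
      drive: {n_episodes: 2000, alpha: 0.1}
      search: {n_episodes: 500}
      supervisory: {n_episodes: 2000}
    supervisory:
      q_bins: 12
      search_reward_weight: 1.0

Key aliases match the external interface names (``speed_kmh`` /
``lane_width_m`` / ``dt_drive_s`` / ``curvature_drift_mps`` ...).
"""

from __future__ import annotations

import dataclasses
from typing import Any

import yaml

from .driving import ConfigurationError, DrivingParams
from .rl import LearningParams
from .search import SearchParams
from .supervisory import MultitaskConfig

_DRIVING_ALIASES = {
    "lane_width": "lane_width_m",
    "dt_drive": "dt_drive_s",
    "curvature_drift": "curvature_drift_mps",
}


def _build(cls, block: dict[str, Any], aliases: dict[str, str] | None = None):
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in (block or {}).items():
        name = (aliases or {}).get(key, key)
        if name not in fields:
            raise ConfigurationError(f"unknown {cls.__name__} key: {key!r}")
        if name == "action_set":
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> MultitaskConfig:
    """Build a MultitaskConfig from a YAML file; missing keys default."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    learning = raw.get("learning", {})
    sup_block = dict(raw.get("supervisory", {}))
    return MultitaskConfig(
        driving=_build(DrivingParams, raw.get("driving", {}), _DRIVING_ALIASES),
        search=_build(SearchParams, raw.get("search", {})),
        drive_learning=_build(LearningParams, learning.get("drive", {})),
        search_learning=_build(LearningParams, learning.get("search", {})),
        supervisory_learning=_build(LearningParams, learning.get("supervisory", {})),
        **sup_block,
    )


def resolved_config_dict(config: MultitaskConfig) -> dict[str, Any]:
    """Echo of the fully resolved configuration (for run manifests)."""
    return {
        "driving": dataclasses.asdict(config.driving),
        "search": dataclasses.asdict(config.search),
        "learning": {
            "drive": dataclasses.asdict(config.drive_learning),
            "search": dataclasses.asdict(config.search_learning),
            "supervisory": dataclasses.asdict(config.supervisory_learning),
        },
        "supervisory": {
            "switch_cost_s": config.switch_cost,
            "display_separation_deg": config.display_separation_deg,
            "q_bins": config.q_bins,
            "search_reward_weight": config.search_reward_weight,
            "n_entropy_bins": config.n_entropy_bins,
            "trial_time_limit_s": config.trial_time_limit_s,
            "eval_tau": config.eval_tau,
        },
    }


def dump_config(config: MultitaskConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(resolved_config_dict(config), fh, sort_keys=False)
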