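"""TOML task-configuration loading and bundled presets."""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path
from typing import Any

from ..engine import EpochSpec, TaskConfig

PRESETS = ("two_choice", "hf_shaping", "fm_shaping_1", "fm_shaping_2", "gonogo")


def _side(value: str | None) -> str | None:
    if value in (None, "", "none", "either"):
        return None
    if value not in ("left", "right", "center"):
        raise ValueError(f"unknown reward port {value!r}")
    return value


def config_from_dict(data: dict[str, Any]) -> TaskConfig:
    task = data["task"]
    end = data.get("session_end", {})
    sched = data["schedule"]
    zone = data.get("reward_zone", {})
    adjust = data.get("adjustable", {})
    epochs = []
    for ep in data["epochs"]:
        rng = ep.get("duration_range_s")
        epochs.append(
            EpochSpec(
                name=ep["name"],
                trigger=ep["trigger"],
                length_cm=ep.get("length_cm"),
                duration_s=ep.get("duration_s"),
                duration_range_s=tuple(rng) if rng else None,
                sensor=ep.get("sensor"),
                timeout_s=ep.get("timeout_s"),
                post_reward_s=ep.get("post_reward_s", 0.5),
                decision=ep.get("decision", False),
                stimulus=ep.get("stimulus"),
            )
        )
    probs = dict(zip(sched["trial_types"], sched["probs"]))
    contingency = {k: _side(v) for k, v in data.get("contingency", {}).items()}
    return TaskConfig(
        task_kind=task["kind"],
        epochs=epochs,
        trial_types=list(sched["trial_types"]),
        type_probs=probs,
        contingency=contingency,
        max_consecutive=sched.get("max_consecutive", 3),
        n_trials=task.get("n_trials", 1000),
        drop_volume_ul=task.get("drop_volume_ul", 6.0),
        iti_s=task.get("iti_s", 2.0),
        response_delay_s=task.get("response_delay_s", 0.0),
        max_rewards=end.get("max_rewards", 125),
        max_duration_min=end.get("max_duration_min", 90.0),
        reward_zone_open_cm=zone.get("open_cm"),
        auto_delivery_cm=zone.get("auto_delivery_cm"),
        auto_release_after_s=task.get("auto_release_after_s", 2.0),
        auto_water=adjust.get("auto_water", False),
        x_left=adjust.get("x_left", False),
        x_right=adjust.get("x_right", False),
        autoclicker=adjust.get("autoclicker", False),
        side_bias_rule=adjust.get("side_bias_rule", False),
        metadata=dict(data.get("metadata", {})),
    )


def config_from_snapshot(snapshot: dict[str, Any]) -> TaskConfig:
    """Rebuild a TaskConfig from the dict snapshot stored in session.json."""
    data = dict(snapshot)
    epochs = []
    for ep in data.pop("epochs"):
        ep = dict(ep)
        rng = ep.get("duration_range_s")
        ep["duration_range_s"] = tuple(rng) if rng else None
        epochs.append(EpochSpec(**ep))
    return TaskConfig(epochs=epochs, **data)


def load_config(source: str | Path) -> TaskConfig:
    """Load a task configuration from a TOML file path or a preset name."""
    name = str(source)
    if name in PRESETS:
        text = resources.files(__package__).joinpath(f"{name}.toml").read_text()
        data = tomllib.loads(text)
    else:
        with open(source, "rb") as fh:
            data = tomllib.load(fh)
    return config_from_dict(data)
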