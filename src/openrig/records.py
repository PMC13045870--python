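"""Standardized trial-record data model and session artifacts.

A session produces two kinds of artifacts:

* an MCU event log — one text file of timestamped events on the lick-port
  controller's own millisecond clock (licks, valve openings, state
  transitions, TTL edges);
* a per-trial record directory — one JSON file per trial holding the
  trial-aligned output structure (timestamps with event flags, combined
  encoder/velocity/frame/pupil arrays), plus a ``session.json`` with the
  configuration snapshot, the parameter-change log, and session metadata.

Per-trial JSON keys deliberately use the camelCase field names of the
original acquisition format (``TrialID``, ``isLickLeft``, ...) so records
are field-compatible with data produced on a physical rig.  All times in
trial records are seconds relative to the anchor-epoch onset (negative
before onset); MCU log times are integer milliseconds.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

#: Event codes accepted in an MCU log.
EVENT_CODES = (
    "LICK_L",
    "LICK_R",
    "VALVE_L",
    "VALVE_R",
    "VALVE",
    "STATE",
    "INIT_TOUCH",
    "TTL_HIGH",
    "TTL_LOW",
    "MANUAL_OPEN",
    "CLICK",
)

MCU_LOG_HEADER = "# mcu_log v1"

#: JSON field name -> TrialRecord attribute, in serialization order.
TRIAL_FIELD_MAP = [
    ("TrialID", "trial_id"),
    ("TrialType", "trial_type"),
    ("NoOfTimestamps", "n_timestamps"),
    ("Timestamps", "timestamps"),
    ("isLickLeft", "is_lick_left"),
    ("isLickRight", "is_lick_right"),
    ("isGratingStart", "is_epoch_start"),
    ("isRewardZoneEntry", "is_reward_zone_entry"),
    ("isRewardTriggered", "is_reward_triggered"),
    ("isGratingEnd", "is_epoch_end"),
    ("isManualOpen", "is_manual_open"),
    ("encoderData_combined", "encoder_combined"),
    ("Velocity", "velocity"),
    ("frameData_combined", "frame_combined"),
    ("pupilRadius_combined", "pupil_radius_combined"),
]

FLAG_ATTRS = (
    "is_lick_left",
    "is_lick_right",
    "is_epoch_start",
    "is_reward_zone_entry",
    "is_reward_triggered",
    "is_epoch_end",
    "is_manual_open",
)

VALID_END_REASONS = ("max_rewards", "max_duration", "manual")


@dataclass
class McuLogLine:
    """One timestamped event on the MCU clock (integer milliseconds)."""

    device_time: int
    event_code: str
    arg: str = ""

    def __post_init__(self) -> None:
        if self.event_code not in EVENT_CODES:
            raise ValueError(f"unknown event code {self.event_code!r}")


@dataclass
class TrialRecord:
    """Per-trial output structure.

    ``timestamps`` are seconds relative to the anchor-epoch onset on the
    MCU clock; the seven boolean flag vectors mark the event kind of each
    timestamp.  Combined arrays carry external-device samples on the
    program clock, also anchor-relative.  ``encoder_combined`` positions
    are in corridor coordinates: negative = distance left to travel in the
    approach epoch, non-negative = distance into the anchor epoch.
    """

    trial_id: int
    trial_type: str
    timestamps: list[float] = field(default_factory=list)
    is_lick_left: list[bool] = field(default_factory=list)
    is_lick_right: list[bool] = field(default_factory=list)
    is_epoch_start: list[bool] = field(default_factory=list)
    is_reward_zone_entry: list[bool] = field(default_factory=list)
    is_reward_triggered: list[bool] = field(default_factory=list)
    is_epoch_end: list[bool] = field(default_factory=list)
    is_manual_open: list[bool] = field(default_factory=list)
    encoder_combined: list[list[float]] = field(default_factory=list)
    velocity: list[list[float]] = field(default_factory=list)
    frame_combined: list[list[float]] = field(default_factory=list)
    pupil_radius_combined: list[list[float]] = field(default_factory=list)
    outcome: str | None = None  # extension field, not part of the core format

    @property
    def n_timestamps(self) -> int:
        return len(self.timestamps)

    def flag_vectors(self) -> dict[str, list[bool]]:
        return {name: getattr(self, name) for name in FLAG_ATTRS}


@dataclass
class ParameterChange:
    trial_index: int
    parameter: str
    old: Any
    new: Any


@dataclass
class SessionRecord:
    """A full session: ordered trial records plus bookkeeping."""

    session_id: str
    config: dict[str, Any]
    trials: list[TrialRecord]
    parameter_log: list[ParameterChange] = field(default_factory=list)
    start_time: str = ""
    end_reason: str = "manual"
    reward_count: int = 0
    reward_volume_ul: float = 0.0
    total_volume_ul: float = 0.0
    frame_paths: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# MCU log
# ---------------------------------------------------------------------------

def write_mcu_log(events: Sequence[McuLogLine], path: str | os.PathLike) -> None:
    """Write a v1 MCU log: header line then one tab-separated line per event.

    Events must be time-ordered (non-decreasing device time); violations
    are rejected with the index of the first out-of-order event.
    """
    for i in range(1, len(events)):
        if events[i].device_time < events[i - 1].device_time:
            raise ValueError(f"events out of order at index {i}")
    with open(path, "w") as fh:
        fh.write(MCU_LOG_HEADER + "\n")
        for ev in events:
            fh.write(f"{ev.device_time}\t{ev.event_code}\t{ev.arg}\n")


def parse_mcu_log(path: str | os.PathLike) -> list[McuLogLine]:
    """Exact inverse of :func:`write_mcu_log`."""
    events: list[McuLogLine] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != MCU_LOG_HEADER:
            raise ValueError(f"not a v1 MCU log: header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed line {lineno}: {line!r}")
            t, code, arg = parts
            try:
                device_time = int(t)
            except ValueError as exc:
                raise ValueError(f"malformed time on line {lineno}: {t!r}") from exc
            if code not in EVENT_CODES:
                raise ValueError(f"unknown event code on line {lineno}: {code!r}")
            events.append(McuLogLine(device_time, code, arg))
    return events


# ---------------------------------------------------------------------------
# JSON trial records
# ---------------------------------------------------------------------------

def _encode(value: Any) -> Any:
    """Recursively encode, mapping NaN to the string "NaN" (JSON has no NaN)."""
    if isinstance(value, float):
        return "NaN" if math.isnan(value) else value
    if isinstance(value, (np.floating,)):
        v = float(value)
        return "NaN" if math.isnan(v) else v
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (list, tuple)):
        return [_encode(v) for v in value]
    if isinstance(value, np.ndarray):
        return [_encode(v) for v in value.tolist()]
    return value


def _decode(value: Any) -> Any:
    if value == "NaN":
        return float("nan")
    if isinstance(value, list):
        return [_decode(v) for v in value]
    return value


def _trial_filename(trial_id: int) -> str:
    return f"trial_{trial_id:04d}.json"


def write_trial_records(session: SessionRecord, directory: str | os.PathLike) -> None:
    """Write ``session.json`` plus one JSON file per trial.

    Trial JSON uses the acquisition-format field names (``TrialID``,
    ``isLickLeft``, ...); NaN values are serialized as the string "NaN".
    """
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    meta = {
        "session_id": session.session_id,
        "config": session.config,
        "n_trials": len(session.trials),
        "parameter_log": [asdict(p) for p in session.parameter_log],
        "start_time": session.start_time,
        "end_reason": session.end_reason,
        "reward_count": session.reward_count,
        "reward_volume_ul": session.reward_volume_ul,
        "total_volume_ul": session.total_volume_ul,
        "frame_paths": session.frame_paths,
    }
    with open(os.path.join(directory, "session.json"), "w") as fh:
        json.dump(_encode(meta), fh, indent=1)
    for trial in session.trials:
        payload: dict[str, Any] = {}
        for json_name, attr in TRIAL_FIELD_MAP:
            if attr == "n_timestamps":
                payload[json_name] = trial.n_timestamps
            else:
                payload[json_name] = _encode(getattr(trial, attr))
        if trial.outcome is not None:
            payload["outcome"] = trial.outcome
        with open(os.path.join(directory, _trial_filename(trial.trial_id)), "w") as fh:
            json.dump(payload, fh)


def read_trial_records(directory: str | os.PathLike) -> SessionRecord:
    """Read a trial-record directory written by :func:`write_trial_records`."""
    directory = str(directory)
    with open(os.path.join(directory, "session.json")) as fh:
        meta = _decode(json.load(fh))
    trials: list[TrialRecord] = []
    for i in range(1, int(meta["n_trials"]) + 1):
        path = os.path.join(directory, _trial_filename(i))
        with open(path) as fh:
            payload = json.load(fh)
        kwargs: dict[str, Any] = {}
        for json_name, attr in TRIAL_FIELD_MAP:
            if attr == "n_timestamps":
                continue
            if json_name not in payload:
                raise ValueError(f"trial {i}: missing required field {json_name!r}")
            kwargs[attr] = _decode(payload[json_name])
        rec = TrialRecord(outcome=payload.get("outcome"), **kwargs)
        if int(payload["NoOfTimestamps"]) != rec.n_timestamps:
            raise ValueError(f"trial {i}: NoOfTimestamps does not match Timestamps")
        trials.append(rec)
    return SessionRecord(
        session_id=meta["session_id"],
        config=meta["config"],
        trials=trials,
        parameter_log=[ParameterChange(**p) for p in meta["parameter_log"]],
        start_time=meta["start_time"],
        end_reason=meta["end_reason"],
        reward_count=int(meta["reward_count"]),
        reward_volume_ul=float(meta["reward_volume_ul"]),
        total_volume_ul=float(meta["total_volume_ul"]),
        frame_paths=list(meta.get("frame_paths", [])),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    trial_id: int | None
    rule: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        where = f"trial {self.trial_id}" if self.trial_id is not None else "session"
        return f"{where}: {self.rule}: {self.detail}"


def validate_session(session: SessionRecord) -> list[Violation]:
    """Check every trial-record invariant; an empty report means valid."""
    report: list[Violation] = []

    ids = [t.trial_id for t in session.trials]
    if ids != list(range(1, len(ids) + 1)):
        report.append(Violation(None, "trial_ids", "ids must be dense and increasing from 1"))
    if session.end_reason not in VALID_END_REASONS:
        report.append(Violation(None, "end_reason", f"unknown end reason {session.end_reason!r}"))
    expected_vol = session.reward_count * session.reward_volume_ul
    if not math.isclose(expected_vol, session.total_volume_ul, rel_tol=1e-9, abs_tol=1e-6):
        report.append(
            Violation(None, "volume", f"reward_count*volume={expected_vol} != total {session.total_volume_ul}")
        )

    last_frame = -np.inf
    for trial in session.trials:
        n = trial.n_timestamps
        for name, vec in trial.flag_vectors().items():
            if len(vec) != n:
                report.append(Violation(trial.trial_id, "flag_length", f"{name} has length {len(vec)} != {n}"))
        flags = list(trial.flag_vectors().values())
        if all(len(v) == n for v in flags):
            for i in range(n):
                k = sum(bool(v[i]) for v in flags)
                if k == 0:
                    report.append(Violation(trial.trial_id, "flag_missing", f"timestamp {i} has no event flag"))
                elif k > 1:
                    report.append(Violation(trial.trial_id, "flag_multiple", f"timestamp {i} has {k} flags set"))
        n_starts = sum(bool(v) for v in trial.is_epoch_start)
        if n_starts > 1:
            report.append(Violation(trial.trial_id, "epoch_start", f"{n_starts} anchor-epoch starts"))
        if trial.velocity:
            if not trial.encoder_combined or len(trial.velocity) != len(trial.encoder_combined):
                report.append(Violation(trial.trial_id, "velocity_shape", "velocity/encoder lengths differ"))
            else:
                tv = [row[0] for row in trial.velocity]
                te = [row[0] for row in trial.encoder_combined]
                if tv != te:
                    report.append(Violation(trial.trial_id, "velocity_time", "velocity/encoder time columns differ"))
            if not math.isnan(trial.velocity[0][1]):
                report.append(
                    Violation(trial.trial_id, "velocity_first_nan", "first velocity sample must be NaN")
                )
        for row in trial.frame_combined:
            if row[1] <= last_frame:
                report.append(
                    Violation(trial.trial_id, "frame_order", f"frame number {row[1]} not strictly increasing")
                )
            last_frame = row[1]
    return report


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def export_session_csv(session: SessionRecord, directory: str | os.PathLike) -> tuple[str, str]:
    """Export a long-format event CSV and a per-trial summary CSV.

    Returns ``(events_path, summary_path)``.  The event CSV has one row
    per recorded timestamp (``trial_id, time, event``); the summary CSV
    one row per trial.
    """
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    flag_to_event = {
        "is_lick_left": "lick_left",
        "is_lick_right": "lick_right",
        "is_epoch_start": "epoch_start",
        "is_reward_zone_entry": "reward_zone_entry",
        "is_reward_triggered": "reward_triggered",
        "is_epoch_end": "epoch_end",
        "is_manual_open": "manual_open",
    }
    event_rows = []
    summary_rows = []
    for trial in session.trials:
        flags = trial.flag_vectors()
        for i, t in enumerate(trial.timestamps):
            label = next((flag_to_event[k] for k, v in flags.items() if v[i]), "unknown")
            event_rows.append({"trial_id": trial.trial_id, "time": t, "event": label})
        summary_rows.append(
            {
                "trial_id": trial.trial_id,
                "trial_type": trial.trial_type,
                "outcome": trial.outcome if trial.outcome is not None else "",
                "n_licks_left": int(sum(bool(v) for v in trial.is_lick_left)),
                "n_licks_right": int(sum(bool(v) for v in trial.is_lick_right)),
                "rewarded": bool(any(trial.is_reward_triggered)),
            }
        )
    events_path = os.path.join(directory, "events.csv")
    summary_path = os.path.join(directory, "trials.csv")
    pd.DataFrame(event_rows, columns=["trial_id", "time", "event"]).to_csv(events_path, index=False)
    pd.DataFrame(
        summary_rows,
        columns=["trial_id", "trial_type", "outcome", "n_licks_left", "n_licks_right", "rewarded"],
    ).to_csv(summary_path, index=False)
    return events_path, summary_path
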