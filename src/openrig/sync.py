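"""Two-clock alignment of device streams into per-trial records.

The platform stamps lick/valve/state events on the MCU clock and
external-device samples (encoder, camera triggers) on the program clock.
Alignment never crosses clocks: each trial's timestamps are re-expressed
relative to the anchor-epoch onset *on the clock that produced them*, so
clock offset and drift cancel within a trial.  Times before anchor onset
are negative; approach-corridor positions are expressed as negative
distance-to-go until the anchor epoch begins.

Trials missing their anchor onset (e.g. a session that ended during the
approach) are excluded, not interpolated, and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .engine import TaskConfig
from .records import McuLogLine, SessionRecord, TrialRecord
from .rig import RawSession

TTL_PERIOD_S = 1.0 / 300.0  # MCU TTL polling period


@dataclass
class AlignmentSpec:
    """Names that define trial structure for alignment."""

    first_epoch: str
    anchor_epoch: str
    epoch_names: tuple[str, ...]
    approach_offset_cm: float = 0.0  # corridor length preceding the anchor epoch


def spec_for_config(config: TaskConfig) -> AlignmentSpec:
    decision = config.decision_epoch()
    anchor = decision.name if decision is not None else config.epochs[-1].name
    offset = 0.0
    for ep in config.epochs:
        if ep.name == anchor:
            break
        offset += ep.length_cm or 0.0
    return AlignmentSpec(
        first_epoch=config.epochs[0].name,
        anchor_epoch=anchor,
        epoch_names=tuple(ep.name for ep in config.epochs),
        approach_offset_cm=offset,
    )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def compute_velocity(encoder_combined: np.ndarray) -> np.ndarray:
    """Finite-difference velocity with the same time column as the input.

    ``v[i] = (x[i]-x[i-1]) / (t[i]-t[i-1])``; the first sample is NaN by
    convention.  Duplicate timestamps are an error (they indicate an
    upstream bug), reported with the offending indices.
    """
    enc = np.asarray(encoder_combined, dtype=float)
    if enc.size == 0:
        return np.empty((0, 2))
    t, x = enc[:, 0], enc[:, 1]
    dt = np.diff(t)
    dup = np.nonzero(dt == 0)[0]
    if dup.size:
        raise ValueError(f"duplicate encoder timestamps at indices {dup.tolist()} / {(dup + 1).tolist()}")
    v = np.empty_like(t)
    v[0] = np.nan
    v[1:] = np.diff(x) / dt
    return np.column_stack([t, v])


def merge_frames(
    frame_triggers: np.ndarray, radii_by_frame: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pair camera triggers with per-frame pupil radii.

    ``frame_triggers`` is (time, frame number); the returned arrays
    share its time column, with radii looked up by frame number.
    """
    trig = np.asarray(frame_triggers, dtype=float)
    if trig.size == 0:
        return np.empty((0, 2)), np.empty((0, 2))
    numbers = trig[:, 1].astype(int)
    radii = np.asarray(radii_by_frame, dtype=float)[numbers]
    return trig.copy(), np.column_stack([trig[:, 0], radii])


def sample_ttl(ttl_edges: np.ndarray, period: float = TTL_PERIOD_S) -> np.ndarray:
    """Timestamp TTL transitions at the MCU polling grid.

    Each true edge is reported at the first sampling tick at or after
    the edge, so latency is in ``[0, period)``.
    """
    edges = np.asarray(ttl_edges, dtype=float)
    ticks = np.ceil(edges / period - 1e-9) * period
    return ticks


def clock_discrepancy(raw: RawSession) -> tuple[float, float]:
    """Per-epoch duration disagreement between the two clocks (ms).

    For every epoch of every aligned trial, compares the MCU-stamped
    duration with the program-stamped duration; returns (mean, max) of
    the absolute differences in milliseconds.
    """
    spec = spec_for_config(raw.config)
    mcu_trials = _mcu_trials(raw.mcu_events, spec)
    prog_trials = _program_trials(raw.program_epochs)
    diffs = []
    for mcu, prog in zip(mcu_trials, prog_trials):
        mb = mcu["boundaries"]
        pb = prog
        n = min(len(mb), len(pb))
        for i in range(n - 1):
            if mb[i][0] != pb[i][0] or mb[i + 1][0] != pb[i + 1][0]:
                continue
            d_mcu = mb[i + 1][1] - mb[i][1]
            d_prog = pb[i + 1][1] - pb[i][1]
            diffs.append(abs(d_mcu - d_prog) * 1e3)
    if not diffs:
        return (0.0, 0.0)
    return (float(np.mean(diffs)), float(np.max(diffs)))


# ---------------------------------------------------------------------------
# trial assembly
# ---------------------------------------------------------------------------

_FLAG_BY_CODE = {
    "LICK_L": "is_lick_left",
    "LICK_R": "is_lick_right",
    "VALVE_L": "is_reward_triggered",
    "VALVE_R": "is_reward_triggered",
    "VALVE": "is_reward_triggered",
    "MANUAL_OPEN": "is_manual_open",
}


def _event_flag(ev: McuLogLine, spec: AlignmentSpec) -> str | None:
    if ev.event_code in _FLAG_BY_CODE:
        return _FLAG_BY_CODE[ev.event_code]
    if ev.event_code == "STATE":
        if ev.arg == f"{spec.anchor_epoch}_start":
            return "is_epoch_start"
        if ev.arg == "reward_zone":
            return "is_reward_zone_entry"
        if ev.arg == "trial_end":
            return "is_epoch_end"
    return None


def _mcu_trials(events: list[McuLogLine], spec: AlignmentSpec) -> list[dict]:
    trials: list[dict] = []
    cur: dict | None = None
    start_args = {f"{name}_start": name for name in spec.epoch_names}
    for ev in events:
        if ev.event_code == "STATE" and ev.arg == f"{spec.first_epoch}_start":
            cur = {"events": [], "boundaries": []}
            trials.append(cur)
        if cur is None:
            continue
        cur["events"].append(ev)
        t_s = ev.device_time / 1e3
        if ev.event_code == "STATE" and ev.arg in start_args:
            cur["boundaries"].append((start_args[ev.arg], t_s))
        elif ev.event_code == "STATE" and ev.arg == "trial_end":
            cur["boundaries"].append(("trial_end", t_s))
            cur = None
    return trials


def _program_trials(program_epochs: list[tuple[int, str, float]]) -> list[list[tuple[str, float]]]:
    by_trial: dict[int, list[tuple[str, float]]] = {}
    for trial_id, name, t in program_epochs:
        by_trial.setdefault(trial_id, []).append((name, t))
    return [by_trial[k] for k in sorted(by_trial)]


def align_trial(
    trial_id: int,
    trial_type: str,
    mcu_events: list[McuLogLine],
    spec: AlignmentSpec,
    encoder_rows: np.ndarray | None = None,
    anchor_prog_s: float | None = None,
    frame_rows: np.ndarray | None = None,
    radii_by_frame: np.ndarray | None = None,
) -> TrialRecord:
    """Assemble one trial record from the two clock domains.

    ``mcu_events`` are this trial's MCU log lines; ``encoder_rows`` and
    ``frame_rows`` are program-clock samples inside the trial window
    (absolute program time; ``anchor_prog_s`` is subtracted here).
    Raises if the anchor onset is missing.
    """
    anchor_mcu = None
    for ev in mcu_events:
        if ev.event_code == "STATE" and ev.arg == f"{spec.anchor_epoch}_start":
            anchor_mcu = ev.device_time / 1e3
            break
    if anchor_mcu is None:
        raise ValueError(f"trial {trial_id}: anchor epoch {spec.anchor_epoch!r} onset missing")

    rec = TrialRecord(trial_id=trial_id, trial_type=trial_type)
    for ev in mcu_events:
        flag = _event_flag(ev, spec)
        if flag is None:
            continue
        rec.timestamps.append(ev.device_time / 1e3 - anchor_mcu)
        for name in (
            "is_lick_left",
            "is_lick_right",
            "is_epoch_start",
            "is_reward_zone_entry",
            "is_reward_triggered",
            "is_epoch_end",
            "is_manual_open",
        ):
            getattr(rec, name).append(name == flag)

    if encoder_rows is not None and len(encoder_rows) and anchor_prog_s is not None:
        enc = np.asarray(encoder_rows, dtype=float).copy()
        enc[:, 0] -= anchor_prog_s
        enc[:, 1] -= spec.approach_offset_cm
        rec.encoder_combined = enc.tolist()
        rec.velocity = compute_velocity(enc).tolist()
    if frame_rows is not None and len(frame_rows) and anchor_prog_s is not None:
        trig = np.asarray(frame_rows, dtype=float).copy()
        trig[:, 0] -= anchor_prog_s
        fc, pc = merge_frames(trig, radii_by_frame if radii_by_frame is not None else np.array([]))
        rec.frame_combined = fc.tolist()
        rec.pupil_radius_combined = pc.tolist()
    return rec


def build_session(
    raw: RawSession, session_id: str | None = None, radii_by_frame: np.ndarray | None = None
) -> tuple[SessionRecord, list[int]]:
    """Align a simulated (or replayed) session into a SessionRecord.

    Returns the session plus the list of excluded trial ids (missing
    anchor).  ``radii_by_frame`` defaults to the generator's true pupil
    radii; a pupillometry pass can supply measured radii instead.
    """
    spec = spec_for_config(raw.config)
    mcu_trials = _mcu_trials(raw.mcu_events, spec)
    prog_trials = _program_trials(raw.program_epochs)
    radii = radii_by_frame if radii_by_frame is not None else raw.pupil_radii
    outcome_by_id = {o.trial_id: o for o in raw.outcomes}
    type_by_id = {t["trial_id"]: t["type"] for t in raw.truth["trials"]}

    trials: list[TrialRecord] = []
    excluded: list[int] = []
    for i, mcu in enumerate(mcu_trials):
        trial_id = i + 1
        prog = prog_trials[i] if i < len(prog_trials) else []
        anchor_prog = next((t for name, t in prog if name == spec.anchor_epoch), None)
        has_anchor = any(
            ev.event_code == "STATE" and ev.arg == f"{spec.anchor_epoch}_start" for ev in mcu["events"]
        )
        if not has_anchor or anchor_prog is None:
            excluded.append(trial_id)
            continue
        t0 = prog[0][1]
        t1 = prog[-1][1] if prog[-1][0] == "trial_end" else np.inf
        enc = raw.encoder
        enc_rows = enc[(enc[:, 0] >= t0) & (enc[:, 0] < t1)] if enc.size else None
        frames = raw.frames
        frame_rows = frames[(frames[:, 0] >= t0) & (frames[:, 0] < t1)] if frames.size else None
        rec = align_trial(
            trial_id,
            type_by_id.get(trial_id, ""),
            mcu["events"],
            spec,
            encoder_rows=enc_rows,
            anchor_prog_s=anchor_prog,
            frame_rows=frame_rows,
            radii_by_frame=radii,
        )
        outcome = outcome_by_id.get(trial_id)
        rec.outcome = outcome.label if outcome is not None else None
        trials.append(rec)

    # excluded trials break the dense-id invariant; renumber the survivors
    for new_id, rec in enumerate(trials, start=1):
        rec.trial_id = new_id

    session = SessionRecord(
        session_id=session_id or f"sim-{raw.seed}",
        config=asdict(raw.config),
        trials=trials,
        parameter_log=list(raw.state.param_log),
        end_reason=raw.end_reason,
        reward_count=raw.rewards,
        reward_volume_ul=raw.config.drop_volume_ul,
        total_volume_ul=raw.volume_ul,
    )
    return session, excluded
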