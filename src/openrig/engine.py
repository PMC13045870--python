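"""Event-driven finite-state task engine.

A session is a sequence of trials; a trial is an ordered sequence of
epochs.  Epoch transitions are triggered by accumulated locomotion
distance (closed-loop corridor tasks), elapsed time, or sensor events
(trial self-initiation).  The engine consumes :class:`RigEvent` streams
(licks, encoder distance deltas, timer ticks, manual commands) and emits
action tuples — valve openings, epoch entries, trial/session ends — that
a rig (real or simulated) executes and logs.

Supported task kinds:

``two_choice_closed_loop``
    Head-fixed corridor task: a 50 cm approach epoch then a 50 cm
    stimulus (grating) epoch.  A vertical grating rewards left licks,
    an angled grating rewards right licks.  The reward zone opens a
    short distance into the stimulus epoch (8.33 cm) and, on trials
    without a correct lick, a reward is delivered automatically from
    the port matching the stimulus shortly before the epoch ends
    (41.67 cm) when auto-water is enabled.
``hf_shaping``
    Head-fixed acclimation: 20 cm of travel gates a 6 s black/white
    stimulus window during which either lick-port delivers water; an
    optional automatic release fires 2 s after the stimulus change.  A
    side-bias deterrent rule locks a port after 3-8 consecutively
    rewarded same-side trials (threshold redrawn every trial).
``fm_shaping_1`` / ``fm_shaping_2``
    Freely moving shaping: stimulus onset after a random delay
    (stage 1) or after the subject touches the trial-initiation sensor
    (stage 2); any lick is rewarded and the trial ends 0.5 s later.
``gonogo_freely_moving``
    Freely moving luminance discrimination: self-initiated 4 s stimulus
    epoch; on Go trials a lick at least 0.5 s after stimulus onset is
    rewarded, on No-go trials licks are never rewarded.

Parameter updates queue during a trial and take effect at the next trial
boundary; manual valve commands act immediately.

``advance`` mutates the passed state in place and returns it together
with the emitted actions; the transition is fully determined by
(config, schedule, event sequence, engine seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .records import ParameterChange

TASK_KINDS = (
    "two_choice_closed_loop",
    "hf_shaping",
    "fm_shaping_1",
    "fm_shaping_2",
    "gonogo_freely_moving",
)

#: Parameters that may be changed online (applied at trial boundaries).
ADJUSTABLE_PARAMS = ("auto_water", "x_left", "x_right", "autoclicker", "side_bias_rule")

MIN_ITI_S = 0.05  # GUI update floor


class EngineError(RuntimeError):
    pass


@dataclass
class EpochSpec:
    """One subsection of a trial with its own transition rule."""

    name: str
    trigger: str  # "distance" | "timer" | "event" | "response"
    length_cm: float | None = None
    duration_s: float | None = None
    duration_range_s: tuple[float, float] | None = None  # timer drawn per trial
    sensor: str | None = None  # for "event": e.g. "init_touch"
    timeout_s: float | None = None  # for "response"
    post_reward_s: float = 0.5  # "response": epoch ends this long after reward
    decision: bool = False  # licks in this epoch are scored / rewardable
    stimulus: str | None = None  # metadata tag

    def __post_init__(self) -> None:
        if self.trigger == "distance" and (self.length_cm is None or self.length_cm <= 0):
            raise ValueError(f"epoch {self.name}: distance trigger requires length_cm > 0")
        if self.trigger == "timer" and self.duration_range_s is None and (
            self.duration_s is None or self.duration_s <= 0
        ):
            raise ValueError(f"epoch {self.name}: timer trigger requires duration_s > 0")
        if self.trigger == "event" and not self.sensor:
            raise ValueError(f"epoch {self.name}: event trigger requires a sensor")


@dataclass
class TaskConfig:
    """Declarative task description (epochs, schedule, contingencies, limits)."""

    task_kind: str
    epochs: list[EpochSpec]
    trial_types: list[str]
    type_probs: dict[str, float]
    contingency: dict[str, str | None]  # trial type -> reward port or None
    max_consecutive: int = 3
    n_trials: int = 1000
    drop_volume_ul: float = 6.0
    iti_s: float = 2.0
    response_delay_s: float = 0.0
    max_rewards: int = 125
    max_duration_min: float = 90.0
    reward_zone_open_cm: float | None = None  # defaults to length/6 of decision epoch
    auto_delivery_cm: float | None = None  # defaults to 5*length/6
    auto_release_after_s: float = 2.0  # shaping auto release after stimulus change
    auto_water: bool = False
    x_left: bool = False
    x_right: bool = False
    autoclicker: bool = False
    side_bias_rule: bool = False
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.task_kind!r}")
        if self.iti_s < MIN_ITI_S:
            raise ValueError(f"iti_s must be >= {MIN_ITI_S} s")
        if self.drop_volume_ul <= 0:
            raise ValueError("drop_volume_ul must be > 0")
        ep = self.decision_epoch()
        if ep is not None and ep.trigger == "distance":
            length = ep.length_cm
            if self.reward_zone_open_cm is None:
                self.reward_zone_open_cm = length / 6.0
            if self.auto_delivery_cm is None:
                self.auto_delivery_cm = 5.0 * length / 6.0
            if not (0 < self.reward_zone_open_cm < self.auto_delivery_cm < length):
                raise ValueError("require 0 < reward_zone_open < auto_delivery < epoch length")

    def decision_epoch(self) -> EpochSpec | None:
        for ep in self.epochs:
            if ep.decision:
                return ep
        return None


@dataclass
class RigEvent:
    """A timestamped input to the engine (program clock, seconds)."""

    kind: str  # lick_left | lick_right | init_touch | distance_delta | timer_tick | manual_open | param_update
    time: float
    delta: float = 0.0
    dt: float = 0.0
    name: str = ""
    value: Any = None


@dataclass
class Lick:
    time: float
    side: str  # "left" | "right" | "center"
    epoch: str
    t_in_epoch: float
    position_cm: float | None = None


@dataclass
class TrialOutcome:
    trial_id: int
    trial_type: str
    label: str
    licks: list[Lick]
    rewarded_drops: int = 0
    auto_delivered: bool = False
    manual_drops: int = 0


@dataclass
class EngineState:
    schedule: list[str]
    rng: np.random.Generator
    started: bool = False
    ended: bool = False
    end_reason: str | None = None
    session_time: float = 0.0
    trial_index: int = -1  # 0-based; -1 before first trial
    phase: str = "idle"  # "idle" | "epoch" | "iti"
    epoch_index: int = 0
    epoch_onset: float = 0.0
    epoch_distance: float = 0.0
    epoch_duration: float | None = None  # drawn duration for ranged timer epochs
    iti_until: float = 0.0
    licks: list[Lick] = field(default_factory=list)
    rewarded_this_trial: bool = False  # subject-triggered correct reward
    any_reward_this_trial: bool = False
    auto_done: bool = False
    auto_passed: bool = False  # auto-delivery distance already crossed
    rz_entered: bool = False
    response_reward_time: float | None = None
    subject_rewarded_side: str | None = None
    trial_drops: int = 0
    trial_manual_drops: int = 0
    rewards: int = 0  # total drops dispensed
    volume_ul: float = 0.0
    # side-bias deterrent
    consec_side: str | None = None
    consec_count: int = 0
    locked_side: str | None = None
    pending_auto_side: str | None = None
    current_threshold: int = 8
    pending_updates: dict[str, Any] = field(default_factory=dict)
    param_log: list[ParameterChange] = field(default_factory=list)
    outcomes: list[TrialOutcome] = field(default_factory=list)

    @property
    def trial_type(self) -> str:
        return self.schedule[self.trial_index]


def _other(side: str) -> str:
    return {"left": "right", "right": "left"}[side]


def init_engine(config: TaskConfig, seed: int, schedule: list[str] | None = None) -> EngineState:
    """Create an engine state with a session-start schedule.

    All engine randomness (schedule, deterrent thresholds, random valve
    sides, ranged epoch durations) derives from ``seed``.
    """
    from .scheduler import ScheduleSpec, generate_schedule

    if schedule is None:
        spec = ScheduleSpec(
            n_trials=config.n_trials,
            type_probs=config.type_probs,
            max_consecutive=config.max_consecutive,
            seed=seed,
        )
        schedule = generate_schedule(spec)
    return EngineState(schedule=schedule, rng=np.random.default_rng([seed, 1]))


def start_session(state: EngineState, config: TaskConfig, t: float = 0.0) -> list[tuple]:
    """Begin the session at time ``t``; returns the first epoch-entry action."""
    if state.started:
        raise EngineError("session already started")
    state.started = True
    actions: list[tuple] = [("log", "session_start")]
    _begin_trial(state, config, t, actions)
    return actions


# ---------------------------------------------------------------------------
# internal transitions
# ---------------------------------------------------------------------------

def _begin_trial(state: EngineState, config: TaskConfig, t: float, actions: list[tuple]) -> None:
    _apply_pending(state, config)
    state.trial_index += 1
    if state.trial_index >= len(state.schedule):
        raise EngineError("schedule exhausted; increase n_trials")
    state.phase = "epoch"
    state.epoch_index = 0
    state.licks = []
    state.rewarded_this_trial = False
    state.any_reward_this_trial = False
    state.auto_done = False
    state.auto_passed = False
    state.rz_entered = False
    state.response_reward_time = None
    state.subject_rewarded_side = None
    state.trial_drops = 0
    state.trial_manual_drops = 0
    # deterrent threshold is redrawn every trial, uniform on {3..8}
    state.current_threshold = int(state.rng.integers(3, 9))
    _enter_epoch(state, config, t, actions)


def _enter_epoch(state: EngineState, config: TaskConfig, t: float, actions: list[tuple]) -> None:
    ep = config.epochs[state.epoch_index]
    state.epoch_onset = t
    state.epoch_distance = 0.0
    state.epoch_duration = None
    if ep.trigger == "timer":
        if ep.duration_range_s is not None:
            lo, hi = ep.duration_range_s
            state.epoch_duration = float(state.rng.uniform(lo, hi))
        else:
            state.epoch_duration = ep.duration_s
    actions.append(("enter_epoch", ep.name, state.trial_index, state.trial_type))


def _complete_epoch(state: EngineState, config: TaskConfig, t: float, actions: list[tuple]) -> None:
    state.epoch_index += 1
    if state.epoch_index < len(config.epochs):
        _enter_epoch(state, config, t, actions)
    else:
        _end_trial(state, config, t, actions)


def _end_trial(state: EngineState, config: TaskConfig, t: float, actions: list[tuple]) -> None:
    label = score_trial(config, state.trial_type, state.licks)
    state.outcomes.append(
        TrialOutcome(
            trial_id=state.trial_index + 1,
            trial_type=state.trial_type,
            label=label,
            licks=list(state.licks),
            rewarded_drops=state.trial_drops,
            auto_delivered=state.auto_done,
            manual_drops=state.trial_manual_drops,
        )
    )
    actions.append(("end_trial", state.trial_index, label))
    if config.side_bias_rule:
        _update_deterrent(state)
    state.phase = "iti"
    state.iti_until = t + config.iti_s


def _update_deterrent(state: EngineState) -> None:
    """Consecutive-same-side accounting for the shaping side-bias rule.

    Counts trials whose reward was triggered by the subject itself; the
    lock threshold is the per-trial draw from {3..8}.  A locked side is
    released only after a trial in which the subject triggered the other
    port.
    """
    side = state.subject_rewarded_side
    if side is None:
        return
    if state.locked_side is not None:
        if side == _other(state.locked_side):
            state.locked_side = None
            state.pending_auto_side = None
            state.consec_side = side
            state.consec_count = 1
        return
    if side == state.consec_side:
        state.consec_count += 1
    else:
        state.consec_side = side
        state.consec_count = 1
    if state.consec_count >= state.current_threshold:
        state.locked_side = side
        state.pending_auto_side = _other(side)
        state.consec_side = None
        state.consec_count = 0


def side_bias_deterrent(state: EngineState) -> dict[str, Any]:
    """Current deterrent lock decision (inspection helper)."""
    return {
        "locked_side": state.locked_side,
        "pending_auto_side": state.pending_auto_side,
        "consecutive_side": state.consec_side,
        "consecutive_count": state.consec_count,
        "threshold": state.current_threshold,
    }


def _apply_pending(state: EngineState, config: TaskConfig) -> None:
    for name, value in state.pending_updates.items():
        old = getattr(config, name)
        setattr(config, name, value)
        state.param_log.append(ParameterChange(state.trial_index + 1, name, old, value))
    state.pending_updates.clear()


def _dispense(
    state: EngineState,
    config: TaskConfig,
    actions: list[tuple],
    side: str,
    drops: int,
    kind: str,
    t: float,
) -> None:
    actions.append(("open_valve", side, drops, kind))
    state.rewards += drops
    state.volume_ul += drops * config.drop_volume_ul
    state.any_reward_this_trial = True
    if kind == "auto":
        state.auto_done = True
    if kind == "manual":
        state.trial_manual_drops += drops
    else:
        state.trial_drops += drops
    if state.rewards >= config.max_rewards:
        _end_session(state, config, t, actions, "max_rewards")


def _end_session(
    state: EngineState, config: TaskConfig, t: float, actions: list[tuple], reason: str
) -> None:
    if state.phase == "epoch":
        # score the in-progress trial before closing out
        label = score_trial(config, state.trial_type, state.licks)
        state.outcomes.append(
            TrialOutcome(
                trial_id=state.trial_index + 1,
                trial_type=state.trial_type,
                label=label,
                licks=list(state.licks),
                rewarded_drops=state.trial_drops,
                auto_delivered=state.auto_done,
                manual_drops=state.trial_manual_drops,
            )
        )
        actions.append(("end_trial", state.trial_index, label))
    state.ended = True
    state.end_reason = reason
    state.phase = "idle"
    actions.append(("end_session", reason))


def auto_delivery_check(state: EngineState, config: TaskConfig) -> tuple | None:
    """Pending corridor auto-delivery action, if its conditions hold.

    Fires at most once per trial, at the first distance sample at or
    beyond the auto-delivery threshold, only when no correct rewarded
    lick has occurred earlier in the trial, from the port associated
    with the presented stimulus.
    """
    if not config.auto_water or state.auto_passed:
        return None
    if state.rewarded_this_trial or state.auto_done:
        return None
    side = config.contingency[state.trial_type]
    if side is None:
        return None
    return ("open_valve", side, 1, "auto")


# ---------------------------------------------------------------------------
# event handling
# ---------------------------------------------------------------------------

def advance(state: EngineState, config: TaskConfig, event: RigEvent) -> tuple[EngineState, list[tuple]]:
    """Feed one event to the engine; returns ``(state, actions)``.

    The state object is updated in place; the transition is
    deterministic given (config, schedule, event sequence, seed).
    """
    if not state.started:
        raise EngineError("event before session start")
    actions: list[tuple] = []
    if state.ended:
        return state, actions
    t = event.time
    state.session_time = t
    _time_checks(state, config, t, actions)
    if state.ended:
        return state, actions

    kind = event.kind
    if kind == "timer_tick":
        pass
    elif kind == "distance_delta":
        _handle_distance(state, config, event.delta, t, actions)
    elif kind in ("lick_left", "lick_right", "lick_center"):
        side = {"lick_left": "left", "lick_right": "right", "lick_center": "center"}[kind]
        _handle_lick(state, config, side, t, actions)
    elif kind == "init_touch":
        _handle_init_touch(state, config, t, actions)
    elif kind == "manual_open":
        _manual_open(state, config, event.name or "", t, actions)
    elif kind == "param_update":
        _handle_param_update(state, config, event.name, event.value, t, actions)
    else:
        raise EngineError(f"unknown event kind {kind!r}")
    return state, actions


def _time_checks(state: EngineState, config: TaskConfig, t: float, actions: list[tuple]) -> None:
    if t >= config.max_duration_min * 60.0:
        _end_session(state, config, t, actions, "max_duration")
        return
    if state.phase == "iti":
        if t >= state.iti_until:
            _begin_trial(state, config, t, actions)
        return
    if state.phase != "epoch":
        return
    ep = config.epochs[state.epoch_index]
    if ep.decision and config.task_kind == "hf_shaping":
        # automatic release 2 s after stimulus change (first-session help or
        # deterrent-scheduled release from the non-locked side)
        if (
            (config.auto_water or state.pending_auto_side is not None)
            and not state.any_reward_this_trial
            and not state.auto_done
            and t - state.epoch_onset >= config.auto_release_after_s
        ):
            if state.pending_auto_side is not None:
                side = state.pending_auto_side
                state.pending_auto_side = None
            else:
                side = "left" if state.rng.random() < 0.5 else "right"
            _dispense(state, config, actions, side, 1, "auto", t)
            if state.ended:
                return
    if ep.trigger == "timer" and t - state.epoch_onset >= state.epoch_duration:
        _complete_epoch(state, config, t, actions)
    elif ep.trigger == "response":
        if state.response_reward_time is not None and t >= state.response_reward_time + ep.post_reward_s:
            _complete_epoch(state, config, t, actions)
        elif ep.timeout_s is not None and t - state.epoch_onset >= ep.timeout_s:
            _complete_epoch(state, config, t, actions)


def _handle_distance(
    state: EngineState, config: TaskConfig, delta: float, t: float, actions: list[tuple]
) -> None:
    if not np.isfinite(delta):
        raise EngineError("distance_delta must be finite")
    if state.phase != "epoch":
        return
    ep = config.epochs[state.epoch_index]
    if ep.trigger != "distance":
        return
    state.epoch_distance = max(0.0, state.epoch_distance + delta)
    if ep.decision and config.task_kind == "two_choice_closed_loop":
        if not state.rz_entered and state.epoch_distance >= config.reward_zone_open_cm:
            state.rz_entered = True
            actions.append(("reward_zone_entry", state.trial_index))
        if not state.auto_passed and state.epoch_distance >= config.auto_delivery_cm:
            action = auto_delivery_check(state, config)
            state.auto_passed = True
            if action is not None:
                _dispense(state, config, actions, action[1], action[2], "auto", t)
                if state.ended:
                    return
    if state.epoch_distance >= (ep.length_cm or np.inf):
        _complete_epoch(state, config, t, actions)


def _handle_lick(
    state: EngineState, config: TaskConfig, side: str, t: float, actions: list[tuple]
) -> None:
    if state.phase != "epoch":
        # ITI licks are logged by the rig but never scored or rewarded
        state.licks.append(Lick(t, side, "iti", 0.0, None))
        return
    ep = config.epochs[state.epoch_index]
    pos = state.epoch_distance if ep.trigger == "distance" else None
    lick = Lick(t, side, ep.name, t - state.epoch_onset, pos)
    state.licks.append(lick)
    if not ep.decision:
        return
    kind = config.task_kind
    if kind == "two_choice_closed_loop":
        required = config.contingency[state.trial_type]
        if (
            not state.rewarded_this_trial
            and not state.auto_done
            and side == required
            and state.locked_side != side
            and config.reward_zone_open_cm <= pos < config.auto_delivery_cm
        ):
            boost = (side == "left" and config.x_left) or (side == "right" and config.x_right)
            drops = 3 if boost else 1
            state.rewarded_this_trial = True
            state.subject_rewarded_side = side
            _dispense(state, config, actions, side, drops, "earned", t)
    elif kind == "hf_shaping":
        if side in ("left", "right") and not state.any_reward_this_trial and state.locked_side != side:
            state.rewarded_this_trial = True
            state.subject_rewarded_side = side
            _dispense(state, config, actions, side, 1, "earned", t)
    elif kind == "gonogo_freely_moving":
        if (
            state.trial_type in config.contingency
            and config.contingency[state.trial_type] is not None
            and not state.rewarded_this_trial
            and lick.t_in_epoch >= config.response_delay_s
        ):
            state.rewarded_this_trial = True
            _dispense(state, config, actions, config.contingency[state.trial_type], 1, "earned", t)
    elif kind in ("fm_shaping_1", "fm_shaping_2"):
        if not state.rewarded_this_trial:
            state.rewarded_this_trial = True
            state.response_reward_time = t
            _dispense(state, config, actions, config.contingency[state.trial_type] or "center", 1, "earned", t)


def _handle_init_touch(state: EngineState, config: TaskConfig, t: float, actions: list[tuple]) -> None:
    if state.phase != "epoch":
        return
    ep = config.epochs[state.epoch_index]
    if ep.trigger == "event" and ep.sensor == "init_touch":
        _complete_epoch(state, config, t, actions)


def _manual_open(state: EngineState, config: TaskConfig, which: str, t: float, actions: list[tuple]) -> None:
    """Immediate manual valve command; logged as a manual dispense.

    ``which`` is "left", "right", or "" for the generic open-valve
    command, which releases from the stimulus-associated port inside the
    decision corridor and otherwise from a random port.
    """
    if which in ("left", "right"):
        side = which
    else:
        ep = config.epochs[state.epoch_index] if state.phase == "epoch" else None
        if ep is not None and ep.decision and config.contingency.get(state.trial_type):
            side = config.contingency[state.trial_type]
        elif len({v for v in config.contingency.values() if v}) == 1:
            side = next(v for v in config.contingency.values() if v)
        else:
            side = "left" if state.rng.random() < 0.5 else "right"
    _dispense(state, config, actions, side, 1, "manual", t)


def _handle_param_update(
    state: EngineState, config: TaskConfig, name: str, value: Any, t: float, actions: list[tuple]
) -> None:
    if name in ("open_valve", "open_valve_left", "open_valve_right"):
        which = name.removeprefix("open_valve").lstrip("_")
        _manual_open(state, config, which, t, actions)
        return
    if name == "end_session":
        _end_session(state, config, t, actions, "manual")
        return
    if name not in ADJUSTABLE_PARAMS:
        raise EngineError(f"parameter {name!r} is not adjustable")
    state.pending_updates[name] = value  # applied at the next trial boundary


def apply_parameter_update(state: EngineState, config: TaskConfig, name: str, value: Any) -> EngineState:
    """Queue a parameter update (or act immediately for valve commands)."""
    _handle_param_update(state, config, name, value, state.session_time, [])
    return state


def session_end_check(state: EngineState, config: TaskConfig) -> tuple | None:
    """Explicit end-of-session test (rewards and elapsed-time rules)."""
    if state.rewards >= config.max_rewards:
        return ("end_session", "max_rewards")
    if state.session_time >= config.max_duration_min * 60.0:
        return ("end_session", "max_duration")
    return None


def run_shaping_hf(state: EngineState, config: TaskConfig, event: RigEvent) -> tuple[EngineState, list[tuple]]:
    """Head-fixed acclimation transitions (thin wrapper over ``advance``)."""
    if config.task_kind != "hf_shaping":
        raise EngineError("run_shaping_hf requires an hf_shaping config")
    return advance(state, config, event)


# ---------------------------------------------------------------------------
# trial scoring
# ---------------------------------------------------------------------------

def score_trial(config: TaskConfig, trial_type: str, licks: list[Lick]) -> str:
    """Score one trial from its lick history.

    Two-choice: the decision is the side of the *first* lick whose
    position lies inside the reward zone of the decision epoch; later
    licks do not change the outcome.  Labels are ``hit_<type>`` /
    ``fa_<type>`` / ``no_interaction``.  Go/No-go: any lick during the
    decision epoch counts, giving hit / miss / false_alarm /
    correct_reject.  Shaping tasks score interaction / no_interaction.
    """
    ep = config.decision_epoch()
    if ep is None:
        return "no_interaction"
    in_epoch = [l for l in licks if l.epoch == ep.name]
    if config.task_kind == "two_choice_closed_loop":
        zone = [
            l
            for l in in_epoch
            if l.position_cm is not None
            and config.reward_zone_open_cm <= l.position_cm < config.auto_delivery_cm
        ]
        if not zone:
            return "no_interaction"
        first = min(zone, key=lambda l: l.time)
        correct = config.contingency[trial_type]
        return f"hit_{trial_type}" if first.side == correct else f"fa_{trial_type}"
    if config.task_kind == "gonogo_freely_moving":
        licked = bool(in_epoch)
        go = config.contingency.get(trial_type) is not None
        if go:
            return "hit" if licked else "miss"
        return "false_alarm" if licked else "correct_reject"
    return "interaction" if in_epoch else "no_interaction"
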