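"""Simulated rig: device clocks, sensor streams, eye frames, and a virtual mouse.

Everything downstream of the hardware — the task engine, the two-clock
synchronization layer, the performance analysis, the pupillometry
pipeline — is exercised against this module instead of a physical rig.

The virtual mouse is an equal-variance signal-detection agent: on each
decision it draws evidence from ``Normal(+d_true/2, 1)`` for the
positive stimulus class (vertical grating / Go / white) and
``Normal(-d_true/2, 1)`` otherwise, and responds "left" when the
evidence exceeds its criterion ``c_true`` (positive criterion = right
bias under the left-lick-positive convention).  Because the generative
model matches the analysis model, the analysis module's d′ and
side-bias estimates have known targets (``d_true``, ``-c_true``).

Two device clocks mirror the platform's split: lick/valve/state events
are stamped on the MCU clock, external-device samples (wheel encoder at
300 Hz, eye-camera triggers at 10 Hz) on the program clock.  Each clock
has configurable offset, drift, Gaussian jitter, and a quantization
grid.  All randomness flows from one session seed through named
sub-streams (schedule, agent, clocks, frames), so each component is
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .engine import (
    EngineState,
    RigEvent,
    TaskConfig,
    TrialOutcome,
    advance,
    init_engine,
    start_session,
)
from .records import McuLogLine

ENCODER_HZ = 300.0
FRAME_HZ = 10.0

POSITIVE_TYPES = {"vertical", "go", "white"}


# ---------------------------------------------------------------------------
# clocks
# ---------------------------------------------------------------------------

@dataclass
class ClockSpec:
    """A device clock: offset, linear drift, jitter, quantization grid."""

    offset_s: float = 0.0
    drift_ppm: float = 0.0
    jitter_sd_ms: float = 0.0
    period_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.period_ms <= 0:
            raise ValueError("period_ms must be > 0")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter_sd_ms must be >= 0")


@dataclass
class RigClocks:
    mcu: ClockSpec = field(default_factory=lambda: ClockSpec(jitter_sd_ms=0.2, drift_ppm=20.0, period_ms=1.0))
    program: ClockSpec = field(default_factory=lambda: ClockSpec(jitter_sd_ms=0.1, period_ms=0.1))


def clock_read(clock: ClockSpec, t_true: float, rng: np.random.Generator | None = None) -> float:
    """Device reading (seconds) of a true time: offset, drift, jitter, grid."""
    t = (t_true + clock.offset_s) * (1.0 + clock.drift_ppm * 1e-6)
    if clock.jitter_sd_ms > 0 and rng is not None:
        t += rng.normal(0.0, clock.jitter_sd_ms) * 1e-3
    period = clock.period_ms * 1e-3
    return round(t / period) * period


def clock_read_array(
    clock: ClockSpec, t_true: np.ndarray, rng: np.random.Generator | None = None
) -> np.ndarray:
    t = (np.asarray(t_true, dtype=float) + clock.offset_s) * (1.0 + clock.drift_ppm * 1e-6)
    if clock.jitter_sd_ms > 0 and rng is not None:
        t = t + rng.normal(0.0, clock.jitter_sd_ms, size=t.shape) * 1e-3
    period = clock.period_ms * 1e-3
    return np.round(t / period) * period


# ---------------------------------------------------------------------------
# agent
# ---------------------------------------------------------------------------

@dataclass
class AgentPolicy:
    """Generative virtual-mouse parameters.

    ``d_true`` and ``c_true`` are in z-units; ``lapse`` is the
    probability of a random-side guess; ``p_lick_approach`` /
    ``p_lick_decision`` are per-trial engagement probabilities; lick and
    locomotion dynamics shape the event streams but not the decisions.
    """

    d_true: float = 2.5
    c_true: float = 0.0
    lapse: float = 0.02
    p_lick_approach: float = 0.1
    p_lick_decision: float = 0.95
    lick_rate_hz: float = 6.0
    speed_mean_cm_s: float = 15.0
    speed_sd_cm_s: float = 5.0

    def __post_init__(self) -> None:
        for name in ("lapse", "p_lick_approach", "p_lick_decision"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lick_rate_hz < 0:
            raise ValueError("lick_rate_hz must be >= 0")
        if self.speed_mean_cm_s <= 0:
            raise ValueError("speed_mean_cm_s must be > 0")


def sample_choice(policy: AgentPolicy, trial_type: str, rng: np.random.Generator) -> str:
    """One signal-detection decision: "left", "right", or "none".

    For single-port (Go/No-go) paradigms callers map "left" to lick and
    "right" to withhold, which preserves the hit/false-alarm algebra.
    Trial type "neutral" draws evidence with zero mean (used in shaping,
    where the stimulus is non-discriminative).
    """
    if rng.random() >= policy.p_lick_decision:
        return "none"
    if policy.lapse > 0 and rng.random() < policy.lapse:
        return "left" if rng.random() < 0.5 else "right"
    if trial_type == "neutral":
        mu = 0.0
    else:
        mu = policy.d_true / 2.0 if trial_type in POSITIVE_TYPES else -policy.d_true / 2.0
    evidence = rng.normal(mu, 1.0)
    return "left" if evidence > policy.c_true else "right"


# ---------------------------------------------------------------------------
# full-session simulation
# ---------------------------------------------------------------------------

@dataclass
class RawSession:
    """Raw acquisition products of one simulated session.

    ``mcu_events`` is the MCU #1 log (device milliseconds).  ``encoder``
    (program-clock seconds, corridor cm within trial) and ``frames``
    (program-clock seconds, global frame number) are external-device
    streams.  ``program_epochs`` are the program-clock epoch boundaries
    ``(trial_id, name, t)``; MCU-clock boundaries live in the STATE
    lines of the log.  ``truth`` holds generator-side ground truth for
    oracle tests.
    """

    config: TaskConfig
    seed: int
    clocks: RigClocks
    mcu_events: list[McuLogLine]
    encoder: np.ndarray
    frames: np.ndarray
    pupil_radii: np.ndarray
    program_epochs: list[tuple[int, str, float]]
    outcomes: list[TrialOutcome]
    truth: dict[str, Any]
    end_reason: str
    rewards: int
    volume_ul: float
    state: EngineState


def _true_outcome(config: TaskConfig, trial_type: str, response: str | None) -> str:
    """Oracle outcome implied by the agent's planned response (engine-free)."""
    if config.task_kind == "two_choice_closed_loop":
        if response in (None, "none"):
            return "no_interaction"
        correct = config.contingency[trial_type]
        return f"hit_{trial_type}" if response == correct else f"fa_{trial_type}"
    if config.task_kind == "gonogo_freely_moving":
        licked = response == "left"
        if config.contingency.get(trial_type) is not None:
            return "hit" if licked else "miss"
        return "false_alarm" if licked else "correct_reject"
    return "interaction" if response not in (None, "none") else "no_interaction"


def run_session(
    config: TaskConfig,
    policy: AgentPolicy,
    clocks: RigClocks | None = None,
    seed: int = 0,
    updates: list[tuple[float, str, Any]] | None = None,
) -> RawSession:
    """Simulate one full closed-loop session end to end.

    ``updates`` optionally injects user parameter commands as
    ``(true_time_s, name, value)`` triples.  Deterministic given
    ``seed``: the same seed yields byte-identical logs.
    """
    import copy

    config = copy.deepcopy(config)  # the engine may mutate adjustable params
    clocks = clocks or RigClocks()
    rng_agent = np.random.default_rng([seed, 2])
    rng_clock = np.random.default_rng([seed, 3])
    rng_pupil = np.random.default_rng([seed, 4])
    rng_click = np.random.default_rng([seed, 5])

    state = init_engine(config, seed)
    head_fixed = config.task_kind in ("two_choice_closed_loop", "hf_shaping")
    dt = 1.0 / ENCODER_HZ

    mcu_events: list[McuLogLine] = []
    last_ms = [0]

    def mcu_line(code: str, arg: str, t: float) -> None:
        ms = int(round(clock_read(clocks.mcu, t, rng_clock) * 1e3))
        ms = max(ms, last_ms[0])  # a device counter never runs backwards
        last_ms[0] = ms
        mcu_events.append(McuLogLine(ms, code, arg))

    encoder_t: list[float] = []
    encoder_x: list[float] = []
    frame_rows: list[tuple[float, int]] = []
    pupil_radii: list[float] = []
    program_epochs: list[tuple[int, str, float]] = []
    truth_trials: list[dict[str, Any]] = []
    pending_licks: list[tuple[str, str, float, str]] = []  # (mode, epoch, threshold, side)
    pending_init: list[float] = []

    valve_code = {"left": "VALVE_L", "right": "VALVE_R", "center": "VALVE"}
    lick_code = {"left": "LICK_L", "right": "LICK_R", "center": "LICK_L"}

    # AR(1) pupil radius around a session mean (cosmetic arousal proxy)
    pupil_mu, pupil_phi, pupil_sd = 12.0, 0.95, 0.6
    pupil_r = pupil_mu

    def plan_epoch(name: str, trial_type: str, t: float) -> None:
        kind = config.task_kind
        if kind == "two_choice_closed_loop":
            if name == "approach":
                if rng_agent.random() < policy.p_lick_approach:
                    pos = rng_agent.uniform(0.0, config.epochs[0].length_cm)
                    side = "left" if rng_agent.random() < 0.5 else "right"
                    pending_licks.append(("distance", name, pos, side))
            elif name == "grating":
                resp = sample_choice(policy, trial_type, rng_agent)
                truth_trials[-1]["response"] = resp
                truth_trials[-1]["outcome_true"] = _true_outcome(config, trial_type, resp)
                if resp != "none":
                    # lick strictly inside the zone: a margin of several
                    # encoder ticks of travel avoids boundary races
                    width = config.auto_delivery_cm - config.reward_zone_open_cm
                    margin = min(0.5, width / 4.0)
                    pos = rng_agent.uniform(
                        config.reward_zone_open_cm + margin, config.auto_delivery_cm - margin
                    )
                    truth_trials[-1]["planned_lick_cm"] = pos
                    pending_licks.append(("distance", name, pos, resp))
        elif kind == "hf_shaping":
            if name == "stimulus":
                resp = sample_choice(policy, "neutral", rng_agent)
                truth_trials[-1]["response"] = resp
                truth_trials[-1]["outcome_true"] = _true_outcome(config, trial_type, resp)
                if resp != "none":
                    t_lick = t + rng_agent.uniform(0.3, 4.0)
                    pending_licks.append(("time", name, t_lick, resp))
        elif kind == "gonogo_freely_moving":
            if name == "prestim":
                pending_init.append(t + rng_agent.uniform(0.3, 2.0))
            elif name == "stimulus":
                resp = sample_choice(policy, trial_type, rng_agent)
                lick = resp == "left"
                truth_trials[-1]["response"] = resp
                truth_trials[-1]["outcome_true"] = _true_outcome(config, trial_type, resp)
                if lick:
                    t_lick = t + config.response_delay_s + rng_agent.uniform(0.05, 2.5)
                    pending_licks.append(("time", name, t_lick, "center"))
        else:  # freely moving shaping stages
            if name == "prestim" and config.epochs[0].trigger == "event":
                pending_init.append(t + rng_agent.uniform(0.3, 2.0))
            elif name == "stimulus":
                if rng_agent.random() < policy.p_lick_decision:
                    truth_trials[-1]["response"] = "center"
                    truth_trials[-1]["outcome_true"] = "interaction"
                    pending_licks.append(("time", name, t + rng_agent.uniform(0.2, 1.5), "center"))

    def handle_actions(actions: list[tuple], t: float) -> None:
        for act in actions:
            op = act[0]
            if op == "enter_epoch":
                _, name, trial_idx, trial_type = act
                if name == config.epochs[0].name:
                    truth_trials.append(
                        {
                            "trial_id": trial_idx + 1,
                            "type": trial_type,
                            "response": None,
                            "outcome_true": _true_outcome(config, trial_type, None),
                            "t_start_true": t,
                        }
                    )
                program_epochs.append((trial_idx + 1, name, clock_read(clocks.program, t, rng_clock)))
                mcu_line("STATE", f"{name}_start", t)
                plan_epoch(name, trial_type, t)
            elif op == "open_valve":
                _, side, drops, kind = act
                code = "MANUAL_OPEN" if kind == "manual" else valve_code[side]
                mcu_line(code, f"{side}:{drops}" if kind == "manual" else str(drops), t)
                truth_trials[-1].setdefault("rewards", []).append(
                    {"t_true": t, "side": side, "drops": drops, "kind": kind}
                )
            elif op == "reward_zone_entry":
                mcu_line("STATE", "reward_zone", t)
            elif op == "end_trial":
                trial_idx = act[1]
                program_epochs.append((trial_idx + 1, "trial_end", clock_read(clocks.program, t, rng_clock)))
                mcu_line("STATE", "trial_end", t)
                pending_licks.clear()
                pending_init.clear()
                truth_trials[-1]["outcome_engine"] = act[2]
            elif op == "end_session":
                mcu_line("STATE", "session_end", t)
            elif op == "log" and act[1] == "session_start":
                mcu_line("STATE", "session_start", t)

    t = 0.0
    handle_actions(start_session(state, config, t), t)
    next_frame = 0.0
    frame_no = 0
    next_click = rng_click.uniform(0.5, 3.0) if config.autoclicker else math.inf
    updates = sorted(updates or [])
    upd_i = 0
    hard_cap = config.max_duration_min * 60.0 + 120.0

    while not state.ended and t < hard_cap:
        t += dt
        # camera free-runs on the program clock (head-fixed rigs only)
        if head_fixed:
            while next_frame <= t + 1e-12:
                frame_rows.append((next_frame, frame_no))
                pupil_r = pupil_mu + pupil_phi * (pupil_r - pupil_mu) + rng_pupil.normal(0.0, pupil_sd)
                pupil_radii.append(pupil_r)
                frame_no += 1
                next_frame += 1.0 / FRAME_HZ
        # scripted user commands
        while upd_i < len(updates) and updates[upd_i][0] <= t:
            _, name, value = updates[upd_i]
            upd_i += 1
            _, acts = advance(state, config, RigEvent("param_update", t, name=name, value=value))
            handle_actions(acts, t)
        if state.ended:
            break
        # locomotion / timer tick
        if head_fixed:
            speed = max(0.0, rng_agent.normal(policy.speed_mean_cm_s, policy.speed_sd_cm_s))
            _, acts = advance(state, config, RigEvent("distance_delta", t, delta=speed * dt))
        else:
            _, acts = advance(state, config, RigEvent("timer_tick", t, dt=dt))
        handle_actions(acts, t)
        if state.ended:
            break
        # encoder sample (wheel position within the corridor, 1 cm = 1 cm)
        if head_fixed and state.phase == "epoch":
            ep = config.epochs[state.epoch_index]
            if ep.trigger == "distance":
                base = sum(e.length_cm or 0.0 for e in config.epochs[: state.epoch_index])
                encoder_t.append(t)
                encoder_x.append(base + state.epoch_distance)
        # planned trial initiation
        if pending_init and t >= pending_init[0]:
            pending_init.pop(0)
            _, acts = advance(state, config, RigEvent("init_touch", t))
            handle_actions(acts, t)
            if state.ended:
                break
        # planned licks
        fired = []
        for i, (mode, epoch, threshold, side) in enumerate(pending_licks):
            if mode == "distance":
                if (
                    state.phase == "epoch"
                    and config.epochs[state.epoch_index].name == epoch
                    and state.epoch_distance >= threshold
                ):
                    fired.append(i)
            elif t >= threshold:
                fired.append(i)
        for i in reversed(fired):
            mode, epoch, threshold, side = pending_licks.pop(i)
            kind = {"left": "lick_left", "right": "lick_right", "center": "lick_center"}[side]
            mcu_line(lick_code[side], "", t)
            _, acts = advance(state, config, RigEvent(kind, t))
            handle_actions(acts, t)
            # consummatory burst after a decision lick (recorded, never scored anew)
            if policy.lick_rate_hz > 0 and mode == "distance" and epoch != config.epochs[0].name:
                for k in range(1, 4):
                    pending_licks.append(("time", epoch, t + k / policy.lick_rate_hz, side))
            if state.ended:
                break
        # decoy relay clicks (log only)
        while config.autoclicker and t >= next_click:
            mcu_line("CLICK", "", next_click)
            next_click += rng_click.uniform(0.5, 3.0)

    if not state.ended:  # safety net; configured sessions end on their own
        _, acts = advance(state, config, RigEvent("param_update", t, name="end_session", value=True))
        handle_actions(acts, t)

    encoder = np.column_stack(
        [clock_read_array(clocks.program, np.array(encoder_t), rng_clock), np.array(encoder_x)]
    ) if encoder_t else np.empty((0, 2))
    if frame_rows:
        ft = clock_read_array(clocks.program, np.array([r[0] for r in frame_rows]), rng_clock)
        frames = np.column_stack([ft, np.array([r[1] for r in frame_rows], dtype=float)])
    else:
        frames = np.empty((0, 2))

    truth = {
        "seed": seed,
        "clocks": {"mcu": asdict(clocks.mcu), "program": asdict(clocks.program)},
        "closed_loop_gain_cm_per_cm": 1.0,
        "trials": truth_trials,
        "pupil": {"mean": pupil_mu, "phi": pupil_phi, "sd": pupil_sd},
    }
    return RawSession(
        config=config,
        seed=seed,
        clocks=clocks,
        mcu_events=mcu_events,
        encoder=encoder,
        frames=frames,
        pupil_radii=np.array(pupil_radii),
        program_epochs=program_epochs,
        outcomes=state.outcomes,
        truth=truth,
        end_reason=state.end_reason or "manual",
        rewards=state.rewards,
        volume_ul=state.volume_ul,
        state=state,
    )


# ---------------------------------------------------------------------------
# synthetic eye frames
# ---------------------------------------------------------------------------

@dataclass
class EyeFrameSpec:
    """Synthetic eye-camera frame model.

    Open frames are a dark pupil disk on a brighter iris background with
    additive Gaussian noise; occluded frames overlay an eyelid band that
    fully covers the pupil.
    """

    width: int = 64
    height: int = 64
    radius_mean_px: float = 12.0
    radius_sd_px: float = 2.0
    center_jitter_px: float = 3.0
    occlusion_prob: float = 0.2
    coverage_range: tuple[float, float] = (0.6, 0.95)
    noise_sd: float = 8.0
    pupil_intensity: float = 30.0
    iris_intensity: float = 150.0
    eyelid_intensity: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValueError("occlusion_prob must be in [0, 1]")
        if self.radius_mean_px + 3 * self.radius_sd_px > min(self.width, self.height) / 2:
            raise ValueError("pupil radii must fit inside the frame")


def generate_eye_frames(
    spec: EyeFrameSpec, n: int, seed: int = 0
) -> tuple[np.ndarray, list[dict[str, Any]]]:
    """Generate ``n`` grayscale frames (uint8) plus per-frame ground truth.

    Truth records carry ``label`` ("open"/"occluded"), the pupil center
    and radius (present for both classes; on occluded frames the pupil
    is drawn, then covered), and the eyelid coverage fraction.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((n, h, w), dtype=np.uint8)
    truth: list[dict[str, Any]] = []
    max_r = min(w, h) / 2 - 2
    for i in range(n):
        r = float(np.clip(rng.normal(spec.radius_mean_px, spec.radius_sd_px), 3.0, max_r))
        cx = w / 2 + float(rng.uniform(-spec.center_jitter_px, spec.center_jitter_px))
        cy = h / 2 + float(rng.uniform(-spec.center_jitter_px, spec.center_jitter_px))
        img = np.full((h, w), spec.iris_intensity, dtype=float)
        dist = np.hypot(xx - cx, yy - cy)
        # 1 px soft edge keeps the disk boundary band-limited
        img += (spec.pupil_intensity - spec.iris_intensity) * np.clip(r + 0.5 - dist, 0.0, 1.0)
        occluded = rng.random() < spec.occlusion_prob
        coverage = 0.0
        if occluded:
            coverage = float(rng.uniform(*spec.coverage_range))
            band_end = max(int(coverage * h), int(math.ceil(cy + r)) + 2)
            band_end = min(band_end, h)
            img[:band_end, :] = spec.eyelid_intensity
            coverage = band_end / h
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
        truth.append(
            {
                "frame": i,
                "label": "occluded" if occluded else "open",
                "cx": cx,
                "cy": cy,
                "radius": r,
                "coverage": coverage,
            }
        )
    return frames, truth
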