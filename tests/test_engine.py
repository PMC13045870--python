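"""Task-engine state transitions, contingencies, and shaping rules."""

import copy

import pytest

import openrig as org
from openrig.engine import (
    Lick,
    RigEvent,
    advance,
    init_engine,
    run_shaping_hf,
    score_trial,
    session_end_check,
    side_bias_deterrent,
    start_session,
)


def fresh(config_name, schedule, seed=0):
    cfg = copy.deepcopy(org.load_config(config_name))
    state = init_engine(cfg, seed, schedule=schedule)
    start_session(state, cfg, 0.0)
    return cfg, state


def step(state, cfg, kind, t, **kw):
    _, actions = advance(state, cfg, RigEvent(kind, t, **kw))
    return actions


def valve_actions(actions):
    return [a for a in actions if a[0] == "open_valve"]


class TestTwoChoice:
    def test_lick_in_open_zone_rewarded(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        step(st, cfg, "distance_delta", 1.0, delta=50.0)  # approach done
        step(st, cfg, "distance_delta", 2.0, delta=10.0)  # 10 cm into grating
        acts = step(st, cfg, "lick_left", 2.1)
        assert valve_actions(acts) == [("open_valve", "left", 1, "earned")]

    def test_lick_before_zone_opens_not_rewarded(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        step(st, cfg, "distance_delta", 1.0, delta=50.0)
        step(st, cfg, "distance_delta", 2.0, delta=5.0)  # zone opens at 8.33
        assert valve_actions(step(st, cfg, "lick_left", 2.1)) == []

    def test_incorrect_side_never_rewarded(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        step(st, cfg, "distance_delta", 1.0, delta=50.0)
        step(st, cfg, "distance_delta", 2.0, delta=20.0)
        assert valve_actions(step(st, cfg, "lick_right", 2.1)) == []

    def test_reward_zone_entry_fires_once(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        step(st, cfg, "distance_delta", 1.0, delta=50.0)
        a1 = step(st, cfg, "distance_delta", 2.0, delta=9.0)
        a2 = step(st, cfg, "distance_delta", 3.0, delta=1.0)
        assert sum(a[0] == "reward_zone_entry" for a in a1) == 1
        assert all(a[0] != "reward_zone_entry" for a in a2)

    def test_backward_motion_floors_at_zero(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        step(st, cfg, "distance_delta", 1.0, delta=10.0)
        step(st, cfg, "distance_delta", 2.0, delta=-30.0)
        assert st.epoch_distance == 0.0


class TestAutoDelivery:
    def test_auto_fires_at_threshold_without_licks(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        step(st, cfg, "distance_delta", 1.0, delta=50.0)
        acts = step(st, cfg, "distance_delta", 2.0, delta=42.0)
        assert ("open_valve", "left", 1, "auto") in acts

    def test_no_auto_after_earned_reward(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        step(st, cfg, "distance_delta", 1.0, delta=50.0)
        step(st, cfg, "distance_delta", 2.0, delta=12.0)
        assert valve_actions(step(st, cfg, "lick_left", 2.1))
        acts = step(st, cfg, "distance_delta", 3.0, delta=30.0)
        assert valve_actions(acts) == []

    def test_auto_disabled_never_fires(self):
        cfg, st = fresh("two_choice", ["angled"] * 5)
        cfg.auto_water = False
        step(st, cfg, "distance_delta", 1.0, delta=50.0)
        acts = step(st, cfg, "distance_delta", 2.0, delta=45.0)
        assert valve_actions(acts) == []

    def test_auto_fires_on_error_trials(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        step(st, cfg, "distance_delta", 1.0, delta=50.0)
        step(st, cfg, "distance_delta", 2.0, delta=12.0)
        step(st, cfg, "lick_right", 2.1)  # error lick, no reward
        acts = step(st, cfg, "distance_delta", 3.0, delta=30.0)
        assert ("open_valve", "left", 1, "auto") in acts


class TestGoNogo:
    def test_response_delay_gates_reward_not_scoring(self):
        cfg, st = fresh("gonogo", ["go"] * 5)
        step(st, cfg, "init_touch", 1.0)  # stimulus epoch starts
        early = step(st, cfg, "lick_center", 1.3)
        assert valve_actions(early) == []
        late = step(st, cfg, "lick_center", 1.6)
        assert valve_actions(late) == [("open_valve", "center", 1, "earned")]
        # the early lick still counts for scoring
        assert st.licks[0].t_in_epoch == pytest.approx(0.3)

    def test_nogo_licks_never_rewarded(self):
        cfg, st = fresh("gonogo", ["nogo"] * 5)
        step(st, cfg, "init_touch", 1.0)
        assert valve_actions(step(st, cfg, "lick_center", 2.0)) == []
        acts = step(st, cfg, "timer_tick", 5.1)  # 4 s stimulus elapses
        labels = [a[2] for a in acts if a[0] == "end_trial"]
        assert labels == ["false_alarm"]


class TestShapingAndDeterrent:
    def run_shaping_trial(self, cfg, st, t0, side=None, lick_offset=1.0):
        """Drive one hf-shaping trial; returns (valve actions, end time)."""
        acts = step(st, cfg, "distance_delta", t0 + 0.1, delta=20.0)  # travel gate
        valves = valve_actions(acts)
        if side is not None:
            valves += valve_actions(step(st, cfg, f"lick_{side}", t0 + 0.1 + lick_offset))
        t_end = t0 + 0.1 + 6.0 + 0.01
        valves += valve_actions(step(st, cfg, "timer_tick", t_end))
        t_next = t_end + cfg.iti_s + 0.01
        valves += valve_actions(step(st, cfg, "timer_tick", t_next))
        return valves, t_next

    def test_travel_gate(self):
        cfg, st = fresh("hf_shaping", ["black"] * 20)
        cfg.auto_water = False
        acts = step(st, cfg, "distance_delta", 0.1, delta=19.9)
        assert all(a[0] != "enter_epoch" for a in acts)
        acts = step(st, cfg, "distance_delta", 0.2, delta=0.1)
        assert ("enter_epoch", "stimulus", 0, "black") in acts

    def test_lick_rewards_from_licked_port(self):
        cfg, st = fresh("hf_shaping", ["black"] * 20)
        cfg.auto_water = False
        valves, _ = self.run_shaping_trial(cfg, st, 0.0, side="right")
        assert valves == [("open_valve", "right", 1, "earned")]

    def test_auto_release_two_seconds_after_stimulus(self):
        cfg, st = fresh("hf_shaping", ["white"] * 20)
        step(st, cfg, "distance_delta", 0.1, delta=20.0)
        assert valve_actions(step(st, cfg, "timer_tick", 2.0)) == []
        acts = step(st, cfg, "timer_tick", 2.2)  # > 2 s after stimulus change
        assert len(valve_actions(acts)) == 1
        assert valve_actions(acts)[0][3] == "auto"

    def test_eight_same_side_trials_always_lock(self):
        cfg, st = fresh("hf_shaping", ["black"] * 40)
        cfg.auto_water = False
        t = 0.0
        for _ in range(8):
            _, t = self.run_shaping_trial(cfg, st, t, side="left")
        assert side_bias_deterrent(st)["locked_side"] == "left"

    def test_two_same_side_trials_never_lock(self):
        for seed in range(10):  # any threshold draw in {3..8}
            cfg, st = fresh("hf_shaping", ["black"] * 40, seed=seed)
            cfg.auto_water = False
            t = 0.0
            for _ in range(2):
                _, t = self.run_shaping_trial(cfg, st, t, side="left")
            assert side_bias_deterrent(st)["locked_side"] is None

    def test_locked_side_gives_no_water_and_other_side_unlocks(self):
        cfg, st = fresh("hf_shaping", ["black"] * 40)
        cfg.auto_water = False
        t = 0.0
        for _ in range(8):
            _, t = self.run_shaping_trial(cfg, st, t, side="left")
            if st.locked_side is not None:
                break
        assert st.locked_side == "left"
        assert st.pending_auto_side == "right"
        # locked side: lick yields nothing; the scheduled release fires from
        # the other port 2 s after the next stimulus change
        step(st, cfg, "distance_delta", t + 0.1, delta=20.0)
        licked = valve_actions(step(st, cfg, "lick_left", t + 0.2))
        assert licked == []
        auto = valve_actions(step(st, cfg, "timer_tick", t + 2.3))
        assert auto == [("open_valve", "right", 1, "auto")]
        step(st, cfg, "timer_tick", t + 6.2)  # stimulus window elapses
        t = t + 6.2 + cfg.iti_s + 0.01
        step(st, cfg, "timer_tick", t)  # next trial begins
        # subject triggers the right port itself -> unlock at trial end
        self.run_shaping_trial(cfg, st, t, side="right")
        assert st.locked_side is None

    def test_run_shaping_hf_rejects_other_configs(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        with pytest.raises(Exception, match="hf_shaping"):
            run_shaping_hf(st, cfg, RigEvent("timer_tick", 1.0))


class TestParameterUpdates:
    def test_update_takes_effect_next_trial(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        cfg.auto_water = False
        step(st, cfg, "param_update", 1.0, name="auto_water", value=True)
        assert cfg.auto_water is False  # still trial 1
        step(st, cfg, "distance_delta", 2.0, delta=50.0)  # approach done
        step(st, cfg, "distance_delta", 3.0, delta=50.0)  # grating done, trial over
        step(st, cfg, "timer_tick", 3.0 + cfg.iti_s + 0.01)  # next trial begins
        assert cfg.auto_water is True
        assert st.param_log[0].parameter == "auto_water"

    def test_last_write_wins(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        step(st, cfg, "param_update", 1.0, name="x_left", value=True)
        step(st, cfg, "param_update", 1.1, name="x_left", value=False)
        step(st, cfg, "distance_delta", 2.0, delta=50.0)
        step(st, cfg, "distance_delta", 3.0, delta=50.0)
        step(st, cfg, "timer_tick", 3.0 + cfg.iti_s + 0.01)
        assert cfg.x_left is False
        assert len(st.param_log) == 1

    def test_manual_open_is_immediate(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        acts = step(st, cfg, "param_update", 0.5, name="open_valve_left", value=None)
        assert valve_actions(acts) == [("open_valve", "left", 1, "manual")]

    def test_unknown_parameter_rejected(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        with pytest.raises(Exception, match="not adjustable"):
            step(st, cfg, "param_update", 0.5, name="drop_volume_ul", value=99)

    def test_x_left_triples_reward(self):
        cfg, st = fresh("two_choice", ["vertical"] * 5)
        cfg.x_left = True
        step(st, cfg, "distance_delta", 1.0, delta=50.0)
        step(st, cfg, "distance_delta", 2.0, delta=12.0)
        acts = step(st, cfg, "lick_left", 2.1)
        assert valve_actions(acts) == [("open_valve", "left", 3, "earned")]


class TestSessionEnd:
    def test_event_before_start_rejected(self):
        cfg = copy.deepcopy(org.load_config("two_choice"))
        st = init_engine(cfg, 0, schedule=["vertical"])
        with pytest.raises(Exception, match="before session start"):
            advance(st, cfg, RigEvent("timer_tick", 0.1))

    def test_max_rewards_ends_session(self):
        cfg, st = fresh("two_choice", ["vertical"] * 10)
        cfg.max_rewards = 2
        for trial in range(2):
            t = trial * 10.0
            step(st, cfg, "distance_delta", t + 1.0, delta=50.0)
            step(st, cfg, "distance_delta", t + 2.0, delta=12.0)
            acts = step(st, cfg, "lick_left", t + 2.1)
            if trial == 0:
                step(st, cfg, "distance_delta", t + 3.0, delta=40.0)
                step(st, cfg, "timer_tick", t + 3.0 + cfg.iti_s + 0.01)
        assert st.ended and st.end_reason == "max_rewards"
        assert ("end_session", "max_rewards") in acts

    def test_max_duration_ends_session(self):
        cfg, st = fresh("two_choice", ["vertical"] * 10)
        _, acts = advance(st, cfg, RigEvent("timer_tick", cfg.max_duration_min * 60.0))
        assert st.end_reason == "max_duration"

    def test_continue_short_of_both_limits(self):
        cfg, st = fresh("two_choice", ["vertical"] * 10)
        st.rewards = cfg.max_rewards - 1
        st.session_time = cfg.max_duration_min * 60.0 - 5.0
        assert session_end_check(st, cfg) is None


class TestScoring:
    def make_lick(self, side, pos, t=1.0, epoch="grating"):
        return Lick(time=t, side=side, epoch=epoch, t_in_epoch=t, position_cm=pos)

    def test_first_in_zone_lick_decides(self, two_choice_config):
        cfg = two_choice_config
        licks = [self.make_lick("left", 12.0, t=1.0), self.make_lick("right", 20.0, t=2.0)]
        assert score_trial(cfg, "vertical", licks) == "hit_vertical"
        assert score_trial(cfg, "angled", licks) == "fa_angled"

    def test_out_of_zone_licks_ignored(self, two_choice_config):
        licks = [self.make_lick("left", 5.0), self.make_lick("left", 45.0)]
        assert score_trial(two_choice_config, "vertical", licks) == "no_interaction"

    def test_gonogo_labels(self, gonogo_config):
        lick = [Lick(1.0, "center", "stimulus", 0.3, None)]
        assert score_trial(gonogo_config, "go", lick) == "hit"
        assert score_trial(gonogo_config, "go", []) == "miss"
        assert score_trial(gonogo_config, "nogo", lick) == "false_alarm"
        assert score_trial(gonogo_config, "nogo", []) == "correct_reject"


class TestConfigValidation:
    def test_iti_floor_enforced(self, two_choice_config):
        import dataclasses

        with pytest.raises(ValueError, match="iti_s"):
            dataclasses.replace(two_choice_config, iti_s=0.01)

    def test_zone_ordering_enforced(self, two_choice_config):
        import dataclasses

        with pytest.raises(ValueError, match="reward_zone"):
            dataclasses.replace(two_choice_config, reward_zone_open_cm=45.0)
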