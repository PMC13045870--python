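"""d-prime, side-bias index, summaries, learning criterion, bias controller."""

import math

import numpy as np
import pytest

import openrig as org
from openrig.analysis import (
    bias_controller,
    bias_index,
    dprime,
    learning_session,
    outcomes_from_records,
    rate_correction,
    sliding_performance,
    summarize_gonogo,
    summarize_two_choice,
)
from openrig.engine import Lick, TrialOutcome


def z_oracle(p):
    """Inverse normal CDF by bisection on math.erf (independent of scipy)."""
    lo, hi = -10.0, 10.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if 0.5 * (1.0 + math.erf(mid / math.sqrt(2.0))) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class TestRateCorrection:
    @pytest.mark.parametrize(
        "k,n,expected", [(10, 20, 0.5), (0, 20, 0.025), (20, 20, 0.975), (1, 4, 0.25)]
    )
    def test_values(self, k, n, expected):
        assert rate_correction(k, n) == pytest.approx(expected)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            rate_correction(0, 0)


class TestDprime:
    def test_symmetry_point(self):
        assert dprime(0.5, 0.5) == 0.0

    @pytest.mark.parametrize("h,f,expected", [(0.8, 0.2, 1.6832), (0.97725, 0.5, 2.0000)])
    def test_frozen_oracle_values(self, h, f, expected):
        assert dprime(h, f) == pytest.approx(expected, abs=2e-4)
        assert dprime(h, f) == pytest.approx(z_oracle(h) - z_oracle(f), abs=1e-6)

    def test_antisymmetry(self, rng):
        for _ in range(100):
            h, f = rng.uniform(0.01, 0.99, size=2)
            assert dprime(h, f) == pytest.approx(-dprime(f, h))

    def test_monotonicity(self):
        hs = np.linspace(0.05, 0.95, 19)
        vals = [dprime(h, 0.3) for h in hs]
        assert np.all(np.diff(vals) > 0)
        vals = [dprime(0.7, f) for f in hs]
        assert np.all(np.diff(vals) < 0)

    def test_boundary_rates_rejected(self):
        with pytest.raises(ValueError):
            dprime(1.0, 0.5)


class TestBiasIndex:
    def test_unbiased(self):
        assert bias_index(0.5, 0.5) == 0.0

    def test_high_left_lick_rates_mean_left_bias(self):
        # hit and fa are both left-lick proportions: licking left on
        # everything is a left (negative) bias
        assert bias_index(0.8, 0.8) == pytest.approx(-0.8416, abs=2e-4)
        assert bias_index(0.2, 0.2) == pytest.approx(+0.8416, abs=2e-4)

    def test_symmetric_in_arguments(self, rng):
        for _ in range(100):
            h, f = rng.uniform(0.01, 0.99, size=2)
            assert bias_index(h, f) == pytest.approx(bias_index(f, h))

    def test_sign_flips_under_complement(self, rng):
        for _ in range(100):
            h, f = rng.uniform(0.01, 0.99, size=2)
            assert bias_index(1 - h, 1 - f) == pytest.approx(-bias_index(h, f))


def make_outcome(trial_id, trial_type, label, lick_specs=()):
    licks = [Lick(time=i, side=s, epoch=e, t_in_epoch=i, position_cm=p) for i, (s, e, p) in enumerate(lick_specs)]
    return TrialOutcome(trial_id=trial_id, trial_type=trial_type, label=label, licks=licks)


class TestSummaries:
    def test_perfect_discrimination_with_correction(self, two_choice_config):
        outcomes = [
            make_outcome(i + 1, "vertical", "hit_vertical", [("left", "grating", 20.0)])
            for i in range(10)
        ] + [
            make_outcome(i + 11, "angled", "hit_angled", [("right", "grating", 20.0)])
            for i in range(10)
        ]
        s = summarize_two_choice(outcomes, two_choice_config)
        assert s.hit_rate == pytest.approx(0.95)
        assert s.fa_rate == pytest.approx(0.05)
        assert s.dprime_grating == pytest.approx(3.2897, abs=2e-4)
        assert s.dprime_grating == pytest.approx(2 * z_oracle(0.95), abs=1e-6)

    def test_all_no_interaction_leaves_dprime_undefined(self, two_choice_config):
        outcomes = [make_outcome(i + 1, "vertical", "no_interaction") for i in range(5)]
        s = summarize_two_choice(outcomes, two_choice_config)
        assert s.dprime_grating is None
        assert s.n_excluded == 5

    def test_epoch_rates_saturate_with_grating_only_licking(self, two_choice_config):
        n = 12
        outcomes = [
            make_outcome(i + 1, "vertical", "hit_vertical", [("left", "grating", 20.0)])
            for i in range(n)
        ]
        s = summarize_two_choice(outcomes, two_choice_config)
        assert s.epoch_hit_rate == pytest.approx(1 - 1 / (2 * n))
        assert s.epoch_fa_rate == pytest.approx(1 / (2 * n))

    def test_central_two_thirds_boundaries(self, two_choice_config):
        # a lick at 7 cm of the approach epoch is outside the central 2/3
        outcomes = [
            make_outcome(1, "vertical", "hit_vertical", [("left", "approach", 7.0), ("left", "grating", 20.0)]),
            make_outcome(2, "vertical", "hit_vertical", [("left", "approach", 10.0), ("left", "grating", 20.0)]),
        ]
        s = summarize_two_choice(outcomes, two_choice_config)
        assert s.epoch_fa_rate == pytest.approx(rate_correction(1, 2))

    def test_gonogo_corrected_rates(self):
        labels = ["hit"] * 30 + ["false_alarm"] * 0 + ["correct_reject"] * 70
        s = summarize_gonogo(labels)
        assert s.hit_rate == pytest.approx(59 / 60)
        assert s.fa_rate == pytest.approx(1 / 140)
        assert s.dprime_grating == pytest.approx(z_oracle(59 / 60) - z_oracle(1 / 140), abs=1e-6)

    def test_equal_counts_give_zero_dprime(self):
        labels = ["hit", "miss", "false_alarm", "correct_reject"] * 5
        assert summarize_gonogo(labels).dprime_grating == pytest.approx(0.0)

    def test_empty_session_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_gonogo([])

    def test_counts_total_scored_trials(self, small_session):
        s = summarize_two_choice(small_session.outcomes, small_session.config)
        assert sum(s.counts.values()) == s.n_scored == len(small_session.outcomes)


class TestSliding:
    def test_window_edges(self):
        assert sliding_performance(["hit"] * 99, window=100) == []
        out = sliding_performance(["hit", "correct_reject"] * 50, window=100)
        assert len(out) == 1 and out[0][0] == 100

    def test_constant_policy_series_is_flat(self, rng):
        labels = []
        for _ in range(400):
            if rng.random() < 0.3:
                labels.append("hit" if rng.random() < 0.9 else "miss")
            else:
                labels.append("false_alarm" if rng.random() < 0.2 else "correct_reject")
        series = [s.dprime_grating for _, s in sliding_performance(labels, window=100)]
        assert np.std(series) < 0.5  # binomial noise only, no trend


class TestLearning:
    def test_immediate(self):
        assert learning_session([2.0, 2.0, 2.0]) == 1

    def test_matches_enumeration_example(self):
        assert learning_session([0, 0, 2, 2, 0]) == 2

    def test_never(self):
        assert learning_session([0.0, 0.0, 0.0]) is None

    def test_agrees_with_brute_force_enumeration(self, rng):
        def brute(vals, thr=1.5, w=3, k=2):
            for s in range(len(vals) - w + 1):
                if sum(v > thr for v in vals[s : s + w]) >= k:
                    return s + 1
            return None

        for _ in range(1000):
            vals = rng.uniform(0, 3, size=rng.integers(0, 12)).tolist()
            assert learning_session(vals) == brute(vals)

    def test_threshold_strictness_is_configurable(self):
        vals = [1.5, 1.5, 1.5]
        assert learning_session(vals, strict=True) is None
        assert learning_session(vals, strict=False) == 1


class TestBiasController:
    def test_right_bias_boosts_left(self):
        assert bias_controller([1.2]) == ["boost_left"]

    def test_two_calm_sessions_re_equalize(self):
        assert bias_controller([1.2, 0.2, 0.2]) == ["boost_left", "boost_left", "re_equalize"]

    def test_subthreshold_never_acts(self):
        assert bias_controller([0.5, 0.5, 0.5]) == ["none"] * 3

    def test_left_bias_boosts_right_and_relapse_restarts(self):
        actions = bias_controller([-1.5, 0.1, 0.8, 0.1, 0.1, 0.3, -1.2])
        assert actions == [
            "boost_right", "boost_right", "boost_right", "boost_right",
            "re_equalize", "none", "boost_right",
        ]


class TestRecordLevelScoring:
    def test_reanalysis_matches_engine_labels(self, small_session, small_session_record):
        cfg = small_session.config
        outcomes = outcomes_from_records(cfg, small_session_record)
        engine_labels = [o.label for o in small_session.outcomes]
        assert [o.label for o in outcomes] == engine_labels
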