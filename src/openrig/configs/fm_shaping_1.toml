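# Freely moving shaping stage 1: stimulus (40 white circles) appears after a
# random 0.5-3 s delay; any lick is rewarded; trial ends 0.5 s after reward.

[task]
kind = "fm_shaping_1"
drop_volume_ul = 4.0
iti_s = 0.5
n_trials = 1500

[session_end]
max_rewards = 190
max_duration_min = 90.0

[[epochs]]
name = "prestim"
trigger = "timer"
duration_range_s = [0.5, 3.0]
stimulus = "gray"

[[epochs]]
name = "stimulus"
trigger = "response"
timeout_s = 60.0
post_reward_s = 0.5
decision = true
stimulus = "white_circles"

[schedule]
trial_types = ["stim"]
probs = [1.0]
max_consecutive = 100000

[contingency]
stim = "center"
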