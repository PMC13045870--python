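# Freely moving shaping stage 2: the subject self-initiates each trial by
# touching the initiation sensor; any lick during the stimulus is rewarded.

[task]
kind = "fm_shaping_2"
drop_volume_ul = 4.0
iti_s = 0.5
n_trials = 1500

[session_end]
max_rewards = 190
max_duration_min = 90.0

[[epochs]]
name = "prestim"
trigger = "event"
sensor = "init_touch"
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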