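# Head-fixed acclimation: 20 cm travel gate, 6 s black/white stimulus window,
# either-port reward, optional auto release 2 s after stimulus change,
# side-bias deterrent rule active.

[task]
kind = "hf_shaping"
drop_volume_ul = 6.0
iti_s = 2.0
auto_release_after_s = 2.0
n_trials = 1000

[session_end]
max_rewards = 125
max_duration_min = 90.0

[[epochs]]
name = "travel"
trigger = "distance"
length_cm = 20.0
stimulus = "gray"

[[epochs]]
name = "stimulus"
trigger = "timer"
duration_s = 6.0
decision = true
stimulus = "black_or_white"

[schedule]
trial_types = ["black", "white"]
probs = [0.5, 0.5]
max_consecutive = 1000000

[contingency]
black = "none"
white = "none"

[adjustable]
auto_water = true
autoclicker = true
side_bias_rule = true
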