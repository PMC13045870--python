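# Head-fixed closed-loop two-choice visual discrimination task.
# Vertical grating -> left licks rewarded; angled (135 deg) grating -> right.

[task]
kind = "two_choice_closed_loop"
drop_volume_ul = 6.0
iti_s = 2.0
response_delay_s = 0.0
n_trials = 1000

[session_end]
max_rewards = 125
max_duration_min = 90.0

[[epochs]]
name = "approach"
trigger = "distance"
length_cm = 50.0
stimulus = "circles"

[[epochs]]
name = "grating"
trigger = "distance"
length_cm = 50.0
decision = true
stimulus = "grating"

[schedule]
trial_types = ["vertical", "angled"]
probs = [0.5, 0.5]
max_consecutive = 3

[contingency]
vertical = "left"
angled = "right"

[reward_zone]
open_cm = 8.333333333333334
auto_delivery_cm = 41.66666666666667

[adjustable]
auto_water = true
x_left = false
x_right = false
autoclicker = true
side_bias_rule = false

[metadata]
spatial_frequency_cpd = 0.04
grating_orientations_deg = [0, 135]
closed_loop_gain_cm_per_cm = 1.0
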