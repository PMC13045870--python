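# Freely moving Go/No-go luminance discrimination: self-initiated 4 s stimulus
# (white circles = Go, black = No-go); Go licks rewarded after a 0.5 s delay.

[task]
kind = "gonogo_freely_moving"
drop_volume_ul = 4.0
iti_s = 0.5
response_delay_s = 0.5
n_trials = 2500

[session_end]
max_rewards = 190
max_duration_min = 120.0

[[epochs]]
name = "prestim"
trigger = "event"
sensor = "init_touch"
stimulus = "gray"

[[epochs]]
name = "stimulus"
trigger = "timer"
duration_s = 4.0
decision = true
stimulus = "luminance_circles"

[schedule]
trial_types = ["go", "nogo"]
probs = [0.3, 0.7]
max_consecutive = 10

[contingency]
go = "center"
nogo = "none"

[metadata]
circle_diameter_px = 50
n_circles = 40
circle_diameter_deg = 6
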