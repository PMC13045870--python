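"""Constrained trial scheduling: probabilities plus a maximum-run limit.

The freely moving task draws Go trials with probability 0.3 but never
presents the same trial type more than 10 times in a row; the head-fixed
task uses 0.5/0.5 with a limit of 3.  Runs that would exceed the limit
are broken by a forced flip (redraw among the other types).
"""

from openrig import ScheduleSpec, empirical_frequencies, generate_schedule, max_run_length

for name, probs, limit in [
    ("two-choice", {"vertical": 0.5, "angled": 0.5}, 3),
    ("go/no-go", {"go": 0.3, "nogo": 0.7}, 10),
]:
    spec = ScheduleSpec(n_trials=2000, type_probs=probs, max_consecutive=limit, seed=7)
    schedule = generate_schedule(spec)
    freqs = {k: round(v, 3) for k, v in empirical_frequencies(schedule).items()}
    print(f"{name}: longest run {max_run_length(schedule)} (limit {limit}), frequencies {freqs}")
# The longest run never exceeds the limit; empirical frequencies stay close
# to the nominal probabilities (the forced flip slightly favors the minority
# type when the constraint binds).
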