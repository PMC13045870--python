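"""Simulate one head-fixed closed-loop two-choice session end to end.

A virtual mouse (signal-detection agent) runs the 50 cm approach + 50 cm
grating corridor; licks in the reward zone trigger water, and the session
ends at 125 rewards (750 ul / 6 ul drops) or 90 min.
"""

from collections import Counter

import openrig as org

config = org.load_config("two_choice")
policy = org.AgentPolicy(d_true=2.5, c_true=0.3, lapse=0.02)  # competent, slight right bias
raw = org.run_session(config, policy, seed=42)

print(f"session ended by {raw.end_reason}: {raw.rewards} rewards, {raw.volume_ul:.0f} ul")
print("trial outcomes:", dict(Counter(o.label for o in raw.outcomes)))

session, excluded = org.build_session(raw)
print(f"aligned {len(session.trials)} trials ({len(excluded)} excluded); "
      f"record invariant violations: {len(org.validate_session(session))}")

rec = session.trials[0]
print(f"\ntrial 1 ({rec.trial_type}): {rec.n_timestamps} MCU timestamps, "
      f"{len(rec.encoder_combined)} encoder samples")
print("first encoder samples (time s, corridor cm; negative = approach distance-to-go):")
for row in rec.encoder_combined[:3]:
    print(f"  {row[0]:+.3f}  {row[1]:+.2f}")
# The outcome labels feed the performance analysis; the per-trial records
# serialize losslessly to the standardized JSON session directory.
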