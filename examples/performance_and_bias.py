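"""Signal-detection performance analysis and the side-bias controller.

Simulates a training trajectory (sessions with increasing sensitivity and
a decaying right bias), scores each session (d' and side-bias index), finds
the learning session, and shows the multi-session reward-boost controller.
"""

import numpy as np

import openrig as org
from openrig.analysis import bias_controller, learning_session, summarize_two_choice

config = org.load_config("two_choice")
d_by_session = [0.3, 0.6, 1.0, 1.4, 1.9, 2.3, 2.6, 2.8]
c_by_session = [1.4, 1.2, 0.9, 0.6, 0.3, 0.15, 0.1, 0.05]  # right bias fading

dprimes, biases = [], []
for s, (d, c) in enumerate(zip(d_by_session, c_by_session)):
    import copy

    cfg = copy.deepcopy(config)
    cfg.max_rewards = 60
    policy = org.AgentPolicy(d_true=d, c_true=c, lapse=0.02)
    raw = org.run_session(cfg, policy, seed=100 + s)
    summary = summarize_two_choice(raw.outcomes, cfg, session_id=f"s{s+1}")
    dprimes.append(summary.dprime_grating)
    biases.append(summary.bias)
    print(f"session {s+1}: d'={summary.dprime_grating:+.2f}  bias={summary.bias:+.2f}  "
          f"(hit {summary.hit_rate:.2f}, fa {summary.fa_rate:.2f})")

learned = learning_session(dprimes, threshold=1.5)
print(f"\nlearning session (first of a 3-session window with >=2 sessions d'>1.5): {learned}")
print("bias controller actions after each session:", bias_controller(biases))
# d' tracks the generative sensitivity; the positive bias index flags the
# right bias, triggering boost_left until two calm sessions re-equalize.
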