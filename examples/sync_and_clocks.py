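"""Two-clock synchronization: discrepancy benchmark and TTL precision.

Lick/valve/state events are stamped on the MCU clock, external-device
samples on the program clock; aligning each stream to the anchor epoch on
its own clock makes offset and drift cancel.  This script measures the
per-epoch duration disagreement between the clocks and the TTL sampling
latency at the 300 Hz polling rate.
"""

import copy

import numpy as np

import openrig as org
from openrig.rig import ClockSpec, RigClocks
from openrig.sync import TTL_PERIOD_S, clock_discrepancy, sample_ttl

cfg = copy.deepcopy(org.load_config("two_choice"))
cfg.max_rewards = 30
clocks = RigClocks(
    mcu=ClockSpec(offset_s=35.0, drift_ppm=20.0, jitter_sd_ms=0.2, period_ms=1.0),
    program=ClockSpec(jitter_sd_ms=0.1, period_ms=0.1),
)
raw = org.run_session(cfg, org.AgentPolicy(d_true=3.0), clocks=clocks, seed=5)
mean_ms, max_ms = clock_discrepancy(raw)
print(f"per-epoch clock discrepancy over {len(raw.outcomes)} trials: "
      f"mean {mean_ms:.3f} ms, max {max_ms:.3f} ms")

rng = np.random.default_rng(5)
edges = rng.uniform(0, 300, size=10_000)
latency = sample_ttl(edges) - edges
print(f"TTL polling at 300 Hz: period {TTL_PERIOD_S*1e3:.1f} ms, "
      f"max latency {latency.max()*1e3:.2f} ms (always < one period)")
# Sub-millisecond mean discrepancy despite a 35 s offset and 20 ppm drift:
# offsets and drift cancel in within-trial durations on a single clock.
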