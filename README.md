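# openrig

A hardware-free, fully testable implementation of an open-source
behavioral platform for rodent psychophysics: a trial/epoch finite-state
task engine for head-fixed closed-loop and freely moving operant
paradigms, constrained trial scheduling, multi-device two-clock
synchronization into a standardized per-trial output format,
signal-detection performance and side-bias analysis, and a two-stage
pupillometry pipeline — all exercised by a simulated rig with a
parametric virtual mouse, so every stage runs and is tested without
hardware or animals.

It is aimed at behavioral/systems neuroscientists who want to prototype
task logic, validate analysis pipelines, or generate realistic synthetic
session data in the platform's standardized trial-record format.

## What it implements

**Tasks.** A head-fixed closed-loop two-choice visual discrimination
task (50 cm approach corridor then 50 cm grating corridor; vertical
grating → left licks rewarded, angled → right; reward zone opens at
8.33 cm, automatic delivery at 41.67 cm, 6 µl drops, sessions end at
125 rewards or 90 min), its shaping stage (20 cm travel gate, 6 s
stimulus window, either-port reward, randomized 3–8-trial side-bias
deterrent), and a freely moving Go/No-go luminance task (self-initiated
4 s stimulus, Go probability 0.3, 0.5 s response delay, 4 µl drops,
190 rewards or 120 min) with its two shaping stages. Parameters update
online at trial boundaries; manual valve commands act immediately.

**Scheduling.** Trial types are drawn i.i.d. at session start under a
maximum-run constraint (3 consecutive for the two-choice task, 10 for
Go/No-go), enforced by a forced flip among the remaining types.

**Analysis.** Performance is the equal-variance signal-detection
sensitivity

    d′ = z(hit rate) − z(false-alarm rate),

and response bias is the criterion-style side-bias index

    index = −(z(hit) + z(fa)) / 2,

computed under the left-lick-positive convention (positive = right
bias), with a 1/(2N) correction for rates of 0 or 1. Learning is the
first session of a 3-session window with at least two sessions above
d′ = 1.5; bias correction engages above |index| = 1 and re-equalizes
after two sessions below 0.25.

**Synchronization.** Lick/valve/state events live on the MCU clock
(integer milliseconds), external-device streams (300 Hz wheel encoder,
10 Hz eye camera) on the program clock. Each trial is aligned to the
anchor (stimulus) epoch onset on each stream's own clock, so offsets
and drift cancel; TTL edges are timestamped at the 300 Hz polling grid
(latency < 3.3 ms).

**Pupillometry.** Frames are classified open/occluded, open frames are
segmented by a circular-Hough accumulator over the binarized dark
region, radii are normalized to the session median, and open-but-
unsegmentable frames are flagged for click-seeded re-segmentation.

## Worked example

```python
from collections import Counter
import openrig as org

config = org.load_config("two_choice")
policy = org.AgentPolicy(d_true=2.5, c_true=0.3, lapse=0.02)
raw = org.run_session(config, policy, seed=42)
session, excluded = org.build_session(raw)
```

prints (via `python examples/simulate_two_choice_session.py`):

```
session ended by max_rewards: 125 rewards, 750 ul
trial outcomes: {'hit_angled': 57, 'fa_vertical': 16, 'hit_vertical': 43, 'fa_angled': 3, 'no_interaction': 6}
aligned 125 trials (0 excluded); record invariant violations: 0
```

The virtual mouse has true sensitivity d′ = 2.5 and a right-ward
criterion of 0.3, so it collects the full 750 µl ration (125 × 6 µl
drops) before the 90 min limit; its right bias shows up as 16 vertical
trials licked right (`fa_vertical`) against only 3 angled trials licked
left (`fa_angled`), and a handful of disengaged trials score
`no_interaction`. Scoring the session with
`summarize_two_choice(raw.outcomes, config)` returns the corrected
hit/false-alarm rates, d′ near the generative 2.5, and a positive bias
index flagging the right bias.

Other entry points are shown in `examples/` (scheduling constraints,
performance + bias-controller trajectory, pupillometry, clock
benchmarking), and the same pipeline is scriptable from the shell:

```
openrig simulate --config two_choice --seed 42 --out session/
openrig validate --session session/
openrig analyze  --session session/ --out analysis/
openrig pupil    --frames session/frames --out pupil/
```

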