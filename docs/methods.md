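# Methods

## Task model

A session is a sequence of trials drawn from a schedule fixed at
session start; a trial is an ordered sequence of epochs, each with its
own transition rule: accumulated locomotion distance (closed-loop
corridor segments), elapsed time, a sensor event (trial
self-initiation), or a response rule (the epoch ends a fixed interval
after a rewarded lick). The engine is an event-driven state machine:
it consumes timestamped events (licks, encoder distance deltas, timer
ticks, manual commands) and emits actions (valve openings, epoch
entries, trial/session ends) that the rig executes and logs.

Key contingencies, with defaults taken from the platform's published
task descriptions:

| parameter | default | meaning |
|---|---|---|
| epoch lengths | 50 cm + 50 cm (two-choice), 20 cm gate (shaping) | corridor segments; 1 cm wheel = 1 cm visual flow |
| reward zone open | length/6 = 8.33 cm | first distance at which a lick can trigger water |
| auto delivery | 5·length/6 = 41.67 cm | automatic reward point on unrewarded trials (auto-water on) |
| drop volume | 6 µl head-fixed, 4 µl freely moving | one valve opening |
| session end | 125 rewards / 90 min; 190 / 120 min | whichever comes first (≈750 µl either way) |
| response delay | 0.5 s (Go/No-go) | licks before it score but cannot trigger reward |
| stimulus window | 4 s (Go/No-go), 6 s (shaping) | timer epochs |
| ITI | 2 s / 0.5 s | floor 50 ms (GUI update bound), enforced at validation |
| run limits | 3 (two-choice), 10 (Go/No-go) | maximum consecutive identical trial types |
| side-bias deterrent | threshold ~ U{3..8}, redrawn per trial | locks a port after that many consecutively rewarded same-side trials |

Design choices where the published description is open:

* The decision lick is the **first** lick whose position lies inside
  the reward zone; later licks are recorded but never change the
  outcome. The decision zone closes at the auto-delivery distance.
* Deterrent counting uses **trials** whose reward the subject itself
  triggered, not raw lick events; the scheduled release from the
  non-locked port fires once, 2 s after the next stimulus change, and
  release of the lock requires the subject to trigger the other port.
* Backward wheel motion decrements accumulated distance but floors at
  the epoch start, so corridor positions are never negative.
* Manual valve commands act immediately and are logged as manual
  dispenses (mutually exclusive with subject-triggered rewards in the
  record flags); all other parameter updates queue and apply at the
  next trial boundary, last write winning.
* The 3-drop reward boost is a single valve action with a drop count,
  so reward accounting stays `drops × drop volume = session volume`.
* `advance` mutates the engine state in place and returns it with the
  emitted actions. The transition is still fully determined by
  (config, schedule, event sequence, engine seed) — verified by a
  byte-identical-log test — and in-place update keeps the 300 Hz event
  loop cheap.

## Scheduling

Trial types are drawn i.i.d. from the configured probabilities; a draw
that would create a run of `max_consecutive + 1` is redrawn from the
remaining types with probabilities renormalized (forced flip). This is
O(n), generates the whole schedule at session start, and slightly
inflates the minority-type frequency when the constraint binds (at
Go probability 0.3 with limit 10 the inflation is far below the
sampling noise of a session); we document rather than correct it.
Whole-schedule rejection sampling would remove the bias but is not what
an online "alter the next trial" rule does.

## Virtual rig

The rig exists so that every downstream module has a ground-truth
oracle; it emulates the study conditions, not any particular animal.

* **Agent.** An equal-variance signal-detection agent: evidence ~
  Normal(±d_true/2, 1), respond left iff evidence > c_true, with a
  lapse probability of a random-side guess and per-trial engagement
  probabilities. Because this matches the analysis model, the
  analysis estimates have known targets: d̂′ → d_true and the side-bias
  index → c_true (positive c_true = right bias under the
  left-lick-positive convention). Defaults (d_true 2.5, lapse 0.02,
  engagement 0.95) describe a trained subject.
* **Locomotion.** Speed per 300 Hz tick is truncated-normal
  (mean 15 cm/s, sd 5, floor 0) — a realistic running gait giving
  variable trial durations; the decision lick position is drawn
  uniformly inside the reward zone with a 0.5 cm margin (several ticks
  of travel) so tick quantization cannot push a planned in-zone lick
  across a zone boundary.
* **Clocks.** Device time = (t + offset)·(1 + drift·1e-6) + jitter,
  quantized to the clock's grid. Licks/valves/states are stamped on
  the MCU clock (integer ms, monotonic), encoder and camera triggers
  on the program clock. Defaults: 0.2/0.1 ms jitter, 20 ppm MCU
  drift — small electronics-grade imperfections.
* **Eye frames.** 64×64 grayscale: a dark pupil disk (intensity 30,
  radius ~ N(12, 2) px) on a brighter iris (150) with additive noise
  (sd 8); occluded frames overlay an eyelid band (200) that fully
  covers the pupil. What this does *not* emulate: specular highlights,
  partial occlusions, gaze shifts, or arousal-linked radius dynamics
  (the session radius series is a cosmetic AR(1) around 12 px).
  Passing tests therefore demonstrate pipeline correctness on
  well-posed frames, not robustness to real video artifacts.

All randomness flows from one session seed through named sub-streams
(schedule, agent, clocks, frames), so components are independently
reproducible and the same seed yields byte-identical logs.

## Synchronization

Anchor-relative times never cross clocks: MCU events are re-expressed
as differences from the anchor-epoch onset *on the MCU clock*, program
streams from the onset on the program clock. Offsets and drift cancel
in within-trial differences, which is the design rationale for the
two-clock layout. Pre-anchor times are negative; approach positions
are negative distance-to-go. Trials missing their anchor are excluded
(and counted), not interpolated; surviving trials are renumbered
densely. Duplicate encoder timestamps raise an error rather than being
merged — they indicate a generator bug. Because the MCU log is integer
milliseconds, two ideal clocks still disagree by up to 1 ms per epoch
duration; the zero-discrepancy case requires both clocks on the same
1 ms grid. The simulated discrepancy benchmark (default jitters) gives
a sub-millisecond mean, consistent with the platform's published
hardware benchmark, but no pass threshold is tied to that
hardware-specific number.

## Analysis

Rates use the 1/(2N) correction for 0 and 1 before the z-transform
(the log-linear alternative would shrink all rates; we only correct
the undefined boundaries). The side-bias index is implemented as the
*signed* criterion −(zH+zF)/2 — the only reading under which positive
values mean a right bias — with decision thresholds applied to its
absolute value. The learning criterion returns the first session of
the qualifying window; strictness of the d′ > 1.5 comparison is a
parameter because published usage varies between > and ≥. Epoch
discrimination passes plain lick proportions through the same
correction and z-machinery as grating discrimination.

Estimator precision: at 300 decision trials the sampling sd of d̂′ is
≈0.15–0.19 for d′ in 0.5–2.5, so a ±0.25 band cannot be hit in ≥95% of
sessions at the upper sensitivities; the bias index, with half that
sd, recovers the generative criterion within ±0.2.

## Pupillometry

Stage 1 is a regularized logistic rule over eight intensity/contrast
features (mean, sd, dark-pixel fraction, percentiles, top-bottom
contrast, smoothed minimum), standardized and persisted as JSON; it is
deliberately lightweight and pluggable — downstream stages only need a
binary label plus confidence, and the 70 + 70 training regime of the
deep model it stands in for is reproduced on synthetic frames. Stage 2
thresholds dark pixels (default 90), runs a circular Hough accumulator
over the mask boundary for radii 5–25 px, accepts peaks above a
normalized accumulator value of 0.4, and refines the radius as the
mean distance of boundary pixels to the detected center (sub-pixel;
median error ≈4% at noise sd 8). Seeded re-segmentation maximizes
inside/outside contrast over centers within ±3 px of the click and
flags fits below 25 intensity units of contrast as low-confidence.
"Session" for median normalization means all frames processed in one
call (one session directory).

## Problem sizes

Default test and acceptance workloads are sized for a laptop-class
run: full 125-reward simulated sessions (~3×10⁵ engine events),
1,000 schedules × 2,000 trials per run-limit check, 200 replicates ×
300 trials for estimator recovery, and 500–1,000 frames for the
pupillometry end-to-end checks.

## Known limitations

* The engine models one lick-port pair plus one initiation sensor; the
  multi-port generality of the original hardware hub is out of scope.
* No stimulus rendering: grating/circle parameters are carried as
  metadata only.
* The freely moving shaping stages use a response-epoch timeout (60 s)
  the original description leaves unspecified.
* The pupillometry classifier contract is validated on synthetic
  frames only; swapping in a deep model for real video is an intended
  extension point, not something the tests certify.
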