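"""Session-start trial-type scheduling under maximum-run constraints.

Schedules are drawn i.i.d. from the configured type probabilities except
that no trial type may repeat more than ``max_consecutive`` times in a
row.  Enforcement is by *forced flip*: when a draw would extend a run to
``max_consecutive + 1``, the trial type is redrawn from the remaining
labels with probabilities renormalized.  The whole schedule is generated
once at session start, so a parameter-change log can reference a fixed
schedule.

The forced flip slightly inflates the long-run frequency of minority
labels relative to the nominal probabilities whenever the constraint
binds; this bias is documented rather than corrected.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ScheduleSpec:
    """Parameters of a session schedule."""

    n_trials: int
    type_probs: dict[str, float]
    max_consecutive: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if self.max_consecutive < 1:
            raise ValueError("max_consecutive must be >= 1")
        total = sum(self.type_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"type probabilities must sum to 1, got {total}")
        if any(p < 0 for p in self.type_probs.values()):
            raise ValueError("probabilities must be non-negative")


def generate_schedule(spec: ScheduleSpec) -> list[str]:
    """Draw a trial-type schedule satisfying the run-length constraint.

    Deterministic given ``spec.seed``.  Raises if the constraint is
    unsatisfiable (a single available label but ``n_trials`` exceeding
    ``max_consecutive``).
    """
    labels = list(spec.type_probs)
    probs = np.array([spec.type_probs[k] for k in labels], dtype=float)
    effective = [k for k, p in zip(labels, probs) if p > 0]
    if len(effective) == 1 and spec.n_trials > spec.max_consecutive:
        raise ValueError(
            "unsatisfiable constraint: single trial type with "
            f"n_trials={spec.n_trials} > max_consecutive={spec.max_consecutive}"
        )
    rng = np.random.default_rng(spec.seed)
    cum = np.cumsum(probs)
    schedule: list[str] = []
    run_label: str | None = None
    run_len = 0
    for _ in range(spec.n_trials):
        idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        label = labels[min(idx, len(labels) - 1)]
        if label == run_label and run_len >= spec.max_consecutive:
            # forced flip: redraw among the remaining labels, renormalized
            others = [i for i, k in enumerate(labels) if k != label and probs[i] > 0]
            if not others:
                raise ValueError("unsatisfiable constraint: no alternative trial type")
            sub = probs[others]
            sub_cum = np.cumsum(sub)
            j = int(np.searchsorted(sub_cum, rng.random() * sub_cum[-1], side="right"))
            label = labels[others[min(j, len(others) - 1)]]
        if label == run_label:
            run_len += 1
        else:
            run_label = label
            run_len = 1
        schedule.append(label)
    return schedule


def max_run_length(schedule: list[str]) -> int:
    """Length of the longest constant run; 0 for an empty schedule."""
    best = 0
    run = 0
    prev: str | None = None
    for label in schedule:
        run = run + 1 if label == prev else 1
        prev = label
        best = max(best, run)
    return best


def empirical_frequencies(schedule: list[str]) -> dict[str, float]:
    """Observed proportion of each label; empty dict for an empty schedule."""
    if not schedule:
        return {}
    counts = Counter(schedule)
    n = len(schedule)
    return {label: counts[label] / n for label in counts}
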