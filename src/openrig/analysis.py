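"""Signal-detection performance and side-bias analysis.

Sensitivity is the standard equal-variance d′,

    d' = z(hit rate) - z(false-alarm rate),

with z the inverse standard normal CDF.  The side-bias index is the
(signed) criterion

    index = -(z(hit rate) + z(false alarm rate)) / 2,

computed under the left-lick-positive convention, so positive values
indicate a bias toward licking right and negative values a bias toward
the left.  Decision thresholds (bias correction engages above |index| =
1 and is considered reduced below 0.25) apply to the absolute value.

Two discriminations are scored for the two-choice corridor task:

* grating discrimination — hit rate is the proportion of vertical
  trials with a correct left lick inside the reward zone, out of
  vertical trials with any in-zone lick; false-alarm rate is the
  proportion of angled trials with an (incorrect) left in-zone lick,
  out of angled trials with any in-zone lick.  No-interaction trials
  are excluded.
* epoch discrimination — hit rate is the proportion of trials with at
  least one lick in the central two-thirds of the decision epoch,
  false-alarm rate the same for the approach epoch.

Observed rates of 0 and 1 are shrunk by the standard 1/(2N) correction
before the z-transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .engine import TaskConfig, TrialOutcome


def rate_correction(k: int, n: int) -> float:
    """Proportion ``k/n`` with 0 -> 1/(2n) and n -> 1 - 1/(2n)."""
    if n <= 0:
        raise ValueError("rate_correction requires n > 0")
    if k == 0:
        return 1.0 / (2 * n)
    if k == n:
        return 1.0 - 1.0 / (2 * n)
    return k / n


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Sensitivity ``z(hit) - z(fa)``; rates must lie strictly in (0, 1)."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must be in (0, 1); apply rate_correction first")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def bias_index(hit_rate: float, fa_rate: float) -> float:
    """Signed criterion ``-(z(hit) + z(fa)) / 2``.

    Positive = right bias, negative = left bias (left-lick-positive
    convention).  Apply thresholds to the absolute value.
    """
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must be in (0, 1); apply rate_correction first")
    return float(-(norm.ppf(hit_rate) + norm.ppf(fa_rate)) / 2.0)


@dataclass
class PerformanceSummary:
    session_id: str = ""
    counts: dict[str, int] = field(default_factory=dict)
    n_scored: int = 0
    n_excluded: int = 0
    hit_rate: float | None = None
    fa_rate: float | None = None
    dprime_grating: float | None = None
    bias: float | None = None
    epoch_hit_rate: float | None = None
    epoch_fa_rate: float | None = None
    dprime_epoch: float | None = None


def _central_zone(config: TaskConfig) -> tuple[float, float]:
    """Central two-thirds of a corridor epoch, in within-epoch cm."""
    ep = config.decision_epoch()
    length = ep.length_cm if ep is not None and ep.length_cm else 50.0
    return (length / 6.0, 5.0 * length / 6.0)


def summarize_two_choice(
    outcomes: Sequence[TrialOutcome], config: TaskConfig, session_id: str = ""
) -> PerformanceSummary:
    """Grating- and epoch-discrimination summary for a two-choice session.

    Epoch discrimination counts trials with any lick in the central
    two-thirds of the decision (hit) versus approach (false alarm)
    epoch; for a 50 cm epoch those bounds are 8.33-41.67 cm, matching
    the reward-zone geometry.
    """
    lo, hi = _central_zone(config)
    approach = config.epochs[0].name
    decision = config.decision_epoch().name
    counts: dict[str, int] = {}
    n_epoch_hit = 0
    n_epoch_fa = 0
    for out in outcomes:
        counts[out.label] = counts.get(out.label, 0) + 1
        pos = [(l.epoch, l.position_cm) for l in out.licks if l.position_cm is not None]
        if any(ep == decision and lo <= p < hi for ep, p in pos):
            n_epoch_hit += 1
        if any(ep == approach and lo <= p < hi for ep, p in pos):
            n_epoch_fa += 1

    n = len(outcomes)
    summary = PerformanceSummary(session_id=session_id, counts=counts, n_scored=n)
    summary.n_excluded = counts.get("no_interaction", 0)
    if n > 0:
        eh = rate_correction(n_epoch_hit, n)
        ef = rate_correction(n_epoch_fa, n)
        summary.epoch_hit_rate = eh
        summary.epoch_fa_rate = ef
        summary.dprime_epoch = dprime(eh, ef)
    hv = counts.get("hit_vertical", 0)
    fv = counts.get("fa_vertical", 0)
    ha = counts.get("hit_angled", 0)
    fa = counts.get("fa_angled", 0)
    if hv + fv > 0 and ha + fa > 0:
        # left-lick convention: hit = left lick on vertical, fa = left lick on angled
        h = rate_correction(hv, hv + fv)
        f = rate_correction(fa, ha + fa)
        summary.hit_rate = h
        summary.fa_rate = f
        summary.dprime_grating = dprime(h, f)
        summary.bias = bias_index(h, f)
    return summary


def summarize_gonogo(
    outcomes: Sequence[TrialOutcome | str], session_id: str = ""
) -> PerformanceSummary:
    """Hit/false-alarm/d′ summary for a Go/No-go session."""
    labels = [o.label if isinstance(o, TrialOutcome) else o for o in outcomes]
    if not labels:
        raise ValueError("empty session")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    hits = counts.get("hit", 0)
    misses = counts.get("miss", 0)
    fas = counts.get("false_alarm", 0)
    crs = counts.get("correct_reject", 0)
    summary = PerformanceSummary(session_id=session_id, counts=counts, n_scored=len(labels))
    if hits + misses > 0 and fas + crs > 0:
        h = rate_correction(hits, hits + misses)
        f = rate_correction(fas, fas + crs)
        summary.hit_rate = h
        summary.fa_rate = f
        summary.dprime_grating = dprime(h, f)
    return summary


def sliding_performance(
    outcomes: Sequence[TrialOutcome | str], window: int = 100
) -> list[tuple[int, PerformanceSummary]]:
    """Go/No-go performance over a sliding window of trials.

    One summary per window end position ``i`` in ``[window, n]``
    (1-based, stride 1); empty when fewer trials than the window.
    """
    labels = [o.label if isinstance(o, TrialOutcome) else o for o in outcomes]
    out = []
    for end in range(window, len(labels) + 1):
        out.append((end, summarize_gonogo(labels[end - window : end])))
    return out


def learning_session(
    dprimes: Sequence[float],
    threshold: float = 1.5,
    window: int = 3,
    min_above: int = 2,
    strict: bool = True,
) -> int | None:
    """First session of a window in which performance counts as learned.

    Returns the smallest 1-based session number ``s`` such that at
    least ``min_above`` of sessions ``{s, ..., s+window-1}`` have d′
    exceeding ``threshold`` (strictly by default), or None.
    """
    n = len(dprimes)
    for s in range(0, n - window + 1):
        vals = dprimes[s : s + window]
        above = sum(v > threshold if strict else v >= threshold for v in vals)
        if above >= min_above:
            return s + 1
    return None


def bias_controller(
    indices: Sequence[float],
    engage_threshold: float = 1.0,
    release_threshold: float = 0.25,
    sessions_required: int = 2,
) -> list[str]:
    """Multi-session reward-boost controller for side bias.

    After a session with index > +1 (right bias) the next session
    boosts the left port (extra drops on left-rewarded trials); index
    < -1 boosts the right port.  Boosting continues until at least two
    consecutive sessions have |index| below 0.25, then rewards are
    re-equalized; afterwards no action unless the threshold is crossed
    again.  Returns the action to take *after* each session, one of
    none / boost_left / boost_right / re_equalize.
    """
    actions: list[str] = []
    boosting: str | None = None
    calm = 0
    for idx in indices:
        if boosting is None:
            if idx > engage_threshold:
                boosting = "boost_left"
                calm = 0
                actions.append(boosting)
            elif idx < -engage_threshold:
                boosting = "boost_right"
                calm = 0
                actions.append(boosting)
            else:
                actions.append("none")
        else:
            calm = calm + 1 if abs(idx) < release_threshold else 0
            if calm >= sessions_required:
                boosting = None
                calm = 0
                actions.append("re_equalize")
            else:
                actions.append(boosting)
    return actions


# ---------------------------------------------------------------------------
# record-level scoring (engine-independent re-analysis of saved sessions)
# ---------------------------------------------------------------------------

def outcomes_from_records(session_config: TaskConfig, session) -> list[TrialOutcome]:
    """Re-derive trial outcomes from saved trial records.

    Lick positions are interpolated from the aligned encoder series, so
    this path is independent of the engine's own scoring and usable on
    any session directory in the standard format.
    """
    from .engine import Lick, score_trial

    approach = session_config.epochs[0].name
    decision = session_config.decision_epoch().name if session_config.decision_epoch() else None
    offset = 0.0
    for ep in session_config.epochs:
        if ep.name == decision:
            break
        offset += ep.length_cm or 0.0
    outs: list[TrialOutcome] = []
    for rec in session.trials:
        licks: list[Lick] = []
        enc = np.asarray(rec.encoder_combined, dtype=float)
        t_end = None
        for t, flag_end in zip(rec.timestamps, rec.is_epoch_end):
            if flag_end:
                t_end = t
        for i, t in enumerate(rec.timestamps):
            side = "left" if rec.is_lick_left[i] else ("right" if rec.is_lick_right[i] else None)
            if side is None:
                continue
            pos = None
            # a lick stamped at the same instant as epoch end still belongs
            # to the decision epoch (the end event closes the trial)
            epoch = decision if t >= 0 and (t_end is None or t <= t_end) else approach
            if enc.size:
                aligned = float(np.interp(t, enc[:, 0], enc[:, 1]))
                # undo the negative distance-to-go convention per epoch
                pos = aligned if aligned >= 0 else aligned + offset
            licks.append(Lick(time=t, side=side, epoch=epoch, t_in_epoch=t, position_cm=pos))
        label = score_trial(session_config, rec.trial_type, licks)
        outs.append(
            TrialOutcome(trial_id=rec.trial_id, trial_type=rec.trial_type, label=label, licks=licks)
        )
    return outs
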