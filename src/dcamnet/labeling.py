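"""Binary fatigue labels from behavior and eye tracking.

Two independent schemes are implemented:

* **Reaction-time scheme** (lane-deviation driving sessions).  Each deviation
  event ``i`` has a local reaction time ``LRT(i) = Act(i) - Dep(i)``, a global
  reaction time ``GRT(i)`` (mean LRT over prior events whose onsets fall within
  a 90 s look-back window), and a dataset-level alert threshold
  ``ART = P95{LRT}``.  An event is FATIGUED when both LRT and GRT exceed
  ``2.5 * ART``, ALERT when both are below ``1.5 * ART``, and DISCARDED
  otherwise (ambiguous band, inclusive of the boundaries, and events whose GRT
  is undefined because fewer than two prior events fall in the window).

* **PERCLOS scheme** (eye tracking).  Per 4 s epoch, PERCLOS is the fraction
  of the observable interval (blink + fixation + saccade + closure durations)
  spent with eyes fully closed; FATIGUED iff PERCLOS > 0.5 (strict).

Subjects are retained only if both classes reach a minimum segment count
(default 50 per class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "LabelOutcome",
    "DeviationEvent",
    "SessionEvents",
    "ReactionSummary",
    "EyeEpochDurations",
    "compute_lrt",
    "compute_grt",
    "compute_art",
    "label_rt_event",
    "label_rt_session",
    "filter_retained_subjects",
    "compute_perclos",
    "label_perclos",
]

GRT_WINDOW_S = 90.0
ART_PERCENTILE = 95.0
FATIGUE_FACTOR = 2.5
ALERT_FACTOR = 1.5
MIN_SEGMENTS_PER_CLASS = 50
PERCLOS_THRESHOLD = 0.5


class LabelOutcome(Enum):
    ALERT = 0
    FATIGUED = 1
    DISCARD = -1


@dataclass(frozen=True)
class DeviationEvent:
    """A lane-deviation onset (`dep`) and the first corrective response (`act`)."""

    dep: float
    act: float

    def __post_init__(self) -> None:
        if self.act < self.dep:
            raise ValueError(f"response time {self.act} precedes onset {self.dep}")


@dataclass
class SessionEvents:
    events: list[DeviationEvent] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        deps = [e.dep for e in self.events]
        if any(b <= a for a, b in zip(deps, deps[1:])):
            raise ValueError("deviation onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ReactionSummary:
    lrt: np.ndarray
    grt: np.ndarray  # NaN where undefined
    art: float


@dataclass(frozen=True)
class EyeEpochDurations:
    """Per-epoch eye-tracker totals in seconds (may not cover the full epoch)."""

    t_blink: float
    t_fixation: float
    t_saccade: float
    t_closure: float
    epoch_index: int = 0

    def __post_init__(self) -> None:
        for name in ("t_blink", "t_fixation", "t_saccade", "t_closure"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def t_interval(self) -> float:
        return self.t_blink + self.t_fixation + self.t_saccade + self.t_closure


def compute_lrt(session: SessionEvents) -> np.ndarray:
    """Local reaction time per event: response minus deviation onset."""
    return np.array([e.act - e.dep for e in session.events], dtype=np.float64)


def compute_grt(
    session: SessionEvents,
    lrt: np.ndarray,
    window_s: float = GRT_WINDOW_S,
    min_events: int = 2,
) -> np.ndarray:
    """Global reaction time: mean LRT of prior events within the look-back window.

    ``grt[i]`` averages ``lrt[j]`` over ``j < i`` with
    ``0 <= dep[i] - dep[j] <= window_s``; NaN when fewer than `min_events`
    qualify.
    """
    lrt = np.asarray(lrt, dtype=np.float64)
    if len(lrt) != len(session):
        raise ValueError("lrt not aligned with session events")
    deps = np.array([e.dep for e in session.events])
    grt = np.full(len(session), np.nan)
    for i in range(len(session)):
        mask = (np.arange(len(session)) < i) & (deps[i] - deps >= 0) & (
            deps[i] - deps <= window_s
        )
        if mask.sum() >= min_events:
            grt[i] = lrt[mask].mean()
    return grt


def compute_art(
    all_lrt: np.ndarray | list[float], percentile: float = ART_PERCENTILE
) -> float:
    """Alert reaction-time threshold: percentile of the pooled LRT values.

    Uses the linear-interpolation percentile convention (numpy default).
    """
    all_lrt = np.asarray(all_lrt, dtype=np.float64)
    if all_lrt.size == 0:
        raise ValueError("cannot compute a percentile of an empty LRT list")
    return float(np.percentile(all_lrt, percentile))


def label_rt_event(lrt: float, grt: float, art: float) -> LabelOutcome:
    """Apply the two-threshold reaction-time rule to a single event.

    Boundary values equal to ``1.5*art`` or ``2.5*art`` and undefined GRT both
    fall in DISCARD (strict inequalities on both sides of the rule).
    """
    if art <= 0:
        raise ValueError("art must be positive")
    if grt is None or (isinstance(grt, float) and math.isnan(grt)):
        return LabelOutcome.DISCARD
    if lrt > FATIGUE_FACTOR * art and grt > FATIGUE_FACTOR * art:
        return LabelOutcome.FATIGUED
    if lrt < ALERT_FACTOR * art and grt < ALERT_FACTOR * art:
        return LabelOutcome.ALERT
    return LabelOutcome.DISCARD


def label_rt_session(
    session: SessionEvents, art: float | None = None
) -> tuple[list[LabelOutcome], ReactionSummary]:
    """Full reaction-time labeling pipeline for one session.

    When `art` is None it is computed from this session's own LRTs; pass a
    dataset-level value to follow the pooled-percentile convention.
    """
    lrt = compute_lrt(session)
    grt = compute_grt(session, lrt)
    art_val = compute_art(lrt) if art is None else art
    labels = [label_rt_event(l, g, art_val) for l, g in zip(lrt, grt)]
    return labels, ReactionSummary(lrt, grt, art_val)


def filter_retained_subjects(
    per_subject_counts: dict, min_per_class: int = MIN_SEGMENTS_PER_CLASS
) -> set:
    """Subjects with at least `min_per_class` segments in *both* classes."""
    return {
        subj
        for subj, (n_fat, n_alert) in per_subject_counts.items()
        if n_fat >= min_per_class and n_alert >= min_per_class
    }


def compute_perclos(d: EyeEpochDurations) -> float:
    """Fraction of the observable interval spent in full eye closure.

    Raises when the interval is empty (no eye-tracking coverage); callers must
    drop such epochs as unlabeled.
    """
    interval = d.t_interval
    if interval <= 0:
        raise ValueError(
            f"epoch {d.epoch_index}: zero observable interval, PERCLOS undefined"
        )
    return d.t_closure / interval


def label_perclos(
    perclos: float, threshold: float = PERCLOS_THRESHOLD
) -> LabelOutcome:
    """FATIGUED iff PERCLOS strictly exceeds the threshold, else ALERT."""
    if not 0.0 <= perclos <= 1.0:
        raise ValueError(f"perclos {perclos} outside [0, 1]")
    return LabelOutcome.FATIGUED if perclos > threshold else LabelOutcome.ALERT
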