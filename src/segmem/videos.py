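"""Stimulus (video) specifications.

Each activity video is described by its duration, the latent event-boundary
times a knowledgeable viewer could detect (at a coarse goal grain and a fine
subgoal grain), and the sizes of the outcome instruments attached to it
(recall action-unit inventories, 2AFC trial counts, expertise-survey items).

The two default stimuli mirror the study design this package analyzes: a
gyoza-making video (411 s, 16 coarse / 86 fine action units, 17 scored survey
items) and a Tai chi video (307 s, 19 coarse / 159 fine action units, 16
scored survey items), each tested with 20 recognition and 66 order-memory
2AFC trials.

Latent boundary *times* are never published for the real stimuli, so the
defaults place coarse boundaries at evenly spaced quantiles of the duration
and fine boundaries uniformly between consecutive coarse ones; both layouts
are injectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GYOZA = "gyoza"
TAICHI = "taichi"
ACTIVITIES = (GYOZA, TAICHI)


def quantile_boundaries(duration: float, count: int) -> np.ndarray:
    """Place ``count`` boundaries at the interior quantiles of ``[0, duration]``.

    Boundary k sits at duration * (k+1)/(count+1), so boundaries are strictly
    inside the video and strictly increasing.
    """
    if count <= 0:
        return np.empty(0)
    return duration * (np.arange(1, count + 1) / (count + 1))


def interleaved_fine_boundaries(
    duration: float, coarse: np.ndarray, count: int
) -> np.ndarray:
    """Spread ``count`` fine boundaries evenly across the coarse segments.

    Each gap between consecutive coarse boundaries (including the video edges)
    receives its proportional share of fine boundaries, placed at the gap's
    interior quantiles. Deterministic, strictly increasing, and disjoint from
    the coarse times.
    """
    if count <= 0:
        return np.empty(0)
    edges = np.concatenate([[0.0], np.asarray(coarse, dtype=float), [duration]])
    widths = np.diff(edges)
    # proportional allocation, largest-remainder rounding
    raw = count * widths / widths.sum()
    alloc = np.floor(raw).astype(int)
    remainder = count - alloc.sum()
    if remainder > 0:
        order = np.argsort(-(raw - alloc))
        alloc[order[:remainder]] += 1
    out: list[float] = []
    for lo, hi, k in zip(edges[:-1], edges[1:], alloc):
        if k > 0:
            out.extend(lo + (hi - lo) * (np.arange(1, k + 1) / (k + 1)))
    return np.asarray(sorted(out))


@dataclass(frozen=True)
class VideoSpec:
    """One activity video and the measurement instruments attached to it.

    Attributes
    ----------
    activity:
        Label, one of ``"gyoza"`` / ``"taichi"`` for the default stimuli.
    duration:
        Video length in seconds.
    coarse_boundaries, fine_boundaries:
        Latent event-boundary times (seconds), strictly increasing, all in
        ``[0, duration]``. Coarse boundaries correspond to goal-level (A2)
        transitions, fine ones to subgoal-level (A1) transitions.
    a1_count, a2_count:
        Number of fine (A1) and coarse (A2) action units in the recall
        coding inventory.
    n_recognition_trials, n_order_trials, n_survey_items:
        Instrument sizes for the 2AFC tasks and the scored expertise survey.
    """

    activity: str
    duration: float
    coarse_boundaries: np.ndarray
    fine_boundaries: np.ndarray
    a1_count: int
    a2_count: int
    n_recognition_trials: int = 20
    n_order_trials: int = 66
    n_survey_items: int = 16

    def __post_init__(self) -> None:
        for name in ("coarse_boundaries", "fine_boundaries"):
            b = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, b)
            if b.size:
                if np.any(b < 0) or np.any(b > self.duration):
                    raise ValueError(f"{name} outside [0, {self.duration}]")
                if np.any(np.diff(b) <= 0):
                    raise ValueError(f"{name} must be strictly increasing")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def all_boundaries(self) -> np.ndarray:
        return np.sort(np.concatenate([self.coarse_boundaries, self.fine_boundaries]))


def default_video(activity: str) -> VideoSpec:
    """Default stimulus spec for ``"gyoza"`` or ``"taichi"``."""
    if activity == GYOZA:
        duration, a1, a2, items = 411.0, 86, 16, 17
    elif activity == TAICHI:
        duration, a1, a2, items = 307.0, 159, 19, 16
    else:
        raise ValueError(f"unknown activity {activity!r}")
    coarse = quantile_boundaries(duration, a2)
    fine = interleaved_fine_boundaries(duration, coarse, a1)
    return VideoSpec(
        activity=activity,
        duration=duration,
        coarse_boundaries=coarse,
        fine_boundaries=fine,
        a1_count=a1,
        a2_count=a2,
        n_survey_items=items,
    )


def default_videos() -> dict[str, VideoSpec]:
    return {a: default_video(a) for a in ACTIVITIES}
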