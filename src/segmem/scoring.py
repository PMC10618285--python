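"""Deterministic scoring of the non-segmentation outcomes.

Every graded outcome is reduced to an :class:`OutcomeRecord` — successes,
trials and their proportion — where ``trials`` doubles as the weight handed
to the binomial models downstream (survey 16/17 items, recognition 20
trials, order 66 trials, recall all coded action units).

Also here: the novice-eligibility screen (at most 10 correct on each
activity's expertise survey), Cohen's kappa for inter-rater reliability of
the recall coding, and the semantic-fluency unique-item count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

SURVEY_ITEMS = {"gyoza": 17, "taichi": 16}
RECOGNITION_TRIALS = 20
ORDER_TRIALS = 66
RECALL_TOTALS = {"gyoza": {"A1": 86, "A2": 16}, "taichi": {"A1": 159, "A2": 19}}
NOVICE_CUTOFF = 10  # eligible iff correct <= 10 on each activity's survey


@dataclass(frozen=True)
class RecallCoding:
    """Coded free-recall unit counts for one participant x session x activity."""

    participant: str
    session: str
    activity: str
    a1_recalled: int
    a1_total: int
    a2_recalled: int
    a2_total: int

    def __post_init__(self) -> None:
        for recalled, total, grain in (
            (self.a1_recalled, self.a1_total, "A1"),
            (self.a2_recalled, self.a2_total, "A2"),
        ):
            if total <= 0:
                raise ValueError(f"{grain} total must be positive")
            if not 0 <= recalled <= total:
                raise ValueError(f"{grain} recalled must be in [0, total]")


@dataclass(frozen=True)
class OutcomeRecord:
    """One scored outcome cell: successes out of ``trials`` (the model weight)."""

    participant: str
    session: str
    activity: str
    outcome: str
    successes: int
    trials: int

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


def survey_score(
    responses: Sequence[int] | np.ndarray,
    n_items: int,
    *,
    participant: str = "",
    session: str = "",
    activity: str = "",
) -> OutcomeRecord:
    """Proportion correct on the scored expertise survey, weight = item count.

    The three qualitative items per activity are removed upstream at ingest;
    the scorer only ever sees the 16 (Tai chi) or 17 (gyoza) scored items.
    """
    responses = np.asarray(responses, dtype=int)
    if responses.size != n_items:
        raise ValueError(f"expected {n_items} responses, got {responses.size}")
    return OutcomeRecord(
        participant, session, activity, "survey",
        successes=int(responses.sum()), trials=int(n_items),
    )


def screen_novice(correct_counts: dict[str, int], cutoff: int = NOVICE_CUTOFF) -> bool:
    """Eligibility: at most ``cutoff`` correct on *each* activity's survey.

    Scoring strictly above the cutoff on either activity marks the person too
    knowledgeable to enrol.
    """
    return all(count <= cutoff for count in correct_counts.values())


def recall_composite(coding: RecallCoding) -> OutcomeRecord:
    """Composite recall: mean of the A1 and A2 recalled proportions.

    The record's weight is the total number of coded units (A1 + A2) and the
    success count is the composite proportion times that weight, rounded to
    the nearest integer — preserving all coded information while keeping the
    successes/trials representation exact under CSV round-trips.
    """
    p1 = coding.a1_recalled / coding.a1_total
    p2 = coding.a2_recalled / coding.a2_total
    composite = (p1 + p2) / 2.0
    trials = coding.a1_total + coding.a2_total
    return OutcomeRecord(
        coding.participant, coding.session, coding.activity, "recall",
        successes=int(round(composite * trials)), trials=trials,
    )


def recall_composite_proportion(coding: RecallCoding) -> float:
    """Exact (unrounded) composite recall proportion."""
    return (coding.a1_recalled / coding.a1_total + coding.a2_recalled / coding.a2_total) / 2.0


def twoafc_score(
    correct: Sequence[int] | np.ndarray,
    task: str,
    *,
    participant: str = "",
    session: str = "",
    activity: str = "",
) -> OutcomeRecord:
    """Proportion correct on a 2AFC task (recognition: 20 trials; order: 66)."""
    expected = {"recognition": RECOGNITION_TRIALS, "order": ORDER_TRIALS}
    if task not in expected:
        raise ValueError(f"unknown 2AFC task {task!r}")
    correct = np.asarray(correct, dtype=int)
    if correct.size != expected[task]:
        raise ValueError(
            f"{task} expects {expected[task]} trials, got {correct.size}"
        )
    return OutcomeRecord(
        participant, session, activity, task,
        successes=int(correct.sum()), trials=int(expected[task]),
    )


def cohen_kappa(rater_a: Sequence[int], rater_b: Sequence[int]) -> float:
    """Cohen's kappa between two aligned binary coding vectors.

    Chance agreement uses the product of the raters' marginals. When both
    raters are constant and identical the statistic is undefined (observed
    and chance agreement are both 1) and a ``ValueError`` is raised rather
    than returning a silent 0 or NaN.
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("raters must be equal-length non-empty 1-D vectors")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise ValueError("kappa undefined: both raters constant and identical")
    return float(cohen_kappa_score(a, b))


def fluency_unique_count(typed_items: Iterable[str]) -> int:
    """Unique items after case-folding and whitespace trimming."""
    normalized = {item.strip().casefold() for item in typed_items}
    normalized.discard("")
    return len(normalized)


# ---------------------------------------------------------------------------
# Table-level scoring


def score_dataset(
    survey: pd.DataFrame, trials: pd.DataFrame, recall: pd.DataFrame
) -> pd.DataFrame:
    """Score all outcome tables into one long outcomes table.

    Columns: participant, session, activity, outcome, successes, trials,
    proportion. Recall totals are validated against the fixed action-unit
    inventories.
    """
    records: list[OutcomeRecord] = []
    for (pid, session, activity), sub in survey.groupby(
        ["participant", "session", "activity"], sort=False
    ):
        records.append(
            survey_score(
                sub["correct"].to_numpy(), SURVEY_ITEMS[activity],
                participant=pid, session=session, activity=activity,
            )
        )
    for (pid, session, activity, task), sub in trials.groupby(
        ["participant", "session", "activity", "task"], sort=False
    ):
        records.append(
            twoafc_score(
                sub["correct"].to_numpy(), task,
                participant=pid, session=session, activity=activity,
            )
        )
    for (pid, session, activity), sub in recall.groupby(
        ["participant", "session", "activity"], sort=False
    ):
        by_grain = sub.set_index("grain")
        coding = RecallCoding(
            participant=pid, session=session, activity=activity,
            a1_recalled=int(by_grain.loc["A1", "n_recalled"]),
            a1_total=int(by_grain.loc["A1", "n_total"]),
            a2_recalled=int(by_grain.loc["A2", "n_recalled"]),
            a2_total=int(by_grain.loc["A2", "n_total"]),
        )
        expected = RECALL_TOTALS.get(activity)
        if expected is not None and (
            coding.a1_total != expected["A1"] or coding.a2_total != expected["A2"]
        ):
            raise ValueError(
                f"recall totals for {activity!r} do not match the coding inventory"
            )
        records.append(recall_composite(coding))
    out = pd.DataFrame([r.__dict__ for r in records])
    out["proportion"] = out["successes"] / out["trials"]
    return out
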