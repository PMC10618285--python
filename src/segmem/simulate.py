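"""Synthetic pre/post intervention studies.

Generates complete datasets with the structure the downstream analysis
assumes: 80 older-adult novices (38 gyoza-trained, 42 Tai-chi-trained) each
measured at pre- and post-test on both activities, with a press-log
segmentation task, an expertise survey, recognition and order-memory 2AFC
trials, and A1/A2 free-recall unit counts.

The generative model
--------------------
*Segmentation* is a latent point process: each latent boundary of the video
is detected independently (separate detection probabilities for coarse and
fine boundaries), detected presses are displaced by Gaussian motor/decision
jitter and clipped to the video, and a homogeneous Poisson process adds
false-alarm presses.

*Graded outcomes* (survey, recognition, order, recall) are Bernoulli /
binomial draws whose logits combine an activity baseline, a practice effect
at post-test, an extra trained-activity increment at post-test (the
intervention effect proper), optional explicitly coded contrast effects, a
participant random intercept, and a participant random time slope. The two
recall grains (A1 fine units, A2 coarse units) share one latent recall
propensity per participant x session x activity, which is what makes the two
recalled proportions strongly correlated across participants.

Default parameter values are calibrated so that cell means land near the
marginal means the study design targets (e.g. trained-activity survey
accuracy rising from ~0.2 to ~0.8, recognition around 0.73-0.95, order
memory 0.55/0.92, segmentation counts ~13 for gyoza and ~20-26 for Tai chi).

Reproducibility: every participant draws from a counter-based substream
keyed by ``(master_seed, participant_index, stage)``, so a fixed master seed
gives bit-identical datasets and adding participants never reshuffles
existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .videos import ACTIVITIES, GYOZA, TAICHI, VideoSpec, default_videos

PRE, POST = "pre", "post"
SESSIONS = (PRE, POST)

# Sum-to-zero contrast codes (first level +1): group gyoza=+1, time pre=+1,
# activity gyoza=+1. Shared with the models module.
def contrast_code(group: str, session: str, activity: str) -> tuple[int, int, int]:
    g = 1 if group == GYOZA else -1
    t = 1 if session == PRE else -1
    a = 1 if activity == GYOZA else -1
    return g, t, a


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class OutcomeParams:
    """Generative parameters for one Bernoulli/binomial outcome.

    ``baseline_logit`` maps activity -> pre-test logit; ``time_effect`` is the
    practice gain (logits) every activity receives at post-test;
    ``training_effect`` maps activity -> the extra post-test gain when that
    activity was the trained one. ``coded_effects`` adds terms of the form
    beta * (product of +-1 contrast codes), keyed by subsets of
    ``{"group","time","activity"}`` joined with ``:`` — this is how simulation
    studies inject an exact Group x Time x Activity coefficient.
    """

    baseline_logit: dict[str, float]
    time_effect: float = 0.0
    training_effect: dict[str, float] = field(default_factory=dict)
    coded_effects: dict[str, float] = field(default_factory=dict)
    participant_sd: float = 0.0
    time_slope_sd: float = 0.0

    def linear_predictor(self, group: str, session: str, activity: str) -> float:
        eta = self.baseline_logit[activity]
        if session == POST:
            eta += self.time_effect
            if group == activity:  # trained activity
                eta += self.training_effect.get(activity, 0.0)
        g, t, a = contrast_code(group, session, activity)
        codes = {"group": g, "time": t, "activity": a}
        for term, beta in self.coded_effects.items():
            prod = 1
            for factor in term.split(":"):
                prod *= codes[factor]
            eta += beta * prod
        return eta


@dataclass
class RecallParams(OutcomeParams):
    """Recall shares the outcome logit machinery plus grain structure.

    ``grain_offset_a2`` shifts the (easier) coarse-unit logit; ``grain_noise_sd``
    is grain-specific noise around the shared latent propensity — smaller
    values give a higher A1/A2 correlation.
    """

    grain_offset_a2: float = 0.3
    grain_noise_sd: float = 0.25


@dataclass
class SegmentationParams:
    """Latent point-process parameters for the press-log generator."""

    detection_coarse: dict[str, float] = field(
        default_factory=lambda: {GYOZA: 0.60, TAICHI: 0.75}
    )
    detection_fine: dict[str, float] = field(
        default_factory=lambda: {GYOZA: 0.02, TAICHI: 0.05}
    )
    jitter_sd: float = 1.0  # seconds
    false_alarm_rate: float = 0.005  # presses per second
    # trained-activity post-test shifts (logit scale for detection; multiplicative
    # for jitter/false alarms). Defaults are null: the study design found the
    # intervention's effects concentrated in survey/recognition, not segmentation.
    training_detection_delta: float = 0.0
    training_jitter_scale: float = 1.0
    training_false_alarm_scale: float = 1.0
    # between-participant heterogeneity
    detection_logit_sd: float = 0.5
    jitter_log_sd: float = 0.3
    false_alarm_log_sd: float = 0.5


def _default_outcomes() -> dict[str, OutcomeParams]:
    return {
        "survey": OutcomeParams(
            baseline_logit={GYOZA: _logit(0.07), TAICHI: _logit(0.22)},
            time_effect=1.0,
            training_effect={GYOZA: 2.43, TAICHI: 1.78},
            participant_sd=0.4,
            time_slope_sd=0.3,
        ),
        "recognition": OutcomeParams(
            baseline_logit={GYOZA: _logit(0.75), TAICHI: _logit(0.81)},
            time_effect=0.3,
            training_effect={GYOZA: 0.2, TAICHI: 1.2},
            participant_sd=0.4,
            time_slope_sd=0.2,
        ),
        "order": OutcomeParams(
            baseline_logit={GYOZA: _logit(0.92), TAICHI: _logit(0.55)},
            time_effect=0.1,
            participant_sd=0.5,
            time_slope_sd=0.1,
        ),
        "recall": RecallParams(
            baseline_logit={GYOZA: _logit(0.17), TAICHI: _logit(0.05)},
            time_effect=-0.15,
            training_effect={GYOZA: 0.25, TAICHI: 0.25},
            participant_sd=0.7,
            time_slope_sd=0.2,
            grain_noise_sd=0.15,
        ),
    }


@dataclass
class SimConfig:
    """Full study configuration.

    ``group_sizes`` maps trained activity -> number of participants
    (defaults 38 gyoza-trained, 42 Tai-chi-trained). ``counterbalance``
    flips each participant's video order between sessions; ``practice_gate``
    enforces the >= 3 presses rule on the practice-stimulus analogue (off for
    experimental videos).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {GYOZA: 38, TAICHI: 42}
    )
    outcomes: dict[str, OutcomeParams] = field(default_factory=_default_outcomes)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    seed: int = 0
    counterbalance: bool = True
    practice_gate: bool = False

    def __post_init__(self) -> None:
        for activity, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group size for {activity!r} must be positive")

    def null(self) -> "SimConfig":
        """Copy with every systematic effect removed (time, training, coded)."""
        outcomes = {}
        for name, p in self.outcomes.items():
            outcomes[name] = replace(
                p, time_effect=0.0, training_effect={}, coded_effects={}
            )
        return replace(self, outcomes=outcomes)


@dataclass
class ParticipantState:
    """Latent per-participant state driving every simulated measure."""

    participant: str
    index: int
    group: str  # trained activity
    knowledge: dict[tuple[str, str], float]  # (activity, session) -> level
    detection: dict[str, tuple[float, float]]  # activity -> (coarse, fine)
    jitter_sd: float
    false_alarm_rate: float
    random_intercepts: dict[str, float]  # outcome -> b_i
    time_slopes: dict[str, float]  # outcome -> u_i (added at post)

    def __post_init__(self) -> None:
        for ps in self.detection.values():
            if not all(0.0 <= p <= 1.0 for p in ps):
                raise ValueError("detection probabilities must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter SD must be non-negative")
        if self.false_alarm_rate < 0:
            raise ValueError("false-alarm rate must be non-negative")
        for activity in ACTIVITIES:
            if self.knowledge[(activity, POST)] < self.knowledge[(activity, PRE)]:
                if activity == self.group:
                    raise ValueError(
                        "knowledge must be non-decreasing for the trained activity"
                    )


@dataclass
class StudyDataset:
    """All tables of one (simulated or ingested) study."""

    design: pd.DataFrame  # participant, group, pre_first, post_first
    presses: pd.DataFrame  # participant, session, activity, press_time
    survey: pd.DataFrame  # participant, session, activity, item, correct
    trials: pd.DataFrame  # participant, session, activity, task, trial, correct
    recall: pd.DataFrame  # participant, session, activity, grain, n_recalled, n_total
    videos: dict[str, VideoSpec] = field(default_factory=default_videos)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "design": self.design,
            "presses": self.presses,
            "survey": self.survey,
            "trials": self.trials,
            "recall": self.recall,
        }


# ---------------------------------------------------------------------------
# RNG plumbing


def participant_rng(seed: int, index: int, stage: int) -> np.random.Generator:
    """Substream for one participant and stage, stable under cohort growth."""
    return np.random.default_rng(np.random.SeedSequence((seed, index, stage)))


_STAGE_TRAITS = 0
_STAGE_PRESS = 1
_STAGE_SURVEY = 2
_STAGE_TRIALS = 3
_STAGE_DESIGN = 4


# ---------------------------------------------------------------------------
# Design


def generate_design(config: SimConfig) -> pd.DataFrame:
    """Assign groups and counterbalanced video orders.

    Participants are labelled ``p001``... in a fixed order; group labels are
    assigned by a seeded permutation (random assignment with fixed group
    totals). Within each group, first-video order at pre-test alternates; with
    counterbalancing on, the post-test order is the reverse of the pre-test
    order for every participant.
    """
    n_total = sum(config.group_sizes.values())
    labels = np.repeat(
        list(config.group_sizes.keys()), list(config.group_sizes.values())
    )
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _STAGE_DESIGN)))
    labels = rng.permutation(labels)
    rows = []
    seen_in_group: dict[str, int] = {g: 0 for g in config.group_sizes}
    for i in range(n_total):
        group = labels[i]
        k = seen_in_group[group]
        seen_in_group[group] += 1
        pre_first = ACTIVITIES[k % 2]
        if config.counterbalance:
            post_first = ACTIVITIES[(k + 1) % 2]
        else:
            post_first = pre_first
        rows.append(
            {
                "participant": f"p{i + 1:03d}",
                "group": group,
                "pre_first": pre_first,
                "post_first": post_first,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Participant state


def draw_participant_state(
    config: SimConfig, participant: str, index: int, group: str
) -> ParticipantState:
    rng = participant_rng(config.seed, index, _STAGE_TRAITS)
    seg = config.segmentation
    detection: dict[str, tuple[float, float]] = {}
    shift = rng.normal(0.0, seg.detection_logit_sd)
    for activity in ACTIVITIES:
        coarse = _invlogit(_logit_clip(seg.detection_coarse[activity]) + shift)
        fine = _invlogit(_logit_clip(seg.detection_fine[activity]) + shift)
        detection[activity] = (float(coarse), float(fine))
    jitter = seg.jitter_sd * float(np.exp(rng.normal(0.0, seg.jitter_log_sd)))
    fa = seg.false_alarm_rate * float(np.exp(rng.normal(0.0, seg.false_alarm_log_sd)))
    knowledge = {}
    for activity in ACTIVITIES:
        knowledge[(activity, PRE)] = 0.0
        knowledge[(activity, POST)] = 1.0 if activity == group else 0.0
    intercepts = {
        name: float(rng.normal(0.0, p.participant_sd))
        for name, p in config.outcomes.items()
    }
    slopes = {
        name: float(rng.normal(0.0, p.time_slope_sd))
        for name, p in config.outcomes.items()
    }
    return ParticipantState(
        participant=participant,
        index=index,
        group=group,
        knowledge=knowledge,
        detection=detection,
        jitter_sd=jitter,
        false_alarm_rate=fa,
        random_intercepts=intercepts,
        time_slopes=slopes,
    )


def _logit_clip(p: float) -> float:
    return _logit(min(max(p, 1e-9), 1.0 - 1e-9))


# ---------------------------------------------------------------------------
# Press logs


def simulate_press_log(
    state: ParticipantState,
    video: VideoSpec,
    rng: np.random.Generator,
    *,
    session: str = PRE,
    config: SimConfig | None = None,
    gate: bool = False,
) -> np.ndarray:
    """One press log: detected latent boundaries + jitter + false alarms.

    Detected boundary times are displaced by N(0, jitter_sd) and clipped to
    ``[0, duration]`` (truncation, not redraw, so boundary-adjacent detections
    are not biased inward). False alarms are a homogeneous Poisson process.
    With ``gate=True`` the draw is repeated until it has >= 3 presses — the
    practice-stimulus rule; experimental videos leave it off, so empty logs
    are legal output.
    """
    seg = config.segmentation if config is not None else SegmentationParams()
    trained_post = session == POST and state.group == video.activity
    coarse_p, fine_p = state.detection[video.activity]
    jitter = state.jitter_sd
    fa_rate = state.false_alarm_rate
    if trained_post:
        coarse_p = _invlogit(_logit_clip(coarse_p) + seg.training_detection_delta)
        fine_p = _invlogit(_logit_clip(fine_p) + seg.training_detection_delta)
        jitter = jitter * seg.training_jitter_scale
        fa_rate = fa_rate * seg.training_false_alarm_scale
    while True:
        hits = []
        for boundaries, p in (
            (video.coarse_boundaries, coarse_p),
            (video.fine_boundaries, fine_p),
        ):
            if boundaries.size and p > 0:
                detected = boundaries[rng.random(boundaries.size) < p]
                if detected.size:
                    hits.append(detected + rng.normal(0.0, jitter, detected.size)
                                if jitter > 0 else detected)
        n_fa = rng.poisson(fa_rate * video.duration)
        if n_fa:
            hits.append(rng.uniform(0.0, video.duration, n_fa))
        presses = (
            np.sort(np.clip(np.concatenate(hits), 0.0, video.duration))
            if hits
            else np.empty(0)
        )
        if not gate or presses.size >= 3:
            return presses


# ---------------------------------------------------------------------------
# Graded outcomes


def _outcome_logit(
    params: OutcomeParams, state: ParticipantState, session: str, activity: str
) -> float:
    eta = params.linear_predictor(state.group, session, activity)
    eta += state.random_intercepts.get(_params_key(params), 0.0)
    if session == POST:
        eta += state.time_slopes.get(_params_key(params), 0.0)
    return eta


def _params_key(params: OutcomeParams) -> str:
    # OutcomeParams instances are stored under their outcome name in SimConfig;
    # the key is attached lazily by simulate_study. Falls back to class-based
    # lookup for direct calls.
    return getattr(params, "_name", "")


def simulate_survey(
    params: OutcomeParams,
    state: ParticipantState,
    video: VideoSpec,
    rng: np.random.Generator,
    session: str,
) -> pd.DataFrame:
    """Item-level Bernoulli survey responses for one cell."""
    if video.n_survey_items <= 0:
        raise ValueError("n_survey_items must be positive")
    p = _invlogit(_outcome_logit(params, state, session, video.activity))
    correct = (rng.random(video.n_survey_items) < p).astype(int)
    return pd.DataFrame(
        {
            "participant": state.participant,
            "session": session,
            "activity": video.activity,
            "item": np.arange(1, video.n_survey_items + 1),
            "correct": correct,
        }
    )


def simulate_memory_trials(
    config: SimConfig,
    state: ParticipantState,
    video: VideoSpec,
    rng: np.random.Generator,
    session: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2AFC recognition/order trials plus A1/A2 recall-unit counts."""
    frames = []
    for task, n_trials, pname in (
        ("recognition", video.n_recognition_trials, "recognition"),
        ("order", video.n_order_trials, "order"),
    ):
        p = _invlogit(_outcome_logit(config.outcomes[pname], state, session, video.activity))
        correct = (rng.random(n_trials) < p).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "participant": state.participant,
                    "session": session,
                    "activity": video.activity,
                    "task": task,
                    "trial": np.arange(1, n_trials + 1),
                    "correct": correct,
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)

    rp = config.outcomes["recall"]
    eta = _outcome_logit(rp, state, session, video.activity)
    grain_offset = getattr(rp, "grain_offset_a2", 0.0)
    grain_sd = getattr(rp, "grain_noise_sd", 0.0)
    p_a1 = _invlogit(eta + (rng.normal(0.0, grain_sd) if grain_sd > 0 else 0.0))
    p_a2 = _invlogit(
        eta + grain_offset + (rng.normal(0.0, grain_sd) if grain_sd > 0 else 0.0)
    )
    recall = pd.DataFrame(
        {
            "participant": state.participant,
            "session": session,
            "activity": video.activity,
            "grain": ["A1", "A2"],
            "n_recalled": [
                int(rng.binomial(video.a1_count, p_a1)),
                int(rng.binomial(video.a2_count, p_a2)),
            ],
            "n_total": [video.a1_count, video.a2_count],
        }
    )
    return trials, recall


# ---------------------------------------------------------------------------
# Whole study


def simulate_study(config: SimConfig, videos: dict[str, VideoSpec] | None = None) -> StudyDataset:
    """Simulate the complete pre/post x two-activity study.

    Every participant contributes both sessions x both activities for every
    measure; per-participant substreams make the output reproducible from the
    master seed alone.
    """
    videos = videos or default_videos()
    for name, params in config.outcomes.items():
        params._name = name  # used by _outcome_logit for random-effect lookup
    design = generate_design(config)
    press_rows, survey_frames, trial_frames, recall_frames = [], [], [], []
    for index, row in design.iterrows():
        state = draw_participant_state(config, row["participant"], int(index), row["group"])
        rng_press = participant_rng(config.seed, int(index), _STAGE_PRESS)
        rng_survey = participant_rng(config.seed, int(index), _STAGE_SURVEY)
        rng_trials = participant_rng(config.seed, int(index), _STAGE_TRIALS)
        for session in SESSIONS:
            first = row["pre_first"] if session == PRE else row["post_first"]
            ordered = (first, *(a for a in ACTIVITIES if a != first))
            for activity in ordered:
                video = videos[activity]
                presses = simulate_press_log(
                    state, video, rng_press,
                    session=session, config=config, gate=config.practice_gate,
                )
                for t in presses:
                    press_rows.append(
                        {
                            "participant": state.participant,
                            "session": session,
                            "activity": activity,
                            "press_time": float(t),
                        }
                    )
                survey_frames.append(
                    simulate_survey(
                        config.outcomes["survey"], state, video, rng_survey, session
                    )
                )
                trials, recall = simulate_memory_trials(
                    config, state, video, rng_trials, session
                )
                trial_frames.append(trials)
                recall_frames.append(recall)
    presses = pd.DataFrame(
        press_rows, columns=["participant", "session", "activity", "press_time"]
    )
    return StudyDataset(
        design=design,
        presses=presses,
        survey=pd.concat(survey_frames, ignore_index=True),
        trials=pd.concat(trial_frames, ignore_index=True),
        recall=pd.concat(recall_frames, ignore_index=True),
        videos=videos,
    )
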