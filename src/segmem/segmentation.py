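"""Boundary profiles and leave-one-out segmentation agreement.

A participant's press log is smoothed into a *boundary profile*: a curve on a
uniform time grid giving, at each sample, a 0-1 likelihood that the
participant perceived an event boundary there. Each press contributes a
Gaussian bump (default SD 1 s) with support truncated at a configurable
radius (default 3 SDs); overlapping bumps sum and the curve is clipped at 1,
so an isolated press peaks at exactly 1 at the press time.

*Normative* boundaries are the element-wise mean profile of a designated
reference group — here, the activity's trained ("knowledgeable") group at
post-test. *Segmentation agreement* is the Pearson correlation between an
individual's profile and the normative profile, computed leave-one-out:
whenever the individual belongs to the reference group, their own post-test
profile is removed from the norm before correlating (for both their pre- and
post-test comparisons, so a person's stable pressing style never correlates
with itself).

Degenerate profiles (no presses, or a constant curve) make the correlation
undefined; such scores carry an explicit status instead of a number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import POST, SESSIONS, StudyDataset
from .videos import VideoSpec

STATUS_OK = "ok"
STATUS_UNDEFINED_OWNER = "undefined_owner"
STATUS_UNDEFINED_REFERENCE = "undefined_reference"


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian smoothing kernel for press logs.

    bandwidth: kernel SD in seconds (the "one-second" kernel is SD = 1, not
    FWHM; configurable because the bandwidth convention is not universal).
    truncation_radius: kernel support half-width in SDs; contributions are
    exactly zero at and beyond this many SDs from a press.
    sampling_rate: profile grid density in samples/second. Results are
    insensitive above ~5/s for a 1 s bandwidth.
    overlap: "sum" adds overlapping kernels and clips the curve at 1 (the
    default); "max" takes the pointwise maximum instead (sensitivity
    analysis).
    """

    bandwidth: float = 1.0
    truncation_radius: float = 3.0
    sampling_rate: float = 10.0
    overlap: str = "sum"

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.truncation_radius < 1:
            raise ValueError("truncation radius must be >= 1 SD")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.overlap not in ("sum", "max"):
            raise ValueError("overlap must be 'sum' or 'max'")


@dataclass
class BoundaryProfile:
    """Smoothed boundary-likelihood curve for one participant x session x activity."""

    participant: str
    session: str
    activity: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")


@dataclass
class AgreementScore:
    """Leave-one-out agreement of one profile with the normative profile."""

    participant: str
    session: str
    activity: str
    r: float | None
    n_reference_used: int
    status: str = STATUS_OK


def profile_grid(duration: float, kernel: KernelSpec) -> np.ndarray:
    """Uniform sample grid over [0, duration]: floor(duration*rate)+1 points."""
    n = int(np.floor(duration * kernel.sampling_rate)) + 1
    return np.arange(n) / kernel.sampling_rate


def boundary_profile(
    press_log: np.ndarray,
    video: VideoSpec,
    kernel: KernelSpec = KernelSpec(),
    *,
    participant: str = "",
    session: str = "",
) -> BoundaryProfile:
    """Smooth one press log into a boundary profile.

    Value at grid time t is ``min(1, sum_p exp(-(t-p)^2 / 2 sigma^2))`` with
    terms zeroed for ``|t-p| >= truncation_radius * sigma``. An empty press
    log yields the all-zero profile. Presses outside ``[0, duration]`` are
    rejected.
    """
    presses = np.asarray(press_log, dtype=float).ravel()
    if presses.size:
        bad = presses[(presses < 0) | (presses > video.duration)]
        if bad.size:
            raise ValueError(
                f"presses outside [0, {video.duration}]: {bad.tolist()}"
            )
    times = profile_grid(video.duration, kernel)
    values = np.zeros_like(times)
    sigma = kernel.bandwidth
    radius = kernel.truncation_radius * sigma
    rate = kernel.sampling_rate
    for p in presses:
        # windowed evaluation: only grid points strictly inside the support
        lo = int(np.ceil((p - radius) * rate))
        hi = int(np.floor((p + radius) * rate))
        lo = max(lo, 0)
        hi = min(hi, times.size - 1)
        if hi < lo:
            continue
        window = times[lo : hi + 1]
        term = np.exp(-((window - p) ** 2) / (2.0 * sigma**2))
        term[np.abs(window - p) >= radius] = 0.0
        if kernel.overlap == "sum":
            values[lo : hi + 1] += term
        else:
            np.maximum(values[lo : hi + 1], term, out=values[lo : hi + 1])
    if kernel.overlap == "sum":
        np.minimum(values, 1.0, out=values)
    return BoundaryProfile(
        participant=participant, session=session, activity=video.activity,
        times=times, values=values,
    )


def normative_profile(
    profiles: Iterable[BoundaryProfile], exclude_owner: str | None = None
) -> BoundaryProfile:
    """Element-wise mean of the included profiles (the normative boundaries)."""
    included = [
        p for p in profiles if exclude_owner is None or p.participant != exclude_owner
    ]
    if not included:
        raise ValueError("no profiles remain after exclusion")
    first = included[0]
    for p in included[1:]:
        if p.times.shape != first.times.shape or not np.allclose(p.times, first.times):
            raise ValueError("profiles must share the same sample grid")
    values = np.mean([p.values for p in included], axis=0)
    return BoundaryProfile(
        participant="<normative>",
        session=first.session,
        activity=first.activity,
        times=first.times.copy(),
        values=values,
    )


def segmentation_count(press_log: np.ndarray) -> int:
    """Raw number of presses; no debouncing."""
    return int(np.asarray(press_log).ravel().size)


def agreement(
    owner_profile: BoundaryProfile,
    reference_profiles: Iterable[BoundaryProfile],
    *,
    method: str = "pearson",
) -> AgreementScore:
    """Correlate one profile with the leave-one-out normative profile.

    The reference set is the trained group's post-test profiles for the
    activity; the owner's own post-test profile is excluded whenever present.
    Returns an undefined status (and no ``r``) when either curve has zero
    variance.
    """
    reference = list(reference_profiles)
    norm = normative_profile(reference, exclude_owner=owner_profile.participant)
    n_used = _count_reference(reference, owner_profile.participant)
    return _correlate(owner_profile, norm, n_used, method=method)


def _count_reference(profiles: Iterable[BoundaryProfile], owner: str) -> int:
    return sum(1 for p in profiles if p.participant != owner)


def _correlate(
    owner: BoundaryProfile, norm: BoundaryProfile, n_used: int, method: str = "pearson"
) -> AgreementScore:
    x = owner.values
    y = norm.values
    if x.shape != y.shape:
        raise ValueError("owner and normative profiles must share the grid")
    if np.ptp(x) == 0.0:
        status, r = STATUS_UNDEFINED_OWNER, None
    elif np.ptp(y) == 0.0:
        status, r = STATUS_UNDEFINED_REFERENCE, None
    else:
        if method == "pearson":
            r = float(stats.pearsonr(x, y).statistic)
        elif method == "spearman":
            r = float(stats.spearmanr(x, y).statistic)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        status = STATUS_OK
    return AgreementScore(
        participant=owner.participant,
        session=owner.session,
        activity=owner.activity,
        r=r,
        n_reference_used=n_used,
        status=status,
    )


def _press_lookup(presses: pd.DataFrame) -> dict[tuple[str, str, str], np.ndarray]:
    lookup: dict[tuple[str, str, str], np.ndarray] = {}
    for key, sub in presses.groupby(["participant", "session", "activity"], sort=False):
        lookup[tuple(key)] = np.sort(sub["press_time"].to_numpy(dtype=float))
    return lookup


def compute_all_agreements(
    dataset: StudyDataset,
    kernel: KernelSpec = KernelSpec(),
    *,
    method: str = "pearson",
) -> pd.DataFrame:
    """Agreement table: one row per participant x session x activity.

    For each activity the reference set is that activity's trained group at
    post-test; reference members are scored against the norm with their own
    post-test profile left out (at both sessions). Columns: participant,
    session, activity, count, r, status, n_reference. Rows whose correlation
    is undefined keep their status and carry a missing ``r``.
    """
    lookup = _press_lookup(dataset.presses)
    participants = dataset.design["participant"].tolist()
    groups = dict(zip(dataset.design["participant"], dataset.design["group"]))

    profiles: dict[tuple[str, str, str], BoundaryProfile] = {}
    for pid in participants:
        for session in SESSIONS:
            for activity, video in dataset.videos.items():
                log = lookup.get((pid, session, activity), np.empty(0))
                profiles[(pid, session, activity)] = boundary_profile(
                    log, video, kernel, participant=pid, session=session
                )

    rows = []
    for activity in dataset.videos:
        reference = [
            profiles[(pid, POST, activity)]
            for pid in participants
            if groups[pid] == activity
        ]
        ref_ids = {p.participant for p in reference}
        # precompute the sum over the full reference set; leave-one-out means
        # are (total - own) / (n - 1)
        total = np.sum([p.values for p in reference], axis=0)
        n_ref = len(reference)
        grid = reference[0].times if reference else None
        for pid in participants:
            for session in SESSIONS:
                owner = profiles[(pid, session, activity)]
                if pid in ref_ids:
                    if n_ref == 1:
                        # sole reference member: nothing left after exclusion
                        rows.append(
                            {
                                "participant": pid,
                                "session": session,
                                "activity": activity,
                                "count": segmentation_count(
                                    lookup.get((pid, session, activity), np.empty(0))
                                ),
                                "r": np.nan,
                                "status": STATUS_UNDEFINED_REFERENCE,
                                "n_reference": 0,
                            }
                        )
                        continue
                    own_post = profiles[(pid, POST, activity)].values
                    norm_values = (total - own_post) / (n_ref - 1)
                    n_used = n_ref - 1
                else:
                    norm_values = total / n_ref
                    n_used = n_ref
                norm = BoundaryProfile(
                    participant="<normative>", session=POST, activity=activity,
                    times=grid, values=norm_values,
                )
                score = _correlate(owner, norm, n_used, method=method)
                rows.append(
                    {
                        "participant": pid,
                        "session": session,
                        "activity": activity,
                        "count": segmentation_count(
                            lookup.get((pid, session, activity), np.empty(0))
                        ),
                        "r": score.r if score.r is not None else np.nan,
                        "status": score.status,
                        "n_reference": n_used,
                    }
                )
    out = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(SESSIONS)}
    return (
        out.sort_values(
            ["participant", "activity", "session"],
            key=lambda c: c.map(order) if c.name == "session" else c,
        ).reset_index(drop=True)
    )
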