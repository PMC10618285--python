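"""Boundary profiles, normative profiles and leave-one-out agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segmem.segmentation import (
    STATUS_OK,
    STATUS_UNDEFINED_OWNER,
    STATUS_UNDEFINED_REFERENCE,
    AgreementScore,
    BoundaryProfile,
    KernelSpec,
    agreement,
    boundary_profile,
    compute_all_agreements,
    normative_profile,
    profile_grid,
    segmentation_count,
)
from segmem.simulate import SimConfig, simulate_study
from segmem.videos import VideoSpec

from _oracles import brute_force_profile, pearson_sum_formula


def make_video(duration=60.0):
    return VideoSpec(
        activity="gyoza", duration=duration,
        coarse_boundaries=np.empty(0), fine_boundaries=np.empty(0),
        a1_count=86, a2_count=16,
    )


class TestBoundaryProfile:
    def test_empty_press_log_gives_all_zero_profile(self):
        prof = boundary_profile(np.empty(0), make_video())
        assert np.all(prof.values == 0.0)

    def test_grid_length_and_spacing(self):
        kernel = KernelSpec(sampling_rate=10.0)
        prof = boundary_profile([5.0], make_video(60.0), kernel)
        assert prof.times.size == int(np.floor(60.0 * 10.0)) + 1
        assert np.allclose(np.diff(prof.times), 0.1)

    def test_single_press_closed_form(self):
        """Isolated press: peak 1 at the press, exp(-1/2) at 1 SD, 0 from 3 SDs."""
        prof = boundary_profile([5.0], make_video(), KernelSpec())
        t = prof.times
        assert prof.values[np.argmin(np.abs(t - 5.0))] == pytest.approx(1.0)
        assert prof.values[np.argmin(np.abs(t - 6.0))] == pytest.approx(
            np.exp(-0.5), abs=1e-12
        )
        assert prof.values[np.argmin(np.abs(t - 8.0))] == 0.0  # exactly 3 SD
        assert prof.values[np.argmin(np.abs(t - 9.0))] == 0.0  # beyond 3 SD

    def test_overlapping_presses_clip_at_one(self):
        prof = boundary_profile([10.0, 10.5], make_video(), KernelSpec(sampling_rate=20.0))
        at = prof.values[np.argmin(np.abs(prof.times - 10.25))]
        # 2*exp(-0.03125) > 1, so the midpoint is clipped
        assert at == pytest.approx(1.0)

    def test_max_pool_overlap_option(self):
        prof = boundary_profile(
            [10.0, 10.5], make_video(), KernelSpec(sampling_rate=20.0, overlap="max")
        )
        at = prof.values[np.argmin(np.abs(prof.times - 10.25))]
        assert at == pytest.approx(np.exp(-0.25**2 / 2.0))

    def test_press_outside_video_rejected_with_value(self):
        with pytest.raises(ValueError, match="70.5"):
            boundary_profile([10.0, 70.5], make_video(60.0))

    def test_kernel_mass_close_to_gaussian_integral(self):
        """Truncation loses < 1% of the sigma*sqrt(2*pi) kernel mass."""
        kernel = KernelSpec(sampling_rate=100.0)
        prof = boundary_profile([30.0], make_video(60.0), kernel)
        mass = np.trapezoid(prof.values, prof.times)
        assert mass == pytest.approx(np.sqrt(2.0 * np.pi), rel=0.01)

    @settings(max_examples=25, deadline=None)
    @given(
        presses=st.lists(
            st.floats(min_value=0.0, max_value=60.0, allow_nan=False), max_size=25
        )
    )
    def test_profile_values_always_within_unit_interval(self, presses):
        prof = boundary_profile(np.asarray(presses), make_video(60.0))
        assert np.all(prof.values >= 0.0)
        assert np.all(prof.values <= 1.0)
        if not presses:
            assert np.all(prof.values == 0.0)


class TestNormativeProfile:
    def test_single_profile_is_identity(self):
        prof = boundary_profile([5.0, 20.0], make_video(), participant="a")
        norm = normative_profile([prof])
        assert np.allclose(norm.values, prof.values)

    def test_mean_of_constant_zero_and_one_profiles(self):
        t = profile_grid(10.0, KernelSpec())
        zero = BoundaryProfile("a", "post", "gyoza", t, np.zeros_like(t))
        one = BoundaryProfile("b", "post", "gyoza", t, np.ones_like(t))
        norm = normative_profile([zero, one])
        assert np.all(norm.values == 0.5)

    def test_excluding_the_only_owner_errors(self):
        prof = boundary_profile([5.0], make_video(), participant="a")
        with pytest.raises(ValueError, match="no profiles"):
            normative_profile([prof], exclude_owner="a")

    def test_mismatched_grids_rejected(self):
        a = boundary_profile([5.0], make_video(60.0), participant="a")
        b = boundary_profile([5.0], make_video(50.0), participant="b")
        with pytest.raises(ValueError, match="grid"):
            normative_profile([a, b])

    def test_leave_one_out_is_insensitive_to_owner_presses(self):
        """The norm excluding owner i must not change when i's presses do."""
        others = [
            boundary_profile([10.0, 30.0], make_video(), participant="b"),
            boundary_profile([12.0], make_video(), participant="c"),
        ]
        for own_presses in ([5.0], [1.0, 2.0, 3.0], []):
            own = boundary_profile(own_presses, make_video(), participant="a")
            norm = normative_profile([own, *others], exclude_owner="a")
            ref = normative_profile(others)
            assert np.array_equal(norm.values, ref.values)


class TestSegmentationCount:
    def test_counts_are_raw_press_counts(self):
        assert segmentation_count(np.empty(0)) == 0
        assert segmentation_count(np.linspace(0, 10, 13)) == 13


class TestAgreement:
    def test_identical_to_single_nonself_reference_gives_r_one(self):
        video = make_video()
        owner = boundary_profile([10.0, 20.0], video, participant="a")
        ref = boundary_profile([10.0, 20.0], video, participant="b")
        score = agreement(owner, [ref])
        assert score.status == STATUS_OK
        assert score.r == pytest.approx(1.0)

    def test_owner_without_presses_is_undefined(self):
        video = make_video()
        owner = boundary_profile([], video, participant="a")
        ref = boundary_profile([10.0], video, participant="b")
        score = agreement(owner, [ref])
        assert score.status == STATUS_UNDEFINED_OWNER
        assert score.r is None

    def test_constant_reference_is_undefined(self):
        t = profile_grid(60.0, KernelSpec())
        owner = boundary_profile([10.0], make_video(), participant="a")
        ref = BoundaryProfile("b", "post", "gyoza", t, np.full_like(t, 0.25))
        score = agreement(owner, [ref])
        assert score.status == STATUS_UNDEFINED_REFERENCE

    def test_agreement_matches_brute_force_oracle(self):
        """Reference owners at {10,20}, {12,22}, {50}; external owner {11,21}."""
        video = make_video(60.0)
        reference_logs = {"r1": [10.0, 20.0], "r2": [12.0, 22.0], "r3": [50.0]}
        refs = [
            boundary_profile(p, video, participant=pid)
            for pid, p in reference_logs.items()
        ]
        owner = boundary_profile([11.0, 21.0], video, participant="x")
        score = agreement(owner, refs)
        _, owner_vals = brute_force_profile([11.0, 21.0], 60.0)
        norm_vals = np.mean(
            [brute_force_profile(p, 60.0)[1] for p in reference_logs.values()], axis=0
        )
        expected = pearson_sum_formula(owner_vals, norm_vals)
        assert score.r == pytest.approx(expected, abs=1e-9)

    def test_agreement_invariant_to_affine_rescaling(self):
        video = make_video()
        owner = boundary_profile([10.0, 25.0], video, participant="a")
        ref = boundary_profile([11.0, 24.0], video, participant="b")
        base = agreement(owner, [ref]).r
        scaled = BoundaryProfile("a", "", "gyoza", owner.times, 0.3 * owner.values + 0.2)
        assert agreement(scaled, [ref]).r == pytest.approx(base, abs=1e-12)

    def test_spearman_flag(self):
        video = make_video()
        owner = boundary_profile([10.0], video, participant="a")
        ref = boundary_profile([10.0], video, participant="b")
        assert agreement(owner, [ref], method="spearman").r == pytest.approx(1.0)


class TestComputeAllAgreements:
    def test_row_count_is_participants_by_sessions_by_activities(
        self, small_study, small_agreement
    ):
        n = len(small_study.design)
        assert len(small_agreement) == n * 2 * 2
        assert set(small_agreement["status"]) <= {
            STATUS_OK, STATUS_UNDEFINED_OWNER, STATUS_UNDEFINED_REFERENCE,
        }

    def test_identical_pressers_all_agree_perfectly(self, videos):
        """If everyone presses identically, every defined r is exactly 1."""
        cfg = SimConfig(seed=11, group_sizes={"gyoza": 3, "taichi": 3})
        ds = simulate_study(cfg)
        rows = []
        import pandas as pd

        for pid in ds.design["participant"]:
            for session in ("pre", "post"):
                for activity in videos:
                    for t in (30.0, 90.0, 150.0):
                        rows.append(
                            {
                                "participant": pid, "session": session,
                                "activity": activity, "press_time": t,
                            }
                        )
        ds.presses = pd.DataFrame(rows)
        table = compute_all_agreements(ds)
        ok = table[table["status"] == STATUS_OK]
        assert len(ok) == len(table)
        assert np.allclose(ok["r"], 1.0)

    def test_counts_column_matches_press_logs(self, small_study, small_agreement):
        sizes = small_study.presses.groupby(
            ["participant", "session", "activity"]
        ).size()
        for _, row in small_agreement.head(20).iterrows():
            key = (row["participant"], row["session"], row["activity"])
            assert row["count"] == sizes.get(key, 0)
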