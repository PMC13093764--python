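"""Visual-cue model: kinematics, angular size, sector, cue sum, transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyconform import (
    CueConfig,
    angular_size,
    compute_cue,
    compute_kinematics,
    in_forward_sector,
    transform_cue,
)
from flyconform.visual_cue import cue_table

from conftest import make_recording


def brute_force_cue(positions, speeds, headings, body_major=3.0, clamp=0.75):
    """Independent pairwise-loop oracle for the visual cue at one frame."""
    n = len(positions)
    out = np.zeros(n)
    for f in range(n):
        for i in range(n):
            if i == f:
                continue
            dx = positions[i, 0] - positions[f, 0]
            dy = positions[i, 1] - positions[f, 1]
            if np.cos(headings[f]) * dx + np.sin(headings[f]) * dy < 0:
                continue
            d = max(np.hypot(dx, dy), clamp)
            out[f] += speeds[i] * 2.0 * np.arctan(body_major / (2.0 * d))
    return out


class TestKinematics:
    def test_straight_line_speed_and_heading(self):
        pos = np.zeros((5, 1, 2))
        pos[:, 0, 0] = np.arange(5) * 1.0  # +1 mm per 0.5 s frame
        kin = compute_kinematics(make_recording(pos))
        np.testing.assert_allclose(kin.speed_mm_s[:, 0], 2.0)
        np.testing.assert_allclose(kin.heading_rad[:, 0], 0.0)

    def test_stationary_carries_last_heading(self):
        pos = np.zeros((6, 1, 2))
        pos[1:, 0] = (0, 1)  # one step in +y, then frozen
        kin = compute_kinematics(make_recording(pos))
        assert kin.speed_mm_s[0, 0] == pytest.approx(2.0)
        np.testing.assert_allclose(kin.speed_mm_s[1:-1, 0], 0.0)
        np.testing.assert_allclose(kin.heading_rad[:, 0], np.pi / 2)

    def test_initial_frames_backfilled(self):
        pos = np.zeros((6, 1, 2))
        pos[4:, 0, 0] = (1, 2)  # first movement at frame 3->4
        kin = compute_kinematics(make_recording(pos))
        np.testing.assert_allclose(kin.heading_rad[:, 0], 0.0)

    def test_circular_path_constant_speed_tangent_heading(self):
        """Closed-form check: regular polygon path has constant step length
        and heading advancing by the constant exterior angle."""
        T, R, k = 40, 20.0, 0.1  # k rad per frame
        th = k * np.arange(T)
        pos = np.stack([R * np.cos(th), R * np.sin(th)], axis=1)[:, None, :]
        kin = compute_kinematics(make_recording(pos))
        step = 2 * R * np.sin(k / 2)
        np.testing.assert_allclose(kin.speed_mm_s[:, 0], step / 0.5, rtol=1e-12)
        # chord direction = tangent of the midpoint angle
        expected = th[:-1] + k / 2 + np.pi / 2
        got = np.unwrap(kin.heading_rad[:-1, 0])
        np.testing.assert_allclose(got, expected, rtol=0, atol=1e-9)

    def test_single_frame_errors(self):
        with pytest.raises(ValueError, match=">= 2 frames"):
            compute_kinematics(make_recording(np.zeros((1, 2, 2))))


class TestAngularSize:
    def test_arctan_identity_at_body_length_half(self):
        assert angular_size(1.5, 3.0) == pytest.approx(np.pi / 2, abs=1e-15)

    def test_numeric_value_at_3mm(self):
        assert angular_size(3.0, 3.0) == pytest.approx(2 * np.arctan(0.5), abs=1e-12)
        assert angular_size(3.0, 3.0) == pytest.approx(0.9272952, abs=1e-6)

    def test_monotone_decreasing_and_bounded(self):
        d = np.linspace(0.05, 500.0, 2000)
        a = angular_size(d)
        assert np.all(np.diff(a) < 0)
        assert np.all(a > 0) and np.all(a < np.pi)

    def test_limits(self):
        assert angular_size(1e9) == pytest.approx(0.0, abs=1e-8)
        # non-positive distances clamp instead of raising, approaching pi
        assert angular_size(0.0) == pytest.approx(np.pi, abs=1e-6)
        assert angular_size(-1.0) == pytest.approx(np.pi, abs=1e-6)


class TestForwardSector:
    @pytest.mark.parametrize(
        "heading,other,expected",
        [
            (0.0, (1.0, 0.0), True),     # directly ahead
            (0.0, (-1.0, 0.0), False),   # directly behind
            (0.0, (0.0, 1.0), True),     # exactly 90 degrees: inclusive
            (0.0, (0.0, -1.0), True),    # other boundary side: inclusive
            (np.pi, (1.0, 0.0), False),
            (np.pi / 2, (-3.0, 0.5), True),
        ],
    )
    def test_half_plane_membership(self, heading, other, expected):
        assert in_forward_sector(heading, (0.0, 0.0), other) is expected


class TestComputeCue:
    def test_all_others_stationary_gives_zero(self):
        pos = np.zeros((4, 3, 2))
        pos[:, 1, 0] = 10.0
        pos[:, 2, 1] = -10.0
        rec = make_recording(pos)
        kin = compute_kinematics(rec)
        cue = compute_cue(rec, kin)
        np.testing.assert_array_equal(cue.raw_cue, 0.0)

    def test_single_neighbor_ahead_analytic(self):
        """One neighbor 1.5 mm dead ahead moving at 10 mm/s: cue = 10 * pi/2."""
        T = 4
        pos = np.zeros((T, 3, 2))
        pos[:, 1, 0] = 1.5  # ahead of the (heading-0) stationary focal
        pos[:, 1, 1] = np.arange(T) * 5.0  # 10 mm/s in +y
        pos[:, 2, 0] = -20.0  # stationary individual behind: contributes 0
        rec = make_recording(pos)
        cue = compute_cue(rec, compute_kinematics(rec))
        assert cue.raw_cue[0, 0] == pytest.approx(10 * np.pi / 2, rel=1e-12)

    def test_matches_brute_force_oracle_on_random_frames(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            T, N = 3, 24
            pos = rng.uniform(-49, 49, size=(T, N, 2))
            rec = make_recording(pos)
            kin = compute_kinematics(rec)
            cue = compute_cue(rec, kin)
            speeds = kin.speed_mm_s[0]
            headings = kin.heading_rad[0]
            expected = brute_force_cue(pos[0], speeds, headings)
            np.testing.assert_allclose(cue.raw_cue[0], expected, rtol=1e-9)

    def test_additive_in_neighbors(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-40, 40, size=(3, 9, 2))
        rec = make_recording(pos)
        kin = compute_kinematics(rec)
        full = compute_cue(rec, kin).raw_cue[0, 0]
        # split neighbors 1..8 into two disjoint sets; focal cue adds up
        total = 0.0
        for subset in (range(1, 5), range(5, 9)):
            keep = [0] + list(subset)
            sub = make_recording(pos[:, keep, :])
            skin = compute_kinematics(sub)
            # focal heading must match the full configuration
            np.testing.assert_allclose(skin.heading_rad[:, 0], kin.heading_rad[:, 0])
            total += compute_cue(sub, skin).raw_cue[0, 0]
        assert total == pytest.approx(full, rel=1e-12)

    def test_rigid_motion_equivariance(self):
        """Rotating + translating every trajectory leaves the raw cue unchanged."""
        rng = np.random.default_rng(11)
        pos = rng.uniform(-40, 40, size=(5, 8, 2))
        rec = make_recording(pos)
        raw = compute_cue(rec, compute_kinematics(rec)).raw_cue
        phi, shift = 1.1, np.array([4.0, -7.0])
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        moved = pos @ rot.T + shift
        rec2 = make_recording(moved)
        raw2 = compute_cue(rec2, compute_kinematics(rec2)).raw_cue
        np.testing.assert_allclose(raw2, raw, rtol=1e-9, atol=1e-12)

    @given(
        speed_scale=st.floats(1.5, 4.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_neighbor_speed(self, speed_scale, seed):
        """Scaling an in-sector neighbor's speed strictly increases the cue."""
        rng = np.random.default_rng(seed)
        base = rng.uniform(-30, 30, size=(3, 5, 2))
        base[:, 1, :] = base[0, 0, :] + np.array([5.0, 0.0])  # park neighbor 1
        base[:, 1, 0] += np.arange(3) * 1.0  # neighbor 1 moves +x at 2 mm/s
        rec = make_recording(base)
        kin = compute_kinematics(rec)
        if not in_forward_sector(
            kin.heading_rad[0, 0], base[0, 0], base[0, 1]
        ):
            return  # neighbor behind: nothing to compare
        cue_lo = compute_cue(rec, kin).raw_cue[0, 0]
        faster = base.copy()
        faster[:, 1, 0] = base[0, 1, 0] + np.arange(3) * speed_scale
        rec2 = make_recording(faster)
        kin2 = compute_kinematics(rec2)
        cue_hi = compute_cue(rec2, kin2).raw_cue[0, 0]
        assert cue_hi > cue_lo

    def test_farther_same_bearing_neighbor_decreases_cue(self):
        pos = np.zeros((3, 2, 2))
        pos[:, 0, 0] = np.arange(3)  # focal walks +x
        pos[:, 1, 1] = np.arange(3) * 2  # neighbor moves +y
        near = pos.copy()
        near[:, 1, 0] = pos[:, 0, 0] + 4.0
        far = pos.copy()
        far[:, 1, 0] = pos[:, 0, 0] + 12.0
        cues = []
        for p in (near, far):
            r = make_recording(p)
            cues.append(compute_cue(r, compute_kinematics(r)).raw_cue[0, 0])
        assert cues[1] < cues[0]

    def test_coincident_positions_clamped_not_raised(self):
        pos = np.zeros((3, 2, 2))
        pos[:, 1, 1] = np.arange(3)  # neighbor moves through the focal
        rec = make_recording(pos)
        cue = compute_cue(rec, compute_kinematics(rec))
        assert np.all(np.isfinite(cue.raw_cue))
        # clamped distance bound: term can never exceed speed * angular(0.75)
        assert cue.raw_cue.max() <= 2.0 * 2 * np.arctan(3.0 / 1.5) + 1e-9


class TestTransform:
    def test_three_value_hand_case(self):
        """Stratum {0, e, e^2}: offset -> {e, e, e^2}, log -> {1, 1, 2}, z-scored."""
        pos = np.zeros((3, 2, 2))
        rec = make_recording(pos)
        kin = compute_kinematics(rec)
        cue = compute_cue(rec, kin)
        cue.raw_cue[:, 0] = [0.0, np.e, np.e**2]
        cue.raw_cue[:, 1] = [0.0, np.e, np.e**2]
        out = transform_cue(cue, rec)
        logged = np.array([1.0, 1.0, 2.0] * 2)
        expected = (logged - logged.mean()) / logged.std()
        np.testing.assert_allclose(
            out.transformed_cue.T.ravel(), expected, rtol=1e-12
        )

    def test_positive_series_offset_is_identity(self):
        """With no zeros the transform is exactly log + z-score."""
        rng = np.random.default_rng(3)
        pos = np.zeros((50, 2, 2))
        rec = make_recording(pos)
        cue = compute_cue(rec, compute_kinematics(rec))
        cue.raw_cue[:] = rng.lognormal(size=(50, 2))
        out = transform_cue(cue, rec)
        logged = np.log(cue.raw_cue)
        expected = (logged - logged.mean()) / logged.std()
        np.testing.assert_allclose(out.transformed_cue, expected, rtol=1e-10)

    def test_species_mean_zero_sd_one(self, coupled_recording):
        rec = coupled_recording
        kin = compute_kinematics(rec)
        out = transform_cue(compute_cue(rec, kin), rec)
        z = out.transformed_cue
        assert abs(z.mean()) < 1e-9
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_stratum_errors(self):
        pos = np.zeros((10, 2, 2))
        rec = make_recording(pos)
        cue = compute_cue(rec, compute_kinematics(rec))
        with pytest.raises(ValueError, match="all-zero"):
            transform_cue(cue, rec)

    def test_cue_table_long_format(self, null_recording):
        rec = null_recording
        kin = compute_kinematics(rec)
        cue = transform_cue(compute_cue(rec, kin), rec)
        tab = cue_table(rec, cue)
        assert len(tab) == rec.n_frames * rec.n_individuals
        assert set(tab.columns) == {
            "individual_id", "frame", "raw_cue", "transformed_cue"
        }
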