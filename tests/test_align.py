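import math

import numpy as np
import pandas as pd
import pytest

from swirtrack import (
    MarkerRoles,
    MarkerTable,
    RigidTransform,
    align_stack,
    apply_transform,
    compute_transform,
    corrupt_markers,
    deinterleave,
    heading_angle,
    markers_for_channel,
    transforms_from_csv,
    transforms_to_csv,
)


def markers(target, anterior):
    return {
        "liver": (target[0], target[1], 1.0),
        "head": (anterior[0], anterior[1], 1.0),
    }


ROLES = MarkerRoles(target="liver", anterior="head")


class TestComputeTransform:
    def test_already_facing_up_gives_zero_rotation(self):
        t = compute_transform(markers((100, 80), (100, 60)), ROLES, (512, 640))
        assert t.theta == pytest.approx(0.0, abs=1e-12)
        assert (t.dx, t.dy) == pytest.approx((639 / 2 - 100, 511 / 2 - 80))

    def test_anterior_to_the_right_rotates_above_centre(self):
        t = compute_transform(markers((50, 50), (70, 50)), ROLES, (128, 128))
        moved = t.apply_to_points([[70.0, 50.0]])[0]
        cx, cy = t.centre()
        assert moved[0] == pytest.approx(cx, abs=1e-9)
        assert moved[1] < cy

    def test_coincident_markers_marked_invalid(self):
        t = compute_transform(markers((50, 50), (50, 50)), ROLES, (128, 128))
        assert not t.valid
        with pytest.raises(ValueError):
            apply_transform(np.zeros((8, 8)), t)

    @pytest.mark.parametrize("angle_deg", [0, 30, 90, 135, 180, 250, 315])
    def test_anterior_always_maps_straight_up(self, angle_deg):
        a = math.radians(angle_deg)
        target = np.array([40.0, 40.0])
        anterior = target + 15 * np.array([math.cos(a), math.sin(a)])
        t = compute_transform(markers(target, anterior), ROLES, (96, 96))
        moved = t.apply_to_points([anterior])[0]
        cx, cy = t.centre()
        assert moved[0] == pytest.approx(cx, abs=1e-9)
        assert cy - moved[1] == pytest.approx(15.0, abs=1e-9)

    def test_rigidity_pairwise_distances_preserved(self, rng):
        pts = rng.uniform(0, 100, size=(6, 2))
        t = compute_transform(markers(pts[0], pts[1]), ROLES, (128, 128))
        moved = t.apply_to_points(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
        assert np.max(np.abs(d0 - d1)) < 1e-9

    def test_theta_wrapped_to_half_open_interval(self):
        t = RigidTransform(frame=0, theta=3 * math.pi, out_shape=(8, 8))
        assert -math.pi < t.theta <= math.pi

    @pytest.mark.parametrize("raw", [-7.0, -math.pi, 0.0, math.pi, 10.5])
    def test_wrapping_preserves_direction(self, raw):
        t = RigidTransform(frame=0, theta=raw, out_shape=(8, 8))
        assert -math.pi < t.theta <= math.pi
        assert math.cos(t.theta) == pytest.approx(math.cos(raw), abs=1e-12)
        assert math.sin(t.theta) == pytest.approx(math.sin(raw), abs=1e-12)


class TestApplyTransform:
    def test_identity_transform_is_identity(self, rng):
        frame = rng.random((16, 16))
        t = RigidTransform(frame=0, out_shape=(16, 16))
        out, mask = apply_transform(frame, t)
        assert np.allclose(out, frame)
        assert not mask.any()

    def test_integer_translation_nearest_is_exact_shift(self, rng):
        frame = rng.integers(0, 1000, (12, 12)).astype(float)
        t = RigidTransform(frame=0, dx=3.0, dy=0.0, out_shape=(12, 12))
        out, mask = apply_transform(frame, t, interpolation="nearest")
        assert np.array_equal(out[:, 3:], frame[:, :-3])
        assert mask[:, :3].all() and not mask[:, 3:].any()
        # total intensity conserved over the overlapping support
        assert out[~mask].sum() == pytest.approx(frame[:, :-3].sum())

    def test_rotation_then_inverse_recovers_smooth_image(self):
        ys, xs = np.mgrid[0:32, 0:32]
        smooth = np.sin(xs / 6.0) + np.cos(ys / 7.0)
        theta = 0.3
        fwd = RigidTransform(frame=0, theta=theta, out_shape=(32, 32))
        back = RigidTransform(frame=0, theta=-theta, out_shape=(32, 32))
        mid, m1 = apply_transform(smooth, fwd)
        out, m2 = apply_transform(mid, back)
        interior = ~m1 & ~m2
        # exclude a border band where the first resampling touched masked pixels
        interior[:8] = interior[-8:] = False
        interior[:, :8] = interior[:, -8:] = False
        assert np.max(np.abs(out[interior] - smooth[interior])) < 1e-2
        # and bilinear inverse composition on points is exact
        pts = np.array([[10.0, 12.0], [20.0, 5.0]])
        assert np.allclose(back.apply_to_points(fwd.apply_to_points(pts)), pts,
                           atol=1e-9)


class TestAlignStack:
    def channel_and_markers(self, phantom, jitter=0.0, miss=0.0, seed=99):
        channels = deinterleave(phantom.stack, phantom.config)
        label = phantom.config.labels[0]
        table = markers_for_channel(
            phantom.markers, phantom.stack.n_frames, phantom.config, label
        )
        if jitter or miss:
            table = corrupt_markers(table, jitter, miss, seed=seed)
        return channels.channels[label], table

    def test_target_marker_lands_on_centre_by_construction(self, moving_phantom):
        member, table = self.channel_and_markers(moving_phantom)
        roles = MarkerRoles(target="liver", anterior="head")
        aligned = align_stack(member, table, roles)
        for i, t in enumerate(aligned.transforms):
            frame = aligned.frame_indices[i]
            tx, ty, _ = table.at_frame(frame)["liver"]
            moved = t.apply_to_points([[tx, ty]])[0]
            assert np.allclose(moved, t.centre(), atol=1e-9)

    def test_anterior_axis_points_up_after_alignment(self, moving_phantom):
        member, table = self.channel_and_markers(moving_phantom)
        aligned = align_stack(member, table, MarkerRoles("liver", "head"))
        for i, t in enumerate(aligned.transforms):
            frame = aligned.frame_indices[i]
            ax, ay, _ = table.at_frame(frame)["head"]
            tx, ty, _ = table.at_frame(frame)["liver"]
            moved_a = t.apply_to_points([[ax, ay]])[0]
            moved_t = t.apply_to_points([[tx, ty]])[0]
            v = moved_a - moved_t
            assert abs(math.atan2(v[0], -v[1])) < 1e-9

    def test_recovered_rotation_negates_programmed_heading(self, moving_phantom):
        member, table = self.channel_and_markers(moving_phantom)
        aligned = align_stack(member, table, MarkerRoles("liver", "head"))
        raw_frames = np.array([0, 1, 2])  # single channel: channel frame == raw
        truth = moving_phantom.truth.set_index("frame")
        for i, t in enumerate(aligned.transforms):
            h = truth.loc[aligned.frame_indices[i], "heading_rad"]
            err = (t.theta + h + math.pi) % (2 * math.pi) - math.pi
            assert abs(err) < 1e-6

    def test_stationary_phantom_gives_equal_transforms(self, quiet_phantom):
        member, table = self.channel_and_markers(quiet_phantom)
        aligned = align_stack(member, table, MarkerRoles("liver", "head"))
        first = aligned.transforms[0]
        for t in aligned.transforms[1:]:
            assert (t.dx, t.dy, t.theta) == (first.dx, first.dy, first.theta)

    def test_all_frames_filtered_out_is_an_error(self, quiet_phantom):
        member, table = self.channel_and_markers(quiet_phantom, miss=1.0)
        with pytest.raises(ValueError, match="no valid frames"):
            align_stack(member, table, MarkerRoles("liver", "head"))

    def test_procrustes_heading_matches_two_point_on_exact_markers(
        self, moving_phantom
    ):
        member, table = self.channel_and_markers(moving_phantom)
        roles = MarkerRoles("liver", "head",
                            peripheral=("tail_base", "left_flank", "right_flank"))
        two_point = align_stack(member, table, roles, heading="two-point")
        procrustes = align_stack(member, table, roles, heading="procrustes")
        for a, b in zip(two_point.transforms, procrustes.transforms):
            err = (a.theta - b.theta + math.pi) % (2 * math.pi) - math.pi
            assert abs(err) < 1e-9

    def test_mirror_flag_flips_before_alignment(self, quiet_phantom):
        member, table = self.channel_and_markers(quiet_phantom)
        plain = align_stack(member, table, MarkerRoles("liver", "head"))
        mirrored = align_stack(member, table, MarkerRoles("liver", "head"),
                               mirror=True)
        # stationary upright phantom: mirroring the input flips the output in x
        a = plain.data[0]
        b = mirrored.data[0]
        assert np.allclose(a, b[:, ::-1], atol=1e-6)

    def test_transforms_csv_round_trip(self, tmp_path, moving_phantom):
        member, table = self.channel_and_markers(moving_phantom)
        aligned = align_stack(member, table, MarkerRoles("liver", "head"))
        path = tmp_path / "transforms.csv"
        transforms_to_csv(aligned.transforms, path)
        back = transforms_from_csv(path, out_shape=member.data.shape[1:])
        for a, b in zip(aligned.transforms, back):
            assert (a.frame, a.valid) == (b.frame, b.valid)
            assert np.allclose([a.dx, a.dy, a.theta], [b.dx, b.dy, b.theta])
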