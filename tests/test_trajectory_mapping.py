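"""Mapping snapshots onto the buckle: alignment, arc length, orientation."""

import numpy as np
import pytest

from bucklesense import (
    GeneratorConfig,
    LabeledFrame,
    make_buckled_sheet,
    place_protein,
    map_trajectory,
    protein_arclength,
    protein_orientation,
    sample_boltzmann_trajectory,
)
from bucklesense.errors import AlignmentError, OrientationError, PipelineError
from bucklesense.frames import ROLE_PROTEIN
from bucklesense.trajectory_mapping import align_to_profile, arclength_from_x, map_frame


def rod_frame(direction, n=10, length=8.0, center=(17.0, 8.5, 5.0), box=(34.02, 17.0, 20.0)):
    """Straight bead rod along a given unit direction."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    t = np.linspace(-length / 2, length / 2, n)
    coords = np.asarray(center) + t[:, None] * direction
    # tiny lateral spread so the covariance is non-degenerate
    coords = coords + np.outer(np.tile([0.01, -0.01], n // 2), [0, 0, 1])
    roles = np.array([ROLE_PROTEIN] * n, dtype=object)
    return LabeledFrame(coords, roles, np.array(box))


class TestAlignment:
    def test_centred_frame_needs_no_shift(self, clean_cfg, profile):
        frame = make_buckled_sheet(clean_cfg)
        _, shift = align_to_profile(frame, profile)
        assert abs(shift) < profile.Lx / 50  # one bin width

    def test_known_shift_is_recovered(self, clean_cfg, profile):
        frame = make_buckled_sheet(clean_cfg).shifted([7.3, 0, 0], wrap_xy=True)
        _, shift = align_to_profile(frame, profile)
        assert shift == pytest.approx(-7.3, abs=profile.Lx / 50)

    def test_full_period_shift_is_identity(self, clean_cfg, profile):
        frame = make_buckled_sheet(clean_cfg).shifted([profile.Lx, 0, 0], wrap_xy=True)
        _, shift = align_to_profile(frame, profile)
        assert abs(shift) < profile.Lx / 50

    def test_inconsistent_box_rejected(self, clean_cfg, profile):
        frame = make_buckled_sheet(clean_cfg)
        bad = LabeledFrame(frame.coords, frame.roles, np.array([50.0, 17.0, 20.0]))
        with pytest.raises(AlignmentError, match="box"):
            align_to_profile(bad, profile)

    def test_sparse_membrane_rejected(self, profile):
        coords = np.array([[1.0, 1.0, 1.0], [1.1, 1.0, 1.0], [1.2, 1.0, 1.0]])
        roles = np.array(["membrane_head"] * 3, dtype=object)
        frame = LabeledFrame(coords, roles, np.array([34.02, 17.0, 20.0]))
        with pytest.raises(AlignmentError, match="bins|sparse"):
            align_to_profile(frame, profile)


class TestArclength:
    def test_inversion_matches_forward_map(self, profile):
        from bucklesense.buckle_geometry import profile_xz

        s_true = np.linspace(0.001, profile.L - 0.001, 500)
        x, _ = profile_xz(profile, s_true)
        s_rec = arclength_from_x(profile, np.clip(x, 0, profile.Lx))
        np.testing.assert_allclose(s_rec, s_true, atol=1e-6 * profile.L)

    def test_crest_maps_to_mid_arc(self, clean_cfg, profile):
        frame = place_protein(clean_cfg, 0.5, 0.0)
        aligned, _ = align_to_profile(frame, profile)
        assert protein_arclength(aligned, profile) == pytest.approx(0.5, abs=1e-3)

    @pytest.mark.parametrize("s_target", [0.1, 0.25, 0.5, 0.75, 0.9])
    def test_generator_positions_recovered(self, clean_cfg, profile, s_target):
        frame = place_protein(clean_cfg, s_target, 20.0)
        placement = map_frame(frame, profile)
        assert placement.s_norm == pytest.approx(s_target, abs=0.01)

    def test_inflection_point_has_zero_curvature(self, clean_cfg, profile):
        placement = map_frame(place_protein(clean_cfg, 0.25, 0.0), profile)
        assert placement.s_norm == pytest.approx(0.25, abs=0.01)
        assert placement.C < 5e-3  # near the analytic zero of C(s)


class TestOrientation:
    def test_rod_along_x(self):
        assert protein_orientation(rod_frame([1, 0, 0])) == pytest.approx(0.0, abs=0.2)

    def test_rod_along_y(self):
        assert protein_orientation(rod_frame([0, 1, 0])) == pytest.approx(90.0, abs=0.2)

    def test_axis_fold_is_rotation_invariant(self):
        d = [np.cos(np.radians(30)), np.sin(np.radians(30)), 0]
        t1 = protein_orientation(rod_frame(d))
        t2 = protein_orientation(rod_frame([-d[0], -d[1], 0]))  # 180 deg about z
        assert t1 == pytest.approx(30.0, abs=0.2)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_reflection_invariance(self, clean_cfg, profile):
        frame = place_protein(clean_cfg, 0.4, 35.0)
        mirrored = LabeledFrame(
            frame.coords * np.array([1, -1, 1]) + np.array([0, frame.box[1], 0]),
            frame.roles,
            frame.box,
        )
        assert protein_orientation(frame) == pytest.approx(protein_orientation(mirrored), abs=1e-6)

    def test_degenerate_cloud_rejected(self):
        coords = np.tile([5.0, 5.0, 5.0], (6, 1))
        roles = np.array([ROLE_PROTEIN] * 6, dtype=object)
        frame = LabeledFrame(coords, roles, np.array([34.0, 17.0, 20.0]))
        with pytest.raises(OrientationError):
            protein_orientation(frame)


class TestRoundTrip:
    @pytest.mark.parametrize("target", [(0.5, 0.0), (0.5, 45.0), (0.5, 90.0), (0.25, 60.0)])
    def test_noiseless_placements_are_exact(self, clean_cfg, profile, target):
        s_t, th_t = target
        placement = map_frame(place_protein(clean_cfg, s_t, th_t), profile)
        assert placement.s_norm == pytest.approx(s_t, abs=0.01)
        assert placement.theta == pytest.approx(th_t, abs=1.0)

    def test_translation_invariance(self, clean_cfg, profile, rng):
        frame = place_protein(clean_cfg, 0.3, 25.0)
        ref = map_frame(frame, profile)
        for dx in rng.uniform(-30, 30, 3):
            moved = map_frame(frame.shifted([dx, 0, 0], wrap_xy=True), profile)
            assert moved.s_norm == pytest.approx(ref.s_norm, abs=1.0 / 50)
            assert moved.theta == pytest.approx(ref.theta, abs=1e-6)

    def test_constant_trajectory_maps_to_constant_placements(self, profile):
        cfg = GeneratorConfig(noise_sigma=0.3, seed=7)
        frames = [place_protein(cfg, 0.5, 45.0, rng=np.random.default_rng(k)) for k in range(100)]
        placements = map_trajectory(frames, profile)
        assert len(placements) == 100
        s = np.array([p.s_norm for p in placements])
        th = np.array([p.theta for p in placements])
        np.testing.assert_allclose(s, 0.5, atol=0.01)
        np.testing.assert_allclose(th, 45.0, atol=1.0)

    def test_single_frame(self, clean_cfg, profile):
        placements = map_trajectory([place_protein(clean_cfg, 0.6, 10.0)], profile)
        assert len(placements) == 1

    def test_boltzmann_marginals_match_sampler_truth(self, profile):
        cfg = GeneratorConfig(
            seed=21, n_frames=800, noise_sigma=0.3,
        )
        frames, truth = sample_boltzmann_trajectory(cfg, stream=True)
        placements = map_trajectory(frames, profile)
        s = np.array([p.s_norm for p in placements])
        th = np.array([p.theta for p in placements])
        err_s = np.minimum(np.abs(s - truth[:, 0]), 1 - np.abs(s - truth[:, 0]))
        assert np.quantile(err_s, 0.99) < 0.01
        assert np.max(np.abs(th - truth[:, 1])) < 1.0

    def test_excess_failures_abort_pipeline(self, clean_cfg, profile):
        good = place_protein(clean_cfg, 0.5, 30.0)
        membrane_only = make_buckled_sheet(clean_cfg)  # no protein -> mapping fails
        with pytest.raises(PipelineError):
            map_trajectory([good, membrane_only, membrane_only], profile)
        with pytest.raises(PipelineError, match="empty"):
            map_trajectory([], profile)
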