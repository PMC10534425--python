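"""Grid detection, phase-encoded projector correspondences and calibration."""

import numpy as np
import pytest

from sfdical import twin as tw
from sfdical.core_model import project_point
from sfdical.geom_calib import (
    CalibrationTarget,
    GridDetectionError,
    build_ray_fields,
    build_system_geometry,
    define_reference_plane,
    detect_grid,
    generate_predistorted_patterns,
    projector_points_from_phase,
    unify_frames,
)
from sfdical.pipeline import calibrate_from_poses
from sfdical.zhang import calibrate_pinhole


@pytest.fixture(scope="module")
def config256():
    return tw.default_config(camera_shape=(256, 256), projector_shape=(256, 144))


@pytest.fixture(scope="module")
def pose_render(config256):
    target = CalibrationTarget()
    board = tw.TargetBoard(target, tw.board_pose(target, z=320.0, tilt_deg=(20.0, 10.0)))
    return target, tw.render_calibration_pose(board, config256)


def exact_correspondences(config, target, pose_params):
    objs, cams, pros = [], [], []
    for tilt, dz in pose_params:
        pose = tw.board_pose(target, z=config.reference_z + dz, tilt_deg=tilt)
        obj = target.object_points()
        glob = pose.to_global(np.column_stack([obj, np.zeros(len(obj))]))
        cams.append(project_point(config.camera_truth, glob))
        pros.append(project_point(config.projector_truth, glob))
        objs.append(obj)
    return objs, cams, pros


class TestDetectGrid:
    def test_centroids_within_tenth_pixel(self, pose_render):
        target, render = pose_render
        pts, _ = detect_grid(render.dc_image, target)
        err = np.linalg.norm(pts - render.marker_cam_px, axis=1)
        assert len(pts) == target.n_points
        assert err.max() < 0.15
        assert err.mean() < 0.1

    def test_full_scale_grid_of_1600_circles(self):
        # the 40x40 grid at proportionally scaled spacing fills the field
        config = tw.default_config(camera_shape=(512, 512), projector_shape=(256, 144))
        target = CalibrationTarget(n_cols=40, n_rows=40, spacing=0.5, circle_diameter=0.25)
        board = tw.TargetBoard(
            target, tw.board_pose(target, z=320.0), edge_width_mm=0.03
        )
        render = tw.render_calibration_pose(board, config, f_ladder=(0.25,))
        pts, _ = detect_grid(render.dc_image, target)
        assert len(pts) == 1600
        err = np.linalg.norm(pts - render.marker_cam_px, axis=1)
        assert err.mean() < 0.2

    def test_count_mismatch_raises_with_counts(self, pose_render):
        target, render = pose_render
        wrong = CalibrationTarget(n_cols=12, n_rows=12)
        with pytest.raises(GridDetectionError, match="100"):
            detect_grid(render.dc_image, wrong)

    def test_rotated_board_axes_resolved_by_markers(self, config256):
        target = CalibrationTarget()
        board = tw.TargetBoard(target, tw.board_pose(target, z=320.0, roll_deg=90.0))
        render = tw.render_calibration_pose(board, config256)
        pts, _ = detect_grid(render.dc_image, target)
        err = np.linalg.norm(pts - render.marker_cam_px, axis=1)
        assert err.max() < 0.15


class TestProjectorPointsFromPhase:
    def test_phase_to_dmd_coordinate_hand_values(self):
        phase_u = np.full((8, 8), 20.0 * np.pi)
        phase_v = np.zeros((8, 8))
        pts = np.array([[4.0, 4.0]])
        dmd, ok = projector_points_from_phase(phase_u, phase_v, pts, (1920, 1080, 10.0, 10.0))
        assert dmd[0, 0] == pytest.approx(960.0)
        assert dmd[0, 1] == pytest.approx(0.0)
        assert ok.all()

    def test_out_of_chip_phase_flagged(self):
        phase_u = np.full((4, 4), -1.0)
        dmd, ok = projector_points_from_phase(phase_u, phase_u, np.array([[2.0, 2.0]]), (1920, 1080, 10.0, 10.0))
        assert not ok.any()

    def test_twin_end_to_end_dmd_decoding(self, pose_render, config256):
        from sfdical.demodulation import demodulate
        from sfdical.pipeline import unwrap_ladder

        target, render = pose_render
        pts, _ = detect_grid(render.dc_image, target)
        pu = unwrap_ladder({f: demodulate(s) for f, s in render.stacks_u.items()})
        pv = unwrap_ladder({f: demodulate(s) for f, s in render.stacks_v.items()})
        n_col, n_row = config256.projector_truth.intrinsics.image_size
        dmd, ok = projector_points_from_phase(
            pu[max(pu)], pv[max(pv)], pts, (n_col, n_row, max(pu), max(pv))
        )
        err = np.linalg.norm(dmd - render.marker_dmd_px, axis=1)
        assert ok.all()
        assert err.max() < 0.2


class TestCalibrateDevice:
    def test_noise_free_recovery_and_rms(self, config256):
        # zero-noise correspondences: every parameter recovers to well below
        # the 0.5 % / 0.05 px targets
        target = CalibrationTarget()
        poses = [((0, 0), 0), ((25, 0), -6), ((-25, 0), 6), ((0, 25), -3), ((0, -25), 3), ((20, 20), 0)]
        objs, cams, pros = exact_correspondences(config256, target, poses)
        res = calibrate_pinhole(objs, cams, config256.camera_truth.intrinsics.image_size)
        truth = config256.camera_truth.intrinsics
        assert res.rms_px < 0.05
        assert res.device.intrinsics.fx == pytest.approx(truth.fx, rel=5e-3)
        assert res.device.intrinsics.fy == pytest.approx(truth.fy, rel=5e-3)
        assert res.device.intrinsics.cx == pytest.approx(truth.cx, abs=0.005 * truth.image_size[0])
        assert res.device.intrinsics.cy == pytest.approx(truth.cy, abs=0.005 * truth.image_size[1])
        k1_true = config256.camera_truth.distortion.radial[0]
        assert res.device.distortion.radial[0] == pytest.approx(k1_true, rel=0.01)

    def test_two_poses_rejected(self, config256):
        target = CalibrationTarget()
        objs, cams, _ = exact_correspondences(config256, target, [((0, 0), 0), ((15, 0), -5)])
        with pytest.raises(ValueError, match="at least three"):
            calibrate_pinhole(objs, cams, (256, 256))

    def test_noise_floor_consistency(self, config256):
        # 0.1 px centroid noise: RMS lands at the noise level, focals within 2 %
        rng = np.random.default_rng(21)
        target = CalibrationTarget()
        poses = [((0, 0), 0), ((25, 0), -6), ((-25, 0), 6), ((0, 25), -3), ((0, -25), 3), ((20, 20), 0)]
        objs, cams, _ = exact_correspondences(config256, target, poses)
        cams = [c + rng.normal(0, 0.1, c.shape) for c in cams]
        res = calibrate_pinhole(objs, cams, (256, 256))
        assert 0.05 < res.rms_px < 0.2
        truth = config256.camera_truth.intrinsics
        assert res.device.intrinsics.fx == pytest.approx(truth.fx, rel=0.02)
        assert res.device.intrinsics.fy == pytest.approx(truth.fy, rel=0.02)


class TestUnifyFrames:
    def test_exact_data_recovers_projector_pose(self, config256):
        target = CalibrationTarget()
        poses = [((0, 0), 0), ((25, 0), -6), ((-25, 0), 6), ((0, 25), -3), ((0, -25), 3), ((20, 20), 0)]
        objs, cams, pros = exact_correspondences(config256, target, poses)
        camr = calibrate_pinhole(objs, cams, config256.camera_truth.intrinsics.image_size)
        pror = calibrate_pinhole(objs, pros, config256.projector_truth.intrinsics.image_size, role="projector")
        _, projector, stats = unify_frames(camr, pror)
        err = np.linalg.norm(projector.pose.center - config256.projector_truth.pose.center)
        assert err < 0.5
        assert stats["translation_spread_mm"] < 0.1

    def test_identical_poses_give_identity(self, config256):
        target = CalibrationTarget()
        poses = [((0, 0), 0), ((25, 0), -6), ((-25, 0), 6)]
        objs, cams, _ = exact_correspondences(config256, target, poses)
        camr = calibrate_pinhole(objs, cams, (256, 256))
        _, projector, _ = unify_frames(camr, camr)
        assert np.allclose(projector.pose.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(projector.pose.translation, 0.0, atol=1e-9)

    def test_single_pose_spread_undefined(self, config256):
        target = CalibrationTarget()
        poses = [((0, 0), 0), ((25, 0), -6), ((-25, 0), 6)]
        objs, cams, pros = exact_correspondences(config256, target, poses)
        camr = calibrate_pinhole(objs, cams, (256, 256))
        pror = calibrate_pinhole(objs, pros, (256, 144), role="projector")
        camr.poses, pror.poses = camr.poses[:1], pror.poses[:1]
        _, _, stats = unify_frames(camr, pror)
        assert stats["translation_spread_mm"] is None


class TestImageBasedCalibration:
    def test_full_chain_from_rendered_images(self, config256):
        target, renders = tw.render_calibration_set(config256)
        geometry, details = calibrate_from_poses(
            renders,
            target,
            config256.camera_truth.intrinsics.image_size,
            config256.projector_truth.intrinsics.image_size,
        )
        assert details["camera_rms_px"] < 0.1
        assert details["projector_rms_px"] < 0.1
        truth = config256.camera_truth.intrinsics
        assert geometry.camera.intrinsics.fx == pytest.approx(truth.fx, rel=5e-3)
        assert geometry.camera.intrinsics.fy == pytest.approx(truth.fy, rel=5e-3)
        center_err = np.linalg.norm(
            geometry.projector.pose.center - config256.projector_truth.pose.center
        )
        assert center_err < 1.0
        # the calibrated volume contains the reference plane
        assert geometry.volume_min[2] < geometry.reference_plane_point[2] < geometry.volume_max[2]


class TestReferencePlaneAndPatterns:
    def test_reference_plane_at_volume_center(self):
        pt, n = define_reference_plane([-10, -10, 310], [10, 10, 330])
        assert np.allclose(pt, [0, 0, 320])
        assert np.allclose(n, [0, 0, 1])

    def test_zero_height_volume(self):
        pt, _ = define_reference_plane([-10, -10, 320], [10, 10, 320])
        assert pt[2] == 320

    def test_shifted_volume_follows_center(self):
        pt, _ = define_reference_plane([-5, -5, 300], [15, 15, 340])
        assert np.allclose(pt, [5, 5, 320])

    def test_zero_frequency_pattern_is_uniform(self, geometry):
        img = generate_predistorted_patterns(geometry, 0.0)
        assert np.allclose(img, img.flat[0])

    def test_out_of_range_frequency_rejected(self, geometry):
        with pytest.raises(ValueError):
            generate_predistorted_patterns(geometry, 1.5)

    @staticmethod
    def _measure_frequency(config, geometry, z: float) -> float:
        """Metric fringe frequency realized on the plane at z, by the phase
        slope of three explicitly rendered, phase-shifted DMD patterns."""
        from sfdical.demodulation import FringeStack, demodulate, unwrap_phase

        shifts = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
        scene = tw.TwinScene(surface=tw.Plane(point=(0, 0, z)), reflectance=tw.LambertianAlbedo())
        frames = [
            tw.render_pattern_image(
                generate_predistorted_patterns(geometry, 0.45, phase_offset=d), scene, config
            )
            for d in shifts
        ]
        res = demodulate(FringeStack(images=np.stack(frames), phase_shifts=shifts))
        phase, _ = unwrap_phase(res.phase_wrapped)
        h, w = phase.shape
        col = phase[h // 4 : 3 * h // 4, w // 2]
        pitch = 21.6 * z / 320.0 / h  # camera pixel footprint widens with z
        slope = np.polyfit(np.arange(len(col)) * pitch, col, 1)[0]
        return abs(slope) / (2 * np.pi)

    def test_projected_pattern_realizes_metric_frequency(self, config, geometry):
        f = self._measure_frequency(config, geometry, 320.0)
        assert f == pytest.approx(0.45, rel=0.005)

    def test_pattern_frequency_scales_with_plane_shift(self, config, geometry):
        f320 = self._measure_frequency(config, geometry, 320.0)
        f330 = self._measure_frequency(config, geometry, 330.0)
        assert f330 / f320 == pytest.approx(320.0 / 330.0, rel=0.005)


class TestRayFields:
    def test_unit_norm_and_central_ray(self, geometry):
        fields = build_ray_fields(geometry)
        cam = fields["camera"]
        assert np.allclose(np.linalg.norm(cam, axis=-1), 1.0, atol=1e-12)
        h, w, _ = cam.shape
        assert np.allclose(cam[h // 2, w // 2], [0, 0, 1], atol=2e-2)

    def test_camera_corner_rays_span_field(self, geometry):
        cam = build_ray_fields(geometry)["camera"]
        left, right = cam[64, 0], cam[64, -1]
        span = (right[0] / right[2] - left[0] / left[2]) * 320.0
        assert span == pytest.approx(21.6, rel=0.02)
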