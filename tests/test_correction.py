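"""Frequency scaling, Lambert normalization, MTF LUT and reflectance."""

import numpy as np
import pytest

from sfdical import twin as tw
from sfdical.correction import (
    MtfLut,
    compute_reflectance,
    correct_frequency,
    lambert_factor,
    magnification,
    scaling_parallel,
    scaling_perpendicular,
)
from sfdical.pipeline import process_measurement, reconstruct_surface
from sfdical.surface import SurfaceMap, compute_angle_maps
from tests.conftest import F_LIST, MU_A_TRUE, MU_S_TRUE, inner_mask

D35 = np.deg2rad(35.0)


class TestScalingFactors:
    @pytest.mark.parametrize(
        "func,theta,phi,expected",
        [
            (scaling_parallel, 0.0, 0.3, 1.0),
            (scaling_parallel, D35, np.pi / 2, 1.0),
            (scaling_parallel, D35, 0.0, np.cos(D35)),
            (scaling_perpendicular, 0.0, 1.0, 1.0),
            (scaling_perpendicular, D35, 0.0, 1.0),
            (scaling_perpendicular, D35, np.pi / 2, np.cos(D35)),
        ],
    )
    def test_hand_values(self, func, theta, phi, expected):
        assert func(theta, phi) == pytest.approx(expected, abs=1e-12)

    def test_parallel_perpendicular_exchange_symmetry(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(0, np.pi / 2 - 0.1, 100)
        phi = rng.uniform(-np.pi, np.pi, 100)
        assert np.allclose(
            scaling_parallel(theta, phi), scaling_perpendicular(theta, np.pi / 2 - phi), atol=1e-12
        )

    def test_factors_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, np.pi / 2 - 1e-3, 1000)
        phi = rng.uniform(-np.pi, np.pi, 1000)
        for f in (scaling_parallel, scaling_perpendicular):
            s = f(theta, phi)
            assert np.all(s > 0) and np.all(s <= 1 + 1e-12)

    @pytest.mark.parametrize(
        "p_ref,p,expected",
        [
            ([0, 0, 320.0], [0, 0, 320.0], 1.0),
            ([0, 0, 320.0], [0, 0, 310.0], 320.0 / 310.0),
            ([0, 0, 320.0], [0, 0, 330.0], 320.0 / 330.0),
        ],
    )
    def test_magnification_hand_values(self, p_ref, p, expected):
        assert magnification(np.array(p_ref), np.array(p)) == pytest.approx(expected)


@pytest.fixture(scope="module")
def hemisphere_far(config):
    """Hemisphere displaced away from the camera (apex at 330 mm)."""
    scene = tw.TwinScene(
        surface=tw.SphereCap(radius=40.0, apex=(0.0, 0.0, 330.0)),
        reflectance=tw.SfdReflectance(mu_a=MU_A_TRUE, mu_s_prime=MU_S_TRUE),
    )
    return tw.render_measurement(scene, config, F_LIST)


@pytest.fixture(scope="module")
def hemisphere_near(config):
    """Hemisphere displaced toward the camera (apex at 310 mm)."""
    scene = tw.TwinScene(
        surface=tw.SphereCap(radius=40.0, apex=(0.0, 0.0, 310.0)),
        reflectance=tw.SfdReflectance(mu_a=MU_A_TRUE, mu_s_prime=MU_S_TRUE),
    )
    return tw.render_measurement(scene, config, F_LIST)


def analytic_surface(points, normals, valid, geometry):
    s = SurfaceMap(points=points, distance=np.linalg.norm(points, axis=-1), normals=normals, valid=valid)
    return compute_angle_maps(s, geometry)


class TestCorrectFrequency:
    def test_flat_at_reference_all_factors_unity(self, geometry, ray_field):
        # sample coincident with the reference plane: exact identity
        t = 320.0 / ray_field[..., 2]
        pts = ray_field * t[..., None]
        normals = np.broadcast_to([0.0, 0.0, -1.0], pts.shape).copy()
        surf = analytic_surface(pts, normals, np.ones(pts.shape[:2], bool), geometry)
        fm = correct_frequency(0.45, surf, geometry)
        assert np.allclose(fm.s_z, 1.0, atol=1e-6)
        assert np.allclose(fm.s_ang_par, 1.0, atol=1e-6)
        assert np.allclose(fm.s_ang_perp, 1.0, atol=1e-6)
        assert np.allclose(fm.f_corr, 0.45, atol=1e-6)

    def test_shifted_plane_pure_magnification(self, geometry, ray_field):
        t = 310.0 / ray_field[..., 2]
        pts = ray_field * t[..., None]
        normals = np.broadcast_to([0.0, 0.0, -1.0], pts.shape).copy()
        surf = analytic_surface(pts, normals, np.ones(pts.shape[:2], bool), geometry)
        fm = correct_frequency(0.45, surf, geometry)
        assert np.allclose(fm.s_ang_par, 1.0, atol=1e-9)
        assert np.allclose(fm.f_corr, 0.45 * 320.0 / 310.0, rtol=1e-6)

    def test_hemisphere_matches_true_local_frequency(
        self, config, geometry, pd_model, ray_field, hemisphere_measurement
    ):
        # the twin knows the exact on-surface frequency; the correction
        # (Lambertian tilt + magnification factors) tracks it closely
        surf, _ = reconstruct_surface(hemisphere_measurement.stacks, geometry, pd_model, ray_field)
        fm = correct_frequency(0.45, surf, geometry)
        ok = inner_mask(fm.valid)
        rel = np.abs(fm.f_corr - hemisphere_measurement.f_local[0.45]) / hemisphere_measurement.f_local[0.45]
        assert rel[ok].mean() < 0.02
        # decomposition invariant: f_corr = f_ref * s_z * s_ang_par
        assert np.allclose(fm.f_corr, 0.45 * fm.s_z * fm.s_ang_par, atol=1e-12)

    def test_masked_pixels_propagate(self, geometry, ray_field):
        t = 320.0 / ray_field[..., 2]
        pts = ray_field * t[..., None]
        normals = np.broadcast_to([0.0, 0.0, -1.0], pts.shape).copy()
        valid = np.ones(pts.shape[:2], bool)
        valid[:10] = False
        surf = analytic_surface(pts, normals, valid, geometry)
        fm = correct_frequency(0.45, surf, geometry)
        assert not fm.valid[:5].any()


class TestLambert:
    def test_hand_value_at_nominal_geometry(self):
        s = lambert_factor(np.deg2rad(4.0), D35, 0.0)
        assert s == pytest.approx(np.cos(np.deg2rad(4.0)) * np.cos(D35), abs=1e-12)

    def test_unity_at_normal_geometry(self):
        assert lambert_factor(0.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_monotone_decreasing_in_detection_angle(self):
        thetas = np.linspace(0, np.pi / 2 - 0.05, 50)
        s = lambert_factor(thetas, D35, 0.0)
        assert np.all(np.diff(s) < 0)


class TestMtfLut:
    @staticmethod
    def synthetic_lut():
        # 3 positions x (DC + 2 frequencies) x 2 x 2 pixels
        l = np.array([[[300.0, 300.0], [300.0, 300.0]],
                      [[310.0, 310.0], [310.0, 310.0]],
                      [[320.0, 320.0], [320.0, 320.0]]])
        f = np.zeros((3, 3, 2, 2))
        f[:, 1] = 0.2
        f[:, 2] = 0.5
        v = np.zeros((3, 3, 2, 2))
        for k in range(3):
            for j in range(3):
                v[k, j] = 1.0 + k + 0.1 * j
        ftab = np.linspace(0, 1, 11)
        return MtfLut(l_nodes=l, f_nodes=f, values=v, r_ref_table=(ftab, np.full_like(ftab, 0.9)))

    def test_query_at_node_returns_node_value(self):
        lut = self.synthetic_lut()
        val, inside = lut.query(np.full((2, 2), 310.0), np.full((2, 2), 0.5))
        assert np.allclose(val, 2.2)
        assert inside.all()

    def test_query_midway_is_bilinear_blend(self):
        lut = self.synthetic_lut()
        val, _ = lut.query(np.full((2, 2), 305.0), np.full((2, 2), 0.35))
        assert np.allclose(val, (1.1 + 1.2 + 2.1 + 2.2) / 4.0)

    def test_out_of_hull_flagged(self):
        lut = self.synthetic_lut()
        _, inside = lut.query(np.full((2, 2), 340.0), np.full((2, 2), 0.2))
        assert not inside.any()

    def test_defocus_peak_at_focal_distance(self, mtf_lut, config):
        # per-pixel AC-vs-l profile peaks at the node nearest the 316 mm
        # focal plane of the camera
        j = 5  # a mid-frequency column
        h, w = mtf_lut.l_nodes.shape[1:]
        prof = mtf_lut.values[:, j, h // 2, w // 2]
        lnod = mtf_lut.l_nodes[:, h // 2, w // 2]
        peak_l = lnod[np.argmax(prof)]
        nearest = lnod[np.argmin(np.abs(lnod - config.focal_distance))]
        assert peak_l == nearest


class TestReflectance:
    def test_reference_self_measurement_identity(
        self, reference_renders, geometry, pd_model, ray_field, mtf_lut
    ):
        # re-processing one of the LUT's own positions must reproduce the
        # reference reflectance at every pixel and frequency
        pos = reference_renders[2]
        refl, _ = process_measurement(pos["stacks"], geometry, pd_model, mtf_lut, ray_field)
        for j, f in enumerate(refl.frequencies):
            ok = refl.valid[j]
            assert ok.mean() > 0.95
            assert np.allclose(refl.r_ac[j][ok], 0.95, atol=1e-6)
        assert np.allclose(refl.r_dc[np.isfinite(refl.r_dc)], 0.95, atol=1e-6)

    def test_hemisphere_reflectance_tracks_forward_model(
        self, config, geometry, pd_model, ray_field, mtf_lut, hemisphere_measurement
    ):
        refl, _ = process_measurement(
            hemisphere_measurement.stacks, geometry, pd_model, mtf_lut, ray_field
        )
        # residuals combine the ~1 % frequency-correction model error and the
        # cosine-product Lambert model's few-percent mismatch on diagonal tilts
        for j, f in enumerate(refl.frequencies):
            if f < 0.1:
                continue
            ok = inner_mask(refl.valid[j])
            r_true = hemisphere_measurement.r_true[f]
            rel = np.abs(refl.r_ac[j] - r_true) / r_true
            assert rel[ok].mean() < 0.035

    def test_corrections_reduce_reflectance_error(
        self, config, geometry, pd_model, ray_field, mtf_lut, hemisphere_far
    ):
        # displaced hemisphere: with corrections the reflectance error is
        # strictly smaller than without, at every nonzero frequency
        meas = hemisphere_far
        errs = {}
        for tag, (fc, ic) in {"on": (True, True), "off": (False, False)}.items():
            refl, _ = process_measurement(
                meas.stacks, geometry, pd_model, mtf_lut, ray_field,
                frequency_correction=fc, intensity_correction=ic,
            )
            per_f = []
            for j, f in enumerate(refl.frequencies):
                ok = inner_mask(refl.valid[j])
                r_true_at = tw.forward_reflectance(refl.f_corr[j], MU_A_TRUE, MU_S_TRUE) \
                    if False else meas.r_true[f]
                per_f.append(float(np.mean(np.abs(refl.r_ac[j] - meas.r_true[f])[ok] / meas.r_true[f][ok])))
            errs[tag] = per_f
        for e_on, e_off in zip(errs["on"], errs["off"]):
            assert e_on < e_off

    def test_uncorrected_shifted_in_frequency_and_amplitude(
        self, config, geometry, pd_model, ray_field, mtf_lut, hemisphere_far, hemisphere_near
    ):
        # skipping the corrections leaves the reflectance at the nominal
        # (higher) frequency for a surface displaced away from the camera,
        # and systematically displaced in amplitude at both positions
        def both(meas):
            on, _ = process_measurement(meas.stacks, geometry, pd_model, mtf_lut, ray_field)
            off, _ = process_measurement(
                meas.stacks, geometry, pd_model, mtf_lut, ray_field,
                frequency_correction=False, intensity_correction=False,
            )
            return on, off

        on_far, off_far = both(hemisphere_far)
        j = len(on_far.frequencies) - 1
        ok = inner_mask(on_far.valid[j] & off_far.valid[j])
        assert np.nanmean(off_far.f_corr[j][ok]) > np.nanmean(on_far.f_corr[j][ok])

        for meas, (on, off) in ((hemisphere_far, (on_far, off_far)), (hemisphere_near, both(hemisphere_near))):
            ok = inner_mask(on.valid[j] & off.valid[j])
            f = on.frequencies[j]
            dev_on = np.abs(on.r_ac[j] - meas.r_true[f])[ok].mean()
            dev_off = np.abs(off.r_ac[j] - meas.r_true[f])[ok].mean()
            assert dev_off > 2 * dev_on

    def test_invalid_out_of_domain_policy_rejected(self, mtf_lut):
        with pytest.raises(ValueError, match="mask"):
            compute_reflectance({}, None, {}, mtf_lut, None, out_of_domain="bogus")

    def test_lut_extrapolation_masked(
        self, config, geometry, pd_model, ray_field, mtf_lut, hemisphere_measurement
    ):
        # hemisphere shifted beyond the last reference position: distances
        # past the LUT hull are masked per pixel
        scene = tw.TwinScene(
            surface=tw.SphereCap(radius=40.0, apex=(0.0, 0.0, 330.0)),
            reflectance=tw.SfdReflectance(),
        )
        meas = tw.render_measurement(scene, config, F_LIST)
        refl, surf = process_measurement(meas.stacks, geometry, pd_model, mtf_lut, ray_field)
        beyond = surf.distance > mtf_lut.l_nodes[-1] + 1e-9
        assert beyond.any()
        assert not (refl.valid[0] & beyond).any()
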