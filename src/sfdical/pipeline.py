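"""End-to-end orchestration: calibrate, reconstruct, correct, invert.

Glues the modules into the standard processing chain
(demodulate -> unwrap -> phase-to-points -> normals/angles -> frequency
correction -> reflectance -> binning -> inversion) with correction toggles
and a reproducible run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .correction import (
    FrequencyMap,
    MtfLut,
    ReflectanceMap,
    build_mtf_lut,
    compute_reflectance,
    correct_frequency,
)
from .demodulation import DemodResult, demodulate, unwrap_phase
from .geom_calib import (
    CalibrationTarget,
    SystemGeometry,
    build_ray_fields,
    build_system_geometry,
    calibrate_device,
    detect_grid,
    projector_points_from_phase,
)
from .inversion import invert_map
from .surface import PhaseDistanceModel, SurfaceMap, compute_angle_maps, fit_phase_distance, phase_to_points

__all__ = [
    "RunConfig",
    "unwrap_ladder",
    "calibrate_from_poses",
    "reconstruct_surface",
    "build_intensity_calibration",
    "process_measurement",
    "run_pipeline",
]


def unwrap_ladder(demods: dict[float, DemodResult]) -> dict[float, np.ndarray]:
    """Absolute temporal unwrapping across an ascending frequency ladder.

    The lowest acquired frequency must stay below one wrap across the
    field so its wrapped phase is already absolute; each higher frequency
    is then unwrapped against the scaled previous level.
    """
    fs = sorted(f for f in demods if f > 0)  # f = 0 carries no phase
    if not fs:
        raise ValueError("no demodulation results with nonzero frequency given")
    out: dict[float, np.ndarray] = {}
    prev_f, prev_phase = None, None
    for f in fs:
        dm = demods[f]
        if prev_phase is None:
            out[f] = dm.phase_wrapped.copy()
        else:
            unwrapped, _ = unwrap_phase(
                dm.phase_wrapped, dm.validity_mask, anchor=prev_phase, anchor_scale=f / prev_f
            )
            out[f] = unwrapped
        dm.phase_unwrapped = out[f]
        prev_f, prev_phase = f, out[f]
    return out


def calibrate_from_poses(
    pose_renders: list,
    target: CalibrationTarget,
    camera_size: tuple[int, int],
    projector_size: tuple[int, int],
    n_radial_terms: int = 2,
    pattern_direction: str = "rows",
) -> tuple[SystemGeometry, dict]:
    """Full step-1 geometric calibration from rendered/acquired target poses.

    Each pose supplies a DC image and DMD row/column phase-ladder stacks;
    the circle grid is detected on the DC image, projector correspondences
    are decoded from the unwrapped phases, and both pinhole models are
    solved and unified.
    """
    obj_list, cam_list, pro_list = [], [], []
    details: dict = {"poses": []}
    for render in pose_renders:
        points, meta = detect_grid(render.dc_image, target)
        demods_u = {f: demodulate(s) for f, s in render.stacks_u.items()}
        demods_v = {f: demodulate(s) for f, s in render.stacks_v.items()}
        pu = unwrap_ladder(demods_u)
        pv = unwrap_ladder(demods_v)
        f_u, f_v = max(pu), max(pv)
        dmd, in_range = projector_points_from_phase(
            pu[f_u], pv[f_v], points, (projector_size[0], projector_size[1], f_u, f_v)
        )
        keep = in_range
        obj_list.append(target.object_points()[keep])
        cam_list.append(points[keep])
        pro_list.append(dmd[keep])
        details["poses"].append({"grid": meta, "n_markers": int(keep.sum())})
    cam_result = calibrate_device(obj_list, cam_list, camera_size, n_radial_terms, role="camera")
    pro_result = calibrate_device(obj_list, pro_list, projector_size, n_radial_terms, role="projector")
    geometry = build_system_geometry(cam_result, pro_result, obj_list, pattern_direction)
    details["camera_rms_px"] = cam_result.rms_px
    details["projector_rms_px"] = pro_result.rms_px
    return geometry, details


def reconstruct_surface(
    stacks: dict,
    geometry: SystemGeometry,
    model: PhaseDistanceModel,
    ray_field: np.ndarray | None = None,
    k_neighbors: int = 16,
) -> tuple[SurfaceMap, dict[float, DemodResult]]:
    """Demodulate, unwrap, convert phase to 3D and attach normals/angles.

    The topography is taken from the highest acquired frequency (best
    phase-to-distance sensitivity), absolutely unwrapped via the ladder.
    """
    if ray_field is None:
        ray_field = build_ray_fields(geometry)["camera"]
    demods = {f: demodulate(s) for f, s in stacks.items()}
    phases = unwrap_ladder(demods)
    # topography frequency: the highest with widely valid modulation (high
    # frequencies can be wiped out by defocus away from the focal plane)
    fracs = {f: float(np.mean(demods[f].validity_mask)) for f in phases}
    good = [f for f in phases if fracs[f] >= 0.5]
    f_top = max(good) if good else max(fracs, key=fracs.get)
    surface = phase_to_points(model, phases[f_top], ray_field, phase_frequency=f_top)
    if demods[f_top].validity_mask is not None:
        surface.valid = surface.valid & demods[f_top].validity_mask
    surface = compute_angle_maps(surface, geometry, k_neighbors=k_neighbors)
    return surface, demods


def build_intensity_calibration(
    reference_positions: list[dict],
    geometry: SystemGeometry,
    model: PhaseDistanceModel,
    r_ref_table,
    ray_field: np.ndarray | None = None,
) -> MtfLut:
    """Step-2 intensity calibration: the per-pixel MTF look-up hypersurface."""
    if ray_field is None:
        ray_field = build_ray_fields(geometry)["camera"]
    measurements = []
    for pos in reference_positions:
        surface, demods = reconstruct_surface(pos["stacks"], geometry, model, ray_field)
        measurements.append({"surface": surface, "demods": demods})
    return build_mtf_lut(measurements, r_ref_table, geometry)


def process_measurement(
    stacks: dict,
    geometry: SystemGeometry,
    model: PhaseDistanceModel,
    lut: MtfLut,
    ray_field: np.ndarray | None = None,
    frequency_correction: bool = True,
    intensity_correction: bool = True,
) -> tuple[ReflectanceMap, SurfaceMap]:
    """Reconstruct a sample measurement and compute its diffuse reflectance.

    With ``frequency_correction`` off, the nominal reference-plane
    frequency is used everywhere; with ``intensity_correction`` off, the
    Lambert normalization is skipped and the reference look-up is taken at
    the reference-plane distance (the classic flat-sample calibration).
    """
    if ray_field is None:
        ray_field = build_ray_fields(geometry)["camera"]
    surface, demods = reconstruct_surface(stacks, geometry, model, ray_field)
    f_list = sorted(f for f in demods if f > 0)
    freq_maps: dict[float, FrequencyMap] = {}
    ones = np.ones(surface.distance.shape)
    for f in f_list:
        if frequency_correction:
            freq_maps[f] = correct_frequency(f, surface, geometry)
        else:
            freq_maps[f] = FrequencyMap(
                f_ref=f,
                f_corr=np.full(surface.distance.shape, f),
                s_ang_par=ones,
                s_ang_perp=ones,
                s_z=ones,
                valid=surface.valid.copy(),
            )
    if intensity_correction:
        refl = compute_reflectance({f: demods[f] for f in demods}, surface, freq_maps, lut, geometry)
    else:
        from .correction import reference_points_for

        flat_surface = SurfaceMap(
            points=reference_points_for(surface.points, geometry),
            distance=np.linalg.norm(reference_points_for(surface.points, geometry), axis=-1),
            normals=np.broadcast_to(
                -geometry.reference_plane_normal, surface.points.shape
            ).copy(),
            valid=surface.valid.copy(),
        )
        refl = compute_reflectance(
            {f: demods[f] for f in demods}, flat_surface, freq_maps, lut, geometry,
            apply_lambert=False,
        )
        refl.provenance["corrections"] = ["mtf_lut_flat_reference"]
    return refl, surface


# ---------------------------------------------------------------------------
# full twin-backed run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full synthetic end-to-end run."""

    f_list: tuple[float, ...] = (0.01, 0.098, 0.186, 0.274, 0.362, 0.45)
    n_phases: int = 3
    bin_factor: int = 16
    n_virtual_planes: int = 10
    n_reference_positions: int = 6
    reference_f_list: tuple[float, ...] = (0.0, 0.01, 0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875, 1.0)
    frequency_correction: bool = True
    intensity_correction: bool = True
    use_true_geometry: bool = True  # skip target-based calibration, use twin truth
    n_calibration_poses: int = 8
    seed: int = 0
    camera_shape: tuple[int, int] = (128, 128)
    projector_shape: tuple[int, int] = (128, 72)
    noise_mult: float = 0.0
    noise_sigma: float = 0.0
    sample_mu_a: float = 0.18
    sample_mu_s_prime: float = 1.98
    sample_radius: float = 40.0
    sample_z_offsets: tuple[float, ...] = (0.0,)
    outputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.f_list) == 0:
            raise ValueError("f_list must not be empty")


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic chain and return results plus a manifest."""
    from . import twin as tw

    config = tw.default_config(
        camera_shape=cfg.camera_shape,
        projector_shape=cfg.projector_shape,
        noise_mult=cfg.noise_mult,
        noise_sigma=cfg.noise_sigma,
    )
    config.seed = cfg.seed
    geometry = tw.truth_geometry(config)
    if not cfg.use_true_geometry:
        target, renders = tw.render_calibration_set(
            config, poses=tw.DEFAULT_CALIBRATION_POSES[: cfg.n_calibration_poses]
        )
        geometry, _ = calibrate_from_poses(
            renders, target, config.camera_truth.intrinsics.image_size,
            config.projector_truth.intrinsics.image_size,
        )
    ray_field = build_ray_fields(geometry)["camera"]
    model = fit_phase_distance(geometry, n_planes=cfg.n_virtual_planes, ray_field=ray_field)

    refs = tw.render_reference_stack(
        config, n_positions=cfg.n_reference_positions, f_list=cfg.reference_f_list
    )
    f_tab = np.linspace(0.0, 1.0, 51)
    albedo = 0.95
    lut = build_intensity_calibration(
        refs, geometry, model, (f_tab, np.full_like(f_tab, albedo)), ray_field
    )

    manifest = {"config": {k: str(v) for k, v in vars(cfg).items()}, "stages": {}}
    results = []
    for dz in cfg.sample_z_offsets:
        scene = tw.TwinScene(
            surface=tw.SphereCap(radius=cfg.sample_radius, apex=(0.0, 0.0, config.reference_z + dz)),
            reflectance=tw.SfdReflectance(mu_a=cfg.sample_mu_a, mu_s_prime=cfg.sample_mu_s_prime),
        )
        meas = tw.render_measurement(scene, config, cfg.f_list, n_phases=cfg.n_phases,
                                     salt=1000 + int(dz * 10))
        refl, surface = process_measurement(
            meas.stacks, geometry, model, lut, ray_field,
            frequency_correction=cfg.frequency_correction,
            intensity_correction=cfg.intensity_correction,
        )
        props = invert_map(refl.r_ac, refl.f_corr, refl.valid, bin_factor=cfg.bin_factor)
        results.append({"z_offset": dz, "reflectance": refl, "surface": surface, "properties": props})
        manifest["stages"][f"sample_dz_{dz:+.1f}"] = {
            "r_ac_checksum": _checksum(refl.r_ac),
            "mu_s_prime_mean": float(np.nanmean(props["mu_s_prime"])),
            "mu_a_mean": float(np.nanmean(props["mu_a"])),
        }
    manifest["stages"]["calibration"] = {
        "reprojection_rms": geometry.reprojection_rms,
        "phase_distance_max_residual_mm": model.max_fit_residual_mm,
    }
    return {"geometry": geometry, "model": model, "lut": lut, "results": results, "manifest": manifest}


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
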