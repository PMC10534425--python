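"""Digital twin of the SFDI acquisition chain.

Renders synthetic camera images of projected fringe patterns on parametric
scenes (planes, spherical caps, the printed calibration target) from
ground-truth pinhole devices, including lens distortion, oblique
projection, illumination falloff, Lambertian foreshortening, a
defocus-dependent MTF roll-off and sensor noise.  Every render also emits
the ground truth (3D points, normals, local fringe frequency, true
reflectance), so the full calibration/correction/inversion pipeline can be
exercised and checked without hardware.

Default geometry mirrors a tabletop multispectral SFDI setup: a camera
viewing a 21.6 mm x 21.6 mm field at a 320 mm reference distance and a
projector at 35 deg oblique incidence, with sinusoidal patterns of
0..1 mm^-1 and >= 3 phase shifts.  The chip sizes default to 256 x 256
(camera) and 256 x 144 (projector) - a downscaled stand-in for the
2048 x 2048 sCMOS / 1920 x 1080 DMD hardware that keeps all metric
quantities (field size, distances, angles, frequencies) at full scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core_model import Distortion, Intrinsics, PinholeDevice, Pose, pixel_ray, project_point
from .demodulation import FringeStack
from .geom_calib import CalibrationTarget, SystemGeometry
from .inversion import forward_reflectance

__all__ = [
    "TwinConfig",
    "TwinScene",
    "Plane",
    "SphereCap",
    "TargetBoard",
    "LambertianAlbedo",
    "SfdReflectance",
    "default_config",
    "truth_geometry",
    "board_pose",
    "render_measurement",
    "render_calibration_pose",
    "render_reference_stack",
    "render_pattern_image",
]

PHASE_SHIFTS_3 = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


# ---------------------------------------------------------------------------
# scene description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plane:
    point: tuple[float, float, float] = (0.0, 0.0, 320.0)
    normal: tuple[float, float, float] = (0.0, 0.0, -1.0)  # toward the camera


@dataclass(frozen=True)
class SphereCap:
    """Spherical cap bulging toward the camera; ``apex`` is its nearest point."""

    radius: float = 40.0
    apex: tuple[float, float, float] = (0.0, 0.0, 320.0)

    @property
    def center(self) -> np.ndarray:
        a = np.asarray(self.apex, dtype=float)
        return a + np.array([0.0, 0.0, self.radius])


@dataclass(frozen=True)
class TargetBoard:
    target: CalibrationTarget
    pose: Pose  # global -> board-local; the board is the local z = 0 plane
    albedo_bright: float = 0.95
    albedo_dark: float = 0.15
    edge_width_mm: float = 0.12  # anti-aliasing width of the printed edges


@dataclass(frozen=True)
class LambertianAlbedo:
    albedo: float = 0.95


@dataclass(frozen=True)
class SfdReflectance:
    """Turbid-medium reflectance from the semi-infinite diffusion model."""

    mu_a: float = 0.18
    mu_s_prime: float = 1.98
    n: float = 1.52
    g: float = 0.6


@dataclass
class TwinScene:
    surface: Plane | SphereCap | TargetBoard
    reflectance: LambertianAlbedo | SfdReflectance = field(default_factory=LambertianAlbedo)


@dataclass
class TwinConfig:
    """Ground-truth devices and radiometric model of the twin."""

    camera_truth: PinholeDevice
    projector_truth: PinholeDevice
    reference_z: float = 320.0
    volume_half_depth: float = 12.5  # mm; the paper-scale 25 mm calibrated depth
    field_half_width: float = 10.8  # mm at the reference plane
    focal_distance: float = 316.0  # camera focal plane, mm
    defocus_slope: float = 0.03  # blur sigma (mm) per mm of defocus
    noise_sigma: float = 0.0  # additive Gaussian, intensity units
    noise_mult: float = 0.0  # multiplicative Gaussian, relative
    pattern_direction: str = "rows"
    seed: int = 0

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed * 9973 + salt) % (2**31))


def _look_at_pose(center: np.ndarray, target: np.ndarray) -> Pose:
    z = np.asarray(target, float) - np.asarray(center, float)
    z = z / np.linalg.norm(z)
    x = np.cross([0.0, 1.0, 0.0], z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    r = np.stack([x, y, z])  # rows = device axes in global coords
    return Pose(r, -r @ np.asarray(center, float))


def default_config(
    camera_shape: tuple[int, int] = (256, 256),
    projector_shape: tuple[int, int] = (256, 144),
    oblique_deg: float = 35.0,
    projector_distance: float = 380.0,
    reference_z: float = 320.0,
    field_width: float = 21.6,
    camera_distortion: Distortion = Distortion(radial=(-0.05, 0.0), tangential=(5e-4, -5e-4)),
    projector_distortion: Distortion = Distortion(radial=(0.08, 0.0), tangential=(-3e-4, 2e-4)),
    **kwargs,
) -> TwinConfig:
    """Twin with the nominal tabletop geometry (35 deg projection, 320 mm)."""
    n_cam = camera_shape[0]
    fx_cam = n_cam * reference_z / field_width
    cam = PinholeDevice(
        Intrinsics(
            fx=fx_cam,
            fy=fx_cam,
            cx=(camera_shape[0] - 1) / 2.0,
            cy=(camera_shape[1] - 1) / 2.0,
            image_size=camera_shape,
        ),
        camera_distortion,
        Pose(),
        role="camera",
    )
    th = np.deg2rad(oblique_deg)
    center = np.array([0.0, projector_distance * np.sin(th), reference_z - projector_distance * np.cos(th)])
    pose = _look_at_pose(center, np.array([0.0, 0.0, reference_z]))
    # frustum sized to the nominal 56.8 x 27.9 mm illuminated area
    fx_pro = projector_shape[0] * projector_distance / 56.8
    fy_pro = projector_shape[1] * projector_distance / 27.9
    pro = PinholeDevice(
        Intrinsics(
            fx=fx_pro,
            fy=fy_pro,
            cx=(projector_shape[0] - 1) / 2.0,
            cy=(projector_shape[1] - 1) / 2.0,
            image_size=projector_shape,
        ),
        projector_distortion,
        pose,
        role="projector",
    )
    half_field = field_width / 2.0
    return TwinConfig(
        camera_truth=cam,
        projector_truth=pro,
        reference_z=reference_z,
        field_half_width=half_field,
        **kwargs,
    )


def truth_geometry(config: TwinConfig) -> SystemGeometry:
    """SystemGeometry built directly from the ground-truth devices."""
    m = config.field_half_width * 1.1
    return SystemGeometry(
        camera=config.camera_truth,
        projector=config.projector_truth,
        reference_plane_point=np.array([0.0, 0.0, config.reference_z]),
        reference_plane_normal=np.array([0.0, 0.0, 1.0]),
        volume_min=np.array([-m, -m, config.reference_z - config.volume_half_depth]),
        volume_max=np.array([m, m, config.reference_z + config.volume_half_depth]),
        pattern_direction=config.pattern_direction,
        metadata={"source": "twin ground truth"},
    )


def board_pose(
    target: CalibrationTarget,
    z: float = 320.0,
    tilt_deg: tuple[float, float] = (0.0, 0.0),
    offset: tuple[float, float] = (0.0, 0.0),
    roll_deg: float = 0.0,
) -> Pose:
    """Pose placing the board center at (offset, z), tilted about x/y axes."""
    tx, ty = np.deg2rad(tilt_deg[0]), np.deg2rad(tilt_deg[1])
    rz = np.deg2rad(roll_deg)
    def rot_x(a):
        return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
    def rot_y(a):
        return np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])
    def rot_z(a):
        return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    r = rot_z(rz) @ rot_x(tx) @ rot_y(ty)
    m = np.array(
        [(target.n_cols - 1) * target.spacing / 2.0, (target.n_rows - 1) * target.spacing / 2.0, 0.0]
    )
    c = np.array([offset[0], offset[1], z])
    t = m - r @ c
    return Pose(r, t)


# ---------------------------------------------------------------------------
# ray tracing and radiometry
# ---------------------------------------------------------------------------

@dataclass
class TraceResult:
    points: np.ndarray  # (H, W, 3)
    distance: np.ndarray
    normals: np.ndarray
    valid: np.ndarray


def _camera_rays(config: TwinConfig) -> np.ndarray:
    n_col, n_row = config.camera_truth.intrinsics.image_size
    u, v = np.meshgrid(np.arange(n_col), np.arange(n_row))
    px = np.stack([u.ravel(), v.ravel()], axis=1).astype(float)
    rays = pixel_ray(config.camera_truth, px, check_bounds=False)
    return rays.reshape(n_row, n_col, 3)


def _trace(scene: TwinScene, config: TwinConfig, rays: np.ndarray) -> TraceResult:
    d = rays.reshape(-1, 3)
    surf = scene.surface
    if isinstance(surf, Plane):
        n0 = np.asarray(surf.normal, float)
        n0 = n0 / np.linalg.norm(n0)
        denom = d @ n0
        ok = np.abs(denom) > 1e-12
        t = (np.asarray(surf.point, float) @ n0) / np.where(ok, denom, 1.0)
        ok &= t > 0
        p = d * t[:, None]
        n = np.broadcast_to(-n0 if n0[2] > 0 else n0, p.shape).copy()
    elif isinstance(surf, SphereCap):
        c = surf.center
        b = d @ c
        disc = b * b - (c @ c - surf.radius**2)
        ok = disc > 0
        t = b - np.sqrt(np.where(ok, disc, 0.0))
        ok &= t > 0
        p = d * t[:, None]
        n = (p - c) / surf.radius
    elif isinstance(surf, TargetBoard):
        pose = surf.pose
        n0 = pose.rotation[2]  # board-local z axis in global coords
        denom = d @ n0
        ok = np.abs(denom) > 1e-12
        t = -pose.translation[2] / np.where(ok, denom, 1.0)
        ok &= t > 0
        p = d * t[:, None]
        n = np.broadcast_to(n0 if n0[2] < 0 else -n0, p.shape).copy()
    else:  # pragma: no cover
        raise TypeError(f"unsupported surface {type(surf)}")
    h, w = rays.shape[:2]
    res = TraceResult(
        points=p.reshape(h, w, 3),
        distance=t.reshape(h, w),
        normals=n.reshape(h, w, 3),
        valid=ok.reshape(h, w),
    )
    frac = float(res.valid.mean())
    if frac < 0.9:
        warnings.warn(f"scene covers only {frac:.0%} of the camera image", stacklevel=3)
    return res


def _illumination(points: np.ndarray, config: TwinConfig) -> np.ndarray:
    """Inverse-square falloff and cos^4 vignetting of the projection optics."""
    c_p = config.projector_truth.pose.center
    axis = config.projector_truth.pose.rotation[2]
    d = points - c_p
    dist = np.linalg.norm(d, axis=-1)
    cosang = np.clip((d @ axis) / dist, 0.0, 1.0)
    ref = np.linalg.norm(np.array([0.0, 0.0, config.reference_z]) - c_p)
    return (ref / dist) ** 2 * cosang**4


def _cos_incidence(points: np.ndarray, normals: np.ndarray, config: TwinConfig) -> np.ndarray:
    to_pro = config.projector_truth.pose.center - points
    to_pro /= np.linalg.norm(to_pro, axis=-1, keepdims=True)
    return np.clip(np.einsum("...i,...i->...", to_pro, normals), 0.0, 1.0)


def _defocus_mtf(distance: np.ndarray, f_metric: np.ndarray, config: TwinConfig) -> np.ndarray:
    """Gaussian blur MTF with kernel width growing linearly with defocus."""
    sigma = config.defocus_slope * np.abs(distance - config.focal_distance)
    return np.exp(-2.0 * np.pi**2 * sigma**2 * np.asarray(f_metric) ** 2)


def _local_frequency(
    points: np.ndarray, normals: np.ndarray, f_ref: float, config: TwinConfig
) -> np.ndarray:
    """Exact metric on-surface frequency of the predistorted pattern.

    The pattern's phase field is phi(X) = 2 pi f c(X) with c the
    pattern-axis coordinate of the reference-plane piercing point of the
    projector ray through X; its in-surface gradient magnitude over 2 pi is
    the local frequency.
    """
    c_p = config.projector_truth.pose.center
    z_ref = config.reference_z
    x = points
    s = (z_ref - c_p[2]) / (x[..., 2] - c_p[2])
    if config.pattern_direction == "rows":
        gy = s
        gz = -s * (x[..., 1] - c_p[1]) / (x[..., 2] - c_p[2])
        grad = np.stack([np.zeros_like(s), gy, gz], axis=-1)
    else:
        gx = s
        gz = -s * (x[..., 0] - c_p[0]) / (x[..., 2] - c_p[2])
        grad = np.stack([gx, np.zeros_like(s), gz], axis=-1)
    grad = grad * f_ref
    gn = np.einsum("...i,...i->...", grad, normals)
    tang = grad - gn[..., None] * normals
    return np.linalg.norm(tang, axis=-1)


def _albedo(scene: TwinScene, points: np.ndarray) -> np.ndarray | None:
    refl = scene.reflectance
    if isinstance(refl, SfdReflectance):
        return None
    if isinstance(scene.surface, TargetBoard):
        board = scene.surface
        local = board.pose.to_device(points.reshape(-1, 3))[:, :2]
        tgt = board.target
        a = tgt.spacing
        gi = np.clip(np.round(local[:, 0] / a), 0, tgt.n_cols - 1)
        gj = np.clip(np.round(local[:, 1] / a), 0, tgt.n_rows - 1)
        dist = np.hypot(local[:, 0] - gi * a, local[:, 1] - gj * a)
        radius = np.full(len(dist), tgt.circle_diameter / 2.0)
        for mi, mj in tgt.marker_nodes:
            is_marker = (gi == mi) & (gj == mj)
            radius[is_marker] = tgt.marker_scale * tgt.circle_diameter / 2.0
        # smooth printed edge
        tgt_cov = np.clip((radius - dist) / board.edge_width_mm + 0.5, 0.0, 1.0)
        alb = board.albedo_bright + (board.albedo_dark - board.albedo_bright) * tgt_cov
        return alb.reshape(points.shape[:-1])
    return np.full(points.shape[:-1], refl.albedo)


def _reflectance(scene: TwinScene, points: np.ndarray, f_loc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(R_dc, R_ac) per pixel for the scene's reflectance model."""
    refl = scene.reflectance
    if isinstance(refl, SfdReflectance):
        r_dc = forward_reflectance(0.0, refl.mu_a, refl.mu_s_prime, n=refl.n)
        r_ac = forward_reflectance(f_loc, refl.mu_a, refl.mu_s_prime, n=refl.n)
        return np.full(f_loc.shape, r_dc), r_ac
    alb = _albedo(scene, points)
    return alb, alb.copy()


def _add_noise(img: np.ndarray, config: TwinConfig, rng: np.random.Generator) -> np.ndarray:
    out = img
    if config.noise_mult > 0:
        out = out * (1.0 + config.noise_mult * rng.standard_normal(img.shape))
    if config.noise_sigma > 0:
        out = out + config.noise_sigma * rng.standard_normal(img.shape)
    return out


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

@dataclass
class MeasurementRender:
    """Fringe stacks plus the ground truth of one twin measurement."""

    stacks: dict  # {f_nominal: FringeStack}
    points: np.ndarray
    distance: np.ndarray
    normals: np.ndarray
    valid: np.ndarray
    f_local: dict  # {f_nominal: (H, W) true local frequency}
    phase: dict  # {f_nominal: (H, W) true absolute phase}
    r_true: dict  # {f_nominal: (H, W) true AC reflectance at f_local}
    r_dc_true: np.ndarray
    cos_incidence: np.ndarray
    illumination: np.ndarray


def render_measurement(
    scene: TwinScene,
    config: TwinConfig,
    f_list: tuple[float, ...],
    n_phases: int = 3,
    phase_fn: Callable | None = None,
    salt: int = 0,
) -> MeasurementRender:
    """Render phase-shifted predistorted-fringe stacks of a scene.

    ``phase_fn(points, f)`` may replace the analytic predistorted-pattern
    phase field (e.g. to feed explicitly generated DMD images through the
    chain).  Ground-truth channels are emitted alongside the images.
    """
    rays = _camera_rays(config)
    tr = _trace(scene, config, rays)
    geom = truth_geometry(config)
    illum = _illumination(tr.points, config)
    cos_inc = _cos_incidence(tr.points, tr.normals, config)
    shifts = tuple(2.0 * np.pi * k / n_phases for k in range(n_phases))
    if n_phases == 3:
        shifts = PHASE_SHIFTS_3
    rng = config.rng(salt)
    stacks, f_local, phases, r_true = {}, {}, {}, {}
    r_dc_map = None
    for f in f_list:
        phi = phase_fn(tr.points, f) if phase_fn else geom.pattern_phase_at(tr.points, f)
        f_loc = _local_frequency(tr.points, tr.normals, f, config)
        r_dc, r_ac = _reflectance(scene, tr.points, f_loc)
        mtf = _defocus_mtf(tr.distance, f_loc, config)
        base = illum * cos_inc
        frames = []
        for delta in shifts:
            img = base * 0.5 * (r_dc + r_ac * mtf * np.cos(phi + delta))
            img = np.where(tr.valid, img, 0.0)
            frames.append(_add_noise(img, config, rng))
        stacks[f] = FringeStack(
            images=np.stack(frames),
            phase_shifts=shifts,
            nominal_frequency=f,
            pattern_direction=config.pattern_direction,
        )
        f_local[f] = f_loc
        phases[f] = phi
        r_true[f] = r_ac
        r_dc_map = r_dc
    return MeasurementRender(
        stacks=stacks,
        points=tr.points,
        distance=tr.distance,
        normals=tr.normals,
        valid=tr.valid,
        f_local=f_local,
        phase=phases,
        r_true=r_true,
        r_dc_true=r_dc_map,
        cos_incidence=cos_inc,
        illumination=illum,
    )


@dataclass
class CalibrationPoseRender:
    """One target pose: DC image, DMD-phase stacks, ground-truth correspondences."""

    dc_image: np.ndarray
    stacks_u: dict  # {f_col: FringeStack}, phase encodes the DMD column
    stacks_v: dict  # {f_row: FringeStack}, phase encodes the DMD row
    marker_obj: np.ndarray  # (N, 2) object points, mm
    marker_cam_px: np.ndarray  # (N, 2) ground-truth camera pixels
    marker_dmd_px: np.ndarray  # (N, 2) ground-truth DMD pixels
    board: TargetBoard


def render_calibration_pose(
    board: TargetBoard,
    config: TwinConfig,
    f_ladder: tuple[float, ...] = (0.25, 2.0, 10.0),
    n_phases: int = 3,
    salt: int = 100,
) -> CalibrationPoseRender:
    """Render the circle-grid board under DMD row/column phase patterns.

    The pattern phase at DMD pixel (u, v) is ``u f_col 4 pi / N_col`` (and
    the row analogue); the ladder of pixel-based frequencies enables
    absolute temporal unwrapping (the lowest stays below one wrap across
    the chip).
    """
    rays = _camera_rays(config)
    scene = TwinScene(surface=board, reflectance=LambertianAlbedo())
    tr = _trace(scene, config, rays)
    illum = _illumination(tr.points, config)
    cos_inc = _cos_incidence(tr.points, tr.normals, config)
    alb = _albedo(scene, tr.points)
    base = illum * cos_inc * alb
    n_col, n_row = config.projector_truth.intrinsics.image_size

    flat = tr.points.reshape(-1, 3)
    ok = tr.valid.ravel()
    dmd = np.zeros((len(flat), 2))
    dmd[ok] = project_point(config.projector_truth, flat[ok])
    u_dlp = dmd[:, 0].reshape(tr.valid.shape)
    v_dlp = dmd[:, 1].reshape(tr.valid.shape)

    rng = config.rng(salt)
    shifts = PHASE_SHIFTS_3 if n_phases == 3 else tuple(2 * np.pi * k / n_phases for k in range(n_phases))

    def make_stacks(coord: np.ndarray, n_pix: int) -> dict:
        out = {}
        for fc in f_ladder:
            phi = coord * fc * 4.0 * np.pi / n_pix
            frames = []
            for delta in shifts:
                img = base * (0.5 + 0.5 * np.cos(phi + delta))
                img = np.where(tr.valid, img, 0.0)
                frames.append(_add_noise(img, config, rng))
            out[fc] = FringeStack(
                images=np.stack(frames), phase_shifts=shifts, nominal_frequency=fc
            )
        return out

    stacks_u = make_stacks(u_dlp, n_col)
    stacks_v = make_stacks(v_dlp, n_row)
    dc_image = _add_noise(np.where(tr.valid, base, 0.0), config, rng)

    # ground-truth correspondences of all grid nodes
    obj = board.target.object_points()
    obj3 = np.column_stack([obj, np.zeros(len(obj))])
    glob = board.pose.to_global(obj3)
    cam_px = project_point(config.camera_truth, glob)
    dmd_px = project_point(config.projector_truth, glob)
    n_cols_cam, n_rows_cam = config.camera_truth.intrinsics.image_size
    inside = (
        (cam_px[:, 0] > 2) & (cam_px[:, 0] < n_cols_cam - 3)
        & (cam_px[:, 1] > 2) & (cam_px[:, 1] < n_rows_cam - 3)
    )
    if not np.all(inside):
        raise ValueError(
            f"calibration board pose leaves {int((~inside).sum())} markers outside the camera frustum"
        )
    return CalibrationPoseRender(
        dc_image=dc_image,
        stacks_u=stacks_u,
        stacks_v=stacks_v,
        marker_obj=obj,
        marker_cam_px=cam_px,
        marker_dmd_px=dmd_px,
        board=board,
    )


# (tilt_x, tilt_y) deg, z offset mm: a pose diversity that keeps the 18 mm
# board inside the 21.6 mm field while spanning the calibrated depth
DEFAULT_CALIBRATION_POSES = (
    ((0, 0), 0.0),
    ((25, 0), -6.0),
    ((-25, 0), 6.0),
    ((0, 25), -3.0),
    ((0, -25), 3.0),
    ((20, 20), 0.0),
    ((-20, 20), 4.0),
    ((20, -20), -4.0),
    ((20, 0), 11.0),
    ((-20, 0), -11.0),
)


def render_calibration_set(
    config: TwinConfig,
    target: CalibrationTarget | None = None,
    poses: tuple = DEFAULT_CALIBRATION_POSES,
) -> tuple[CalibrationTarget, list[CalibrationPoseRender]]:
    """Render the default diverse set of calibration-target poses."""
    if target is None:
        target = CalibrationTarget()
    renders = [
        render_calibration_pose(
            TargetBoard(target, board_pose(target, z=config.reference_z + dz, tilt_deg=tilt)),
            config,
            salt=100 + 7 * k,
        )
        for k, (tilt, dz) in enumerate(poses)
    ]
    return target, renders


# nine nominal reference frequencies spanning 0..1 mm^-1 plus a wrap-free
# 0.01 mm^-1 anchor for absolute temporal unwrapping
REFERENCE_F_LIST = (0.0, 0.01, 0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875, 1.0)


def render_reference_stack(
    config: TwinConfig,
    n_positions: int = 6,
    f_list: tuple[float, ...] = REFERENCE_F_LIST,
    albedo: float = 0.95,
    margin: float = 1.0,
    salt: int = 200,
    z_range: tuple[float, float] | None = None,
) -> list[dict]:
    """Reference-standard (white Lambertian plane) measurements for the MTF LUT.

    Renders ``n_positions`` z-planes evenly distributed over the calibrated
    volume at ``f_list`` frequencies (``z_range`` overrides the volume, e.g.
    with the z-extent of a target-calibrated geometry).  Returns one dict
    per position with the z value, the rendered stacks and the ground-truth
    render object.
    """
    if z_range is None:
        z_lo = config.reference_z - config.volume_half_depth + margin
        z_hi = config.reference_z + config.volume_half_depth - margin
    else:
        z_lo, z_hi = z_range[0] + margin, z_range[1] - margin
    out = []
    for k, z in enumerate(np.linspace(z_lo, z_hi, n_positions)):
        scene = TwinScene(
            surface=Plane(point=(0.0, 0.0, float(z))), reflectance=LambertianAlbedo(albedo)
        )
        render = render_measurement(scene, config, tuple(f_list), salt=salt + k)
        out.append({"z": float(z), "render": render, "stacks": render.stacks})
    return out


def render_pattern_image(
    dmd_image: np.ndarray,
    scene: TwinScene,
    config: TwinConfig,
    salt: int = 300,
) -> np.ndarray:
    """Project an explicit DMD intensity image onto a scene (one camera frame).

    Used to close the loop on predistorted-pattern generation: the DMD
    image is sampled bilinearly at the (distorted) DMD pixel that
    illuminates each camera pixel's surface point.
    """
    from scipy import ndimage

    rays = _camera_rays(config)
    tr = _trace(scene, config, rays)
    illum = _illumination(tr.points, config)
    cos_inc = _cos_incidence(tr.points, tr.normals, config)
    alb = _albedo(scene, tr.points)
    if alb is None:
        alb = np.ones(tr.distance.shape)
    flat = tr.points.reshape(-1, 3)
    ok = tr.valid.ravel()
    dmd = np.zeros((len(flat), 2))
    dmd[ok] = project_point(config.projector_truth, flat[ok])
    pattern = ndimage.map_coordinates(
        np.asarray(dmd_image, float), np.stack([dmd[:, 1], dmd[:, 0]]), order=1, mode="constant"
    ).reshape(tr.distance.shape)
    img = illum * cos_inc * alb * pattern
    img = np.where(tr.valid, img, 0.0)
    return _add_noise(img, config, config.rng(salt))
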