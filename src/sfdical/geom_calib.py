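"""Step-1 geometric calibration of the camera-projector pair.

From snapshots of a planar circle-grid target in several orientations the
camera is calibrated directly; the projector is calibrated through the same
planar solver after phase-shifted patterns along DMD rows and columns
encode, at every detected marker, the DMD pixel that illuminates it.  Both
devices are then expressed in a single global frame (the camera frame), a
reference plane is defined in the center of the calibrated volume, and
per-pixel ray fields plus predistorted fringe patterns are derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .core_model import PinholeDevice, Pose, pixel_ray
from .zhang import CalibrationResult, calibrate_pinhole, estimate_homography

__all__ = [
    "CalibrationTarget",
    "CorrespondenceSet",
    "SystemGeometry",
    "GridDetectionError",
    "detect_grid",
    "projector_points_from_phase",
    "calibrate_device",
    "unify_frames",
    "define_reference_plane",
    "generate_predistorted_patterns",
    "build_ray_fields",
]


class GridDetectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationTarget:
    """Planar grid of dark circles; three enlarged markers fix origin and axes.

    Markers sit at grid nodes (0,0), (n_cols-1,0) and (0,n_rows-1); the first
    defines the origin, the others the +u and +v axes of the object frame.
    Object coordinates are in mm (grid units times the spacing ``a``).
    """

    n_cols: int = 10
    n_rows: int = 10
    spacing: float = 2.0  # mm, the grid constant a
    circle_diameter: float = 1.0  # mm
    marker_scale: float = 1.5  # marker circle diameter relative to others

    def __post_init__(self):
        if not self.spacing > self.circle_diameter > 0:
            raise ValueError("need spacing > circle_diameter > 0")

    @property
    def n_points(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def marker_nodes(self) -> tuple[tuple[int, int], ...]:
        return ((0, 0), (self.n_cols - 1, 0), (0, self.n_rows - 1))

    def object_points(self) -> np.ndarray:
        """(N, 2) grid coordinates in mm, row-major (index = j*n_cols + i)."""
        i, j = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        return np.stack([i.ravel() * self.spacing, j.ravel() * self.spacing], axis=1).astype(float)


@dataclass
class CorrespondenceSet:
    """3D-2D correspondences for both devices over all target poses."""

    object_points: list[np.ndarray]
    camera_image_points: list[np.ndarray]
    projector_image_points: list[np.ndarray]

    @property
    def n_poses(self) -> int:
        return len(self.object_points)

    def __post_init__(self):
        if not (len(self.object_points) == len(self.camera_image_points) == len(self.projector_image_points)):
            raise ValueError("per-pose lists must have equal length")
        for o, c, p in zip(self.object_points, self.camera_image_points, self.projector_image_points):
            if not (len(o) == len(c) == len(p)):
                raise ValueError("per-pose point counts must match across the three lists")


@dataclass
class SystemGeometry:
    """Calibrated camera-projector system in the camera (= global) frame."""

    camera: PinholeDevice
    projector: PinholeDevice
    reference_plane_point: np.ndarray
    reference_plane_normal: np.ndarray
    volume_min: np.ndarray  # axis-aligned calibrated volume, mm
    volume_max: np.ndarray
    reprojection_rms: dict = field(default_factory=dict)
    pattern_direction: str = "rows"  # fringe lines along global x, frequency along y
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.reference_plane_point = np.asarray(self.reference_plane_point, dtype=float)
        n = np.asarray(self.reference_plane_normal, dtype=float)
        self.reference_plane_normal = n / np.linalg.norm(n)
        self.volume_min = np.asarray(self.volume_min, dtype=float)
        self.volume_max = np.asarray(self.volume_max, dtype=float)

    @property
    def projector_center(self) -> np.ndarray:
        return self.projector.pose.center

    @property
    def pattern_axis(self) -> np.ndarray:
        """Unit vector along which the fringe phase varies on the reference plane."""
        return np.array([0.0, 1.0, 0.0]) if self.pattern_direction == "rows" else np.array([1.0, 0.0, 0.0])

    @property
    def fringe_axis(self) -> np.ndarray:
        """Direction of constant phase (the fringe lines) on the reference plane."""
        return np.array([1.0, 0.0, 0.0]) if self.pattern_direction == "rows" else np.array([0.0, 1.0, 0.0])

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        p = np.asarray(points)
        return np.all((p >= self.volume_min - margin) & (p <= self.volume_max + margin), axis=-1)

    def pattern_phase_at(self, points: np.ndarray, f_target: float, phase_offset: float = 0.0) -> np.ndarray:
        """Global phase of the predistorted pattern of metric frequency ``f_target``.

        The predistorted pattern realizes, on the reference plane, the phase
        ``2 pi f c + offset`` where c is the metric coordinate along the
        pattern axis.  Because all constant-phase surfaces are planes through
        the projector center, the phase at any 3D point equals the phase at
        the reference-plane piercing point of the projector ray through it.
        """
        pts = np.asarray(points, dtype=float)
        c_p = self.projector_center
        d = pts - c_p
        n = self.reference_plane_normal
        denom = d @ n
        t = ((self.reference_plane_point - c_p) @ n) / denom
        hit = c_p + t[..., None] * d
        coord = hit @ self.pattern_axis
        return 2.0 * np.pi * f_target * coord + phase_offset

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "camera": self.camera.to_dict(),
            "projector": self.projector.to_dict(),
            "reference_plane": {
                "point": self.reference_plane_point.tolist(),
                "normal": self.reference_plane_normal.tolist(),
            },
            "volume": {"min": self.volume_min.tolist(), "max": self.volume_max.tolist()},
            "reprojection_rms": self.reprojection_rms,
            "pattern_direction": self.pattern_direction,
            "metadata": self.metadata,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SystemGeometry":
        return cls(
            camera=PinholeDevice.from_dict(d["camera"]),
            projector=PinholeDevice.from_dict(d["projector"]),
            reference_plane_point=np.array(d["reference_plane"]["point"]),
            reference_plane_normal=np.array(d["reference_plane"]["normal"]),
            volume_min=np.array(d["volume"]["min"]),
            volume_max=np.array(d["volume"]["max"]),
            reprojection_rms=d.get("reprojection_rms", {}),
            pattern_direction=d.get("pattern_direction", "rows"),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, path) -> "SystemGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# grid detection
# ---------------------------------------------------------------------------

def detect_grid(dc_image: np.ndarray, target: CalibrationTarget) -> tuple[np.ndarray, dict]:
    """Detect and order the circle-grid centroids in a DC image.

    Returns ``(points, meta)`` where points is (n_points, 2) pixel
    coordinates ordered row-major by grid node, and meta records the marker
    assignment.  Raises :class:`GridDetectionError` on blob-count mismatch
    or ambiguous axis markers.
    """
    img = np.asarray(dc_image, dtype=float)
    thr = threshold_otsu(img)
    dark = img < thr
    labels = label(dark)
    props = regionprops(labels, intensity_image=img.max() - img)
    if not props:
        raise GridDetectionError("no blobs detected")
    areas = np.array([p.area for p in props])
    med = np.median(areas)
    props = [p for p in props if p.area > 0.25 * med]
    if len(props) != target.n_points:
        raise GridDetectionError(
            f"blob count mismatch: detected {len(props)}, expected {target.n_points} "
            f"({target.n_cols}x{target.n_rows})"
        )
    cents = np.array([p.centroid_weighted[::-1] for p in props])  # (u, v)
    areas = np.array([p.area for p in props])

    # the three markers are the enlarged circles
    order = np.argsort(areas)[::-1]
    marker_idx = order[:3]
    if areas[order[2]] < 1.3 * areas[order[3]]:
        raise GridDetectionError("ambiguous axis markers: marker blobs not separable by area")
    mk = cents[marker_idx]

    # origin marker: not an endpoint of the longest marker-pair side
    d01 = np.linalg.norm(mk[0] - mk[1])
    d02 = np.linalg.norm(mk[0] - mk[2])
    d12 = np.linalg.norm(mk[1] - mk[2])
    longest = int(np.argmax([d12, d02, d01]))  # index of marker NOT on the longest side
    origin = mk[longest]
    others = [mk[i] for i in range(3) if i != longest]

    obj = target.object_points()
    mk_obj = np.array(
        [
            [0.0, 0.0],
            [(target.n_cols - 1) * target.spacing, 0.0],
            [0.0, (target.n_rows - 1) * target.spacing],
        ]
    )

    # the board is seen from the front, so the image preserves the object
    # frame's handedness: cross(u_axis - origin, v_axis - origin) > 0 in
    # (u right, v down) image coordinates resolves the axis assignment even
    # for square grids (where pairwise distances alone are ambiguous)
    d1, d2 = others[0] - origin, others[1] - origin
    cross_z = d1[0] * d2[1] - d1[1] * d2[0]
    candidates = ((others[0], others[1]),) if cross_z > 0 else ((others[1], others[0]),)
    best = None
    for u_ax, v_ax in candidates:
        src = mk_obj
        dst = np.array([origin, u_ax, v_ax])
        # affine from 3 correspondences
        a = np.column_stack([src, np.ones(3)])
        try:
            coef = np.linalg.solve(a, dst)  # (3,2)
        except np.linalg.LinAlgError:
            continue
        pred = np.column_stack([obj, np.ones(len(obj))]) @ coef
        assign, res = _match_points(pred, cents)
        if assign is None:
            continue
        # refine with a homography and re-match
        for _ in range(2):
            h = estimate_homography(obj, cents[assign])
            ph = np.column_stack([obj, np.ones(len(obj))]) @ h.T
            pred = ph[:, :2] / ph[:, 2:3]
            assign, res = _match_points(pred, cents)
            if assign is None:
                break
        if assign is not None and (best is None or res < best[1]):
            best = (assign, res, (origin, u_ax, v_ax))
    if best is None:
        raise GridDetectionError("could not establish a consistent grid ordering")
    assign, res, markers = best
    meta = {
        "mean_match_residual_px": float(res),
        "origin_px": markers[0].tolist(),
        "u_axis_px": markers[1].tolist(),
        "v_axis_px": markers[2].tolist(),
    }
    return cents[assign], meta


def _match_points(pred: np.ndarray, det: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Bijectively match predicted grid positions to detected centroids."""
    d = np.linalg.norm(pred[:, None, :] - det[None, :, :], axis=2)
    assign = np.argmin(d, axis=1)
    if len(set(assign.tolist())) != len(pred):
        return None, np.inf
    res = float(np.mean(d[np.arange(len(pred)), assign]))
    # sanity: matches must be closer than half the predicted grid pitch
    pitch = np.median(np.linalg.norm(np.diff(pred.reshape(-1, 2)[:2], axis=0)))
    if res > max(pitch, 1.0):
        return None, np.inf
    return assign, res


# ---------------------------------------------------------------------------
# projector correspondences from phase
# ---------------------------------------------------------------------------

def projector_points_from_phase(
    phase_u: np.ndarray,
    phase_v: np.ndarray,
    camera_points: np.ndarray,
    pattern_spec: tuple[int, int, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """DMD pixel coordinates of markers from unwrapped phase maps.

    ``pattern_spec`` is (N_Col, N_Row, f_Col, f_Row): chip size and the
    pixel-based pattern frequencies.  The absolute phases sampled
    (bilinearly) at the detected camera centroids convert to DMD
    coordinates via ``u = phi_u / (f_Col 4 pi / N_Col)`` and the analogue
    for v.  Returns ``(dmd_points, in_range)``; out-of-chip values are
    flagged rather than dropped so the caller controls filtering.
    """
    n_col, n_row, f_col, f_row = pattern_spec
    pts = np.asarray(camera_points, dtype=float)
    coords = np.stack([pts[:, 1], pts[:, 0]])  # (row, col) order for map_coordinates
    pu = ndimage.map_coordinates(np.asarray(phase_u, dtype=float), coords, order=1, mode="nearest")
    pv = ndimage.map_coordinates(np.asarray(phase_v, dtype=float), coords, order=1, mode="nearest")
    u = pu / (f_col * 4.0 * np.pi / n_col)
    v = pv / (f_row * 4.0 * np.pi / n_row)
    dmd = np.stack([u, v], axis=1)
    in_range = (u >= 0) & (u < n_col) & (v >= 0) & (v < n_row)
    return dmd, in_range


# ---------------------------------------------------------------------------
# device calibration and frame unification
# ---------------------------------------------------------------------------

def calibrate_device(
    object_points: list[np.ndarray],
    image_points: list[np.ndarray],
    image_size: tuple[int, int],
    n_radial_terms: int = 2,
    role: str = "camera",
) -> CalibrationResult:
    """Solve one pinhole model from planar correspondences (>= 3 poses)."""
    return calibrate_pinhole(
        object_points, image_points, image_size, n_radial_terms=n_radial_terms, role=role
    )


def unify_frames(
    camera_result: CalibrationResult,
    projector_result: CalibrationResult,
    spread_tol_mm: float = 1.0,
) -> tuple[PinholeDevice, PinholeDevice, dict]:
    """Express the projector in the camera frame (the global frame).

    The per-pose relative transforms camera->projector are averaged
    (rotation by quaternion mean, translation arithmetically); their spread
    is reported and warned about above ``spread_tol_mm``.
    Returns (camera_device, projector_device, stats).
    """
    if len(camera_result.poses) != len(projector_result.poses):
        raise ValueError("camera and projector must be calibrated on the same pose set")
    quats, trans = [], []
    for pc, pp in zip(camera_result.poses, projector_result.poses):
        r_rel = pp.rotation @ pc.rotation.T
        t_rel = pp.translation - r_rel @ pc.translation
        quats.append(Rotation.from_matrix(r_rel).as_quat())
        trans.append(t_rel)
    quats = np.asarray(quats)
    # sign-align quaternions then average via the outer-product eigenvector
    quats[quats @ quats[0] < 0] *= -1
    w, v = np.linalg.eigh(quats.T @ quats)
    q_mean = v[:, -1]
    r_mean = Rotation.from_quat(q_mean).as_matrix()
    t_all = np.asarray(trans)
    t_mean = t_all.mean(axis=0)
    spread = float(np.max(np.linalg.norm(t_all - t_mean, axis=1))) if len(t_all) > 1 else None
    stats = {
        "translation_spread_mm": spread,
        "n_poses": len(trans),
    }
    if spread is not None and spread > spread_tol_mm:
        import warnings

        warnings.warn(
            f"projector pose spread {spread:.3f} mm exceeds tolerance {spread_tol_mm} mm",
            stacklevel=2,
        )
    camera = PinholeDevice(
        camera_result.device.intrinsics, camera_result.device.distortion, Pose(), role="camera"
    )
    projector = PinholeDevice(
        projector_result.device.intrinsics,
        projector_result.device.distortion,
        Pose(r_mean, t_mean),
        role="projector",
    )
    return camera, projector, stats


def calibrated_volume(camera_result: CalibrationResult, object_points: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box, in the camera frame, swept by the target."""
    pts = []
    for pose, obj in zip(camera_result.poses, object_points):
        obj3 = np.column_stack([np.asarray(obj)[:, :2], np.zeros(len(obj))])
        pts.append(pose.to_device(obj3))  # camera frame
    allp = np.concatenate(pts)
    return allp.min(axis=0), allp.max(axis=0)


def define_reference_plane(volume_min: np.ndarray, volume_max: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plane through the volume center, normal along the camera optical axis."""
    center = (np.asarray(volume_min, dtype=float) + np.asarray(volume_max, dtype=float)) / 2.0
    return center, np.array([0.0, 0.0, 1.0])


def build_system_geometry(
    camera_result: CalibrationResult,
    projector_result: CalibrationResult,
    object_points: list[np.ndarray],
    pattern_direction: str = "rows",
) -> SystemGeometry:
    """Assemble the full system description from the two calibrations."""
    camera, projector, stats = unify_frames(camera_result, projector_result)
    vmin, vmax = calibrated_volume(camera_result, object_points)
    plane_pt, plane_n = define_reference_plane(vmin, vmax)
    return SystemGeometry(
        camera=camera,
        projector=projector,
        reference_plane_point=plane_pt,
        reference_plane_normal=plane_n,
        volume_min=vmin,
        volume_max=vmax,
        reprojection_rms={
            "camera_px": camera_result.rms_px,
            "projector_px": projector_result.rms_px,
        },
        pattern_direction=pattern_direction,
        metadata={"unify_stats": stats},
    )


# ---------------------------------------------------------------------------
# predistorted patterns and ray fields
# ---------------------------------------------------------------------------

def generate_predistorted_patterns(
    geometry: SystemGeometry,
    f_target: float,
    orientation: str = "pattern",
    phase_offset: float = 0.0,
) -> np.ndarray:
    """DMD intensity image that realizes metric frequency ``f_target`` on the
    reference plane.

    Each DMD pixel's ray is intersected with the reference plane and the
    target fringe field (in mm^-1 along the pattern axis) evaluated there;
    intensities are in [0, 1].  Rays parallel to the plane are set to 0.
    """
    if not 0.0 <= f_target <= 1.0:
        raise ValueError("f_target must be within the supported 0..1 mm^-1 range")
    n_col, n_row = geometry.projector.intrinsics.image_size
    u, v = np.meshgrid(np.arange(n_col), np.arange(n_row))
    px = np.stack([u.ravel(), v.ravel()], axis=1).astype(float)
    rays = pixel_ray(geometry.projector, px, check_bounds=False)
    c_p = geometry.projector_center
    n = geometry.reference_plane_normal
    denom = rays @ n
    ok = np.abs(denom) > 1e-12
    t = np.where(ok, ((geometry.reference_plane_point - c_p) @ n) / np.where(ok, denom, 1.0), 0.0)
    hits = c_p + t[:, None] * rays
    axis = geometry.pattern_axis if orientation == "pattern" else geometry.fringe_axis
    coord = hits @ axis
    img = 0.5 + 0.5 * np.cos(2.0 * np.pi * f_target * coord + phase_offset)
    img[~ok] = 0.0
    return img.reshape(n_row, n_col)


def build_ray_fields(geometry: SystemGeometry) -> dict[str, np.ndarray]:
    """Per-pixel unit ray directions (global frame) for camera and projector."""
    out = {}
    for name, dev in (("camera", geometry.camera), ("projector", geometry.projector)):
        n_col, n_row = dev.intrinsics.image_size
        u, v = np.meshgrid(np.arange(n_col), np.arange(n_row))
        px = np.stack([u.ravel(), v.ravel()], axis=1).astype(float)
        rays = pixel_ray(dev, px, check_bounds=False)
        out[name] = rays.reshape(n_row, n_col, 3)
    return out
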