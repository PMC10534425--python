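"""Planar calibration solver (Zhang's method + Levenberg-Marquardt refinement).

Estimates intrinsics, distortion and per-pose extrinsics of a pinhole
device from >= 3 views of a planar grid: per-view homographies (normalized
DLT), closed-form intrinsics from the homography constraints, homography
decomposition for the extrinsic initial guesses, and a joint bundle
refinement of all parameters minimizing the reprojection error with
``scipy.optimize.least_squares``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .core_model import Distortion, Intrinsics, PinholeDevice, Pose, project_point

__all__ = ["estimate_homography", "calibrate_pinhole", "CalibrationResult"]


def _normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform bringing points to zero mean, sqrt(2) RMS radius."""
    mean = pts.mean(axis=0)
    scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - mean, axis=1)), 1e-12)
    t = np.array([[scale, 0, -scale * mean[0]], [0, scale, -scale * mean[1]], [0, 0, 1]])
    return t


def estimate_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """DLT homography mapping src (N,2) plane coords to dst (N,2) pixels."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) < 4:
        raise ValueError("homography needs at least 4 correspondences")
    ts, td = _normalization(src), _normalization(dst)
    s_h = np.column_stack([src, np.ones(len(src))]) @ ts.T
    d_h = np.column_stack([dst, np.ones(len(dst))]) @ td.T
    a = []
    for (x, y, _), (u, v, _) in zip(s_h, d_h):
        a.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        a.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    _, _, vt = np.linalg.svd(np.asarray(a))
    h = vt[-1].reshape(3, 3)
    h = np.linalg.inv(td) @ h @ ts
    return h / h[2, 2]


def _v_ij(h: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array(
        [
            h[0, i] * h[0, j],
            h[0, i] * h[1, j] + h[1, i] * h[0, j],
            h[1, i] * h[1, j],
            h[2, i] * h[0, j] + h[0, i] * h[2, j],
            h[2, i] * h[1, j] + h[1, i] * h[2, j],
            h[2, i] * h[2, j],
        ]
    )


def _intrinsics_from_homographies(hs: list[np.ndarray], image_size) -> np.ndarray:
    rows = []
    for h in hs:
        rows.append(_v_ij(h, 0, 1))
        rows.append(_v_ij(h, 0, 0) - _v_ij(h, 1, 1))
    v = np.asarray(rows)
    _, _, vt = np.linalg.svd(v)
    b11, b12, b22, b13, b23, b33 = vt[-1]
    try:
        cy = (b12 * b13 - b11 * b23) / (b11 * b22 - b12 * b12)
        lam = b33 - (b13 * b13 + cy * (b12 * b13 - b11 * b23)) / b11
        fx = np.sqrt(lam / b11)
        fy = np.sqrt(lam * b11 / (b11 * b22 - b12 * b12))
        cx = -b13 * fx * fx / lam
        k = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1]])
        if not np.all(np.isfinite(k)) or fx <= 0 or fy <= 0:
            raise FloatingPointError
        return k
    except (FloatingPointError, ZeroDivisionError, ValueError):
        # fall back to a generic telecentric-ish guess; LM refines from here
        n_cols, n_rows = image_size
        f0 = 2.0 * max(n_cols, n_rows)
        return np.array([[f0, 0, (n_cols - 1) / 2.0], [0, f0, (n_rows - 1) / 2.0], [0, 0, 1]])


def _extrinsics_from_homography(k: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k_inv = np.linalg.inv(k)
    a = k_inv @ h
    lam = 1.0 / np.linalg.norm(k_inv @ h[:, 0])
    r1, r2, t = lam * a[:, 0], lam * a[:, 1], lam * a[:, 2]
    if t[2] < 0:  # plane must be in front of the device
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    r = np.column_stack([r1, r2, r3])
    # nearest rotation
    u, _, vt = np.linalg.svd(r)
    r = u @ np.diag([1.0, 1.0, np.linalg.det(u @ vt)]) @ vt
    return r, t


class CalibrationResult:
    """Calibrated device, per-pose extrinsics and reprojection statistics."""

    def __init__(self, device: PinholeDevice, poses: list[Pose], rms_px: float, residuals: np.ndarray):
        self.device = device
        self.poses = poses
        self.rms_px = rms_px
        self.residuals = residuals


def calibrate_pinhole(
    object_points: list[np.ndarray],
    image_points: list[np.ndarray],
    image_size: tuple[int, int],
    n_radial_terms: int = 2,
    fit_tangential: bool = True,
    role: str = "camera",
) -> CalibrationResult:
    """Joint intrinsic/extrinsic/distortion estimation from planar views.

    ``object_points``: per-pose (N,2) planar grid coordinates in mm;
    ``image_points``: per-pose (N,2) pixel coordinates on this device's chip.
    """
    n_poses = len(object_points)
    if n_poses < 3:
        raise ValueError(f"at least three target poses required, got {n_poses}")
    if len(image_points) != n_poses:
        raise ValueError("object_points and image_points must have the same length")
    obj = [np.asarray(o, dtype=float)[:, :2] for o in object_points]
    img = [np.asarray(p, dtype=float) for p in image_points]
    for o, p in zip(obj, img):
        if len(o) != len(p):
            raise ValueError("point count mismatch between object and image points")

    hs = [estimate_homography(o, p) for o, p in zip(obj, img)]
    k0 = _intrinsics_from_homographies(hs, image_size)
    ext0 = [_extrinsics_from_homography(k0, h) for h in hs]

    if not (0 <= n_radial_terms <= 3):
        raise ValueError("n_radial_terms must be between 0 and 3")

    n_dist = n_radial_terms + (2 if fit_tangential else 0)

    def pack(k, dist, exts):
        p = [k[0, 0], k[1, 1], k[0, 2], k[1, 2], *dist]
        for r, t in exts:
            p.extend(Rotation.from_matrix(r).as_rotvec())
            p.extend(t)
        return np.asarray(p)

    def unpack(p):
        fx, fy, cx, cy = p[:4]
        dist = p[4 : 4 + n_dist]
        radial = tuple(dist[:n_radial_terms])
        tang = tuple(dist[n_radial_terms:]) if fit_tangential else (0.0, 0.0)
        exts = []
        for i in range(n_poses):
            base = 4 + n_dist + 6 * i
            r = Rotation.from_rotvec(p[base : base + 3]).as_matrix()
            t = p[base + 3 : base + 6]
            exts.append((r, t))
        return (fx, fy, cx, cy), radial, tang, exts

    def residual(p):
        (fx, fy, cx, cy), radial, tang, exts = unpack(p)
        try:
            intr = Intrinsics(fx=fx, fy=fy, cx=cx, cy=cy, image_size=image_size)
        except ValueError:
            return np.full(2 * sum(len(o) for o in obj), 1e6)
        dist = Distortion(radial=radial, tangential=tang)
        res = []
        for (r, t), o, pts in zip(exts, obj, img):
            dev = PinholeDevice(intr, dist, Pose(r, t), role=role)
            obj3 = np.column_stack([o, np.zeros(len(o))])
            try:
                proj = project_point(dev, obj3)
            except Exception:
                return np.full(2 * sum(len(oo) for oo in obj), 1e6)
            res.append((proj - pts).ravel())
        return np.concatenate(res)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # transient out-of-chip principal points during LM
        p0 = pack(k0, np.zeros(n_dist), ext0)
        sol = least_squares(residual, p0, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=2000)

    (fx, fy, cx, cy), radial, tang, exts = unpack(sol.x)
    res = sol.fun.reshape(-1, 2)
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    if not np.isfinite(rms) or rms > 1e3:
        raise RuntimeError(
            "calibration solver failed to converge (rank-deficient or degenerate "
            f"pose configuration?); residual RMS {rms:.3g} px"
        )
    intr = Intrinsics(fx=fx, fy=fy, cx=cx, cy=cy, image_size=image_size)
    dist = Distortion(radial=tuple(radial), tangential=tuple(tang))
    poses = [Pose(r, t) for r, t in exts]
    device = PinholeDevice(intr, dist, Pose(), role=role)
    return CalibrationResult(device, poses, rms, res)
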