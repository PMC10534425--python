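"""Pinhole imaging model shared by camera and projector.

Both devices of an SFDI setup (the camera and the DMD projector) are
described by the same parameterized pinhole model: a perspective projection
through a single center, radial/tangential lens distortion applied in
normalized image coordinates, and a rigid pose relating the global frame to
the device frame.  The global frame is, by convention, the camera frame
(the camera pose is the identity), with the optical axis along +z and all
translations in millimetres.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Intrinsics",
    "Distortion",
    "Pose",
    "PinholeDevice",
    "DegenerateGeometryError",
    "project_point",
    "apply_distortion",
    "undistort",
    "pixel_ray",
]


class DegenerateGeometryError(ValueError):
    """A point at or behind the projection center, or a ray parallel to a plane."""


MAX_RADIAL_TERMS = 3


@dataclass(frozen=True)
class Intrinsics:
    """Focal lengths and principal point in pixel units.

    ``image_size`` is (n_cols, n_rows).  Pixel coordinates are 0-based with
    (u, v) = (column, row) and pixel centers at integer coordinates.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    image_size: tuple[int, int]

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        n_cols, n_rows = self.image_size
        if not (0 <= self.cx < n_cols and 0 <= self.cy < n_rows):
            warnings.warn(
                f"principal point ({self.cx}, {self.cy}) lies outside the "
                f"{n_cols}x{n_rows} chip",
                stacklevel=3,
            )

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 intrinsic matrix A."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class Distortion:
    """Radial (k1..k3) and tangential (p1, p2) distortion coefficients.

    Applied in normalized image coordinates (after the perspective divide,
    before the intrinsic mapping).  All-zero coefficients give the ideal
    pinhole.
    """

    radial: tuple[float, ...] = ()
    tangential: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if len(self.radial) > MAX_RADIAL_TERMS:
            raise ValueError(
                f"at most {MAX_RADIAL_TERMS} radial terms supported, got {len(self.radial)}"
            )
        vals = (*self.radial, *self.tangential)
        if not np.all(np.isfinite(vals)):
            raise ValueError("distortion coefficients must be finite")

    @property
    def is_zero(self) -> bool:
        return not any(self.radial) and not any(self.tangential)


def _check_rotation(r: np.ndarray, tol: float = 1e-9) -> None:
    if r.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        raise ValueError("rotation is not orthonormal")
    if not np.isclose(np.linalg.det(r), 1.0, atol=tol):
        raise ValueError("rotation must have det +1")


@dataclass(frozen=True)
class Pose:
    """Rigid transform from the global frame into the device frame.

    ``X_dev = R @ X_glob + t`` with t in mm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))
        _check_rotation(self.rotation)

    def to_device(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def to_global(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.translation) @ self.rotation

    @property
    def center(self) -> np.ndarray:
        """The projection center in global coordinates."""
        return -self.rotation.T @ self.translation

    def compose_with(self, other: "Pose") -> "Pose":
        """Pose mapping global -> self applied after other (other then self)."""
        return Pose(self.rotation @ other.rotation, self.rotation @ other.translation + self.translation)


@dataclass(frozen=True)
class PinholeDevice:
    """One imaging device (camera or projector): intrinsics + distortion + pose."""

    intrinsics: Intrinsics
    distortion: Distortion = field(default_factory=Distortion)
    pose: Pose = field(default_factory=Pose)
    role: str = "camera"

    def __post_init__(self):
        if self.role not in ("camera", "projector"):
            raise ValueError(f"role must be 'camera' or 'projector', got {self.role!r}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "intrinsics": {
                "fx": self.intrinsics.fx,
                "fy": self.intrinsics.fy,
                "cx": self.intrinsics.cx,
                "cy": self.intrinsics.cy,
            },
            "image_size": list(self.intrinsics.image_size),
            "distortion": {
                "radial": list(self.distortion.radial),
                "tangential": list(self.distortion.tangential),
            },
            "pose": {
                "rotation": self.pose.rotation.tolist(),
                "translation": self.pose.translation.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PinholeDevice":
        intr = Intrinsics(
            fx=d["intrinsics"]["fx"],
            fy=d["intrinsics"]["fy"],
            cx=d["intrinsics"]["cx"],
            cy=d["intrinsics"]["cy"],
            image_size=tuple(d["image_size"]),
        )
        dist = Distortion(
            radial=tuple(d["distortion"]["radial"]),
            tangential=tuple(d["distortion"]["tangential"]),
        )
        pose = Pose(np.array(d["pose"]["rotation"]), np.array(d["pose"]["translation"]))
        return cls(intrinsics=intr, distortion=dist, pose=pose, role=d.get("role", "camera"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PinholeDevice":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_distortion(distortion: Distortion, normalized_pt: np.ndarray) -> np.ndarray:
    """Displace normalized image coordinates by the radial + tangential model.

    Accepts a single (2,) point or an (..., 2) array.
    """
    pt = np.asarray(normalized_pt, dtype=float)
    u, v = pt[..., 0], pt[..., 1]
    r2 = u * u + v * v
    radial = np.zeros_like(r2)
    r_pow = r2.copy() if isinstance(r2, np.ndarray) else r2
    r_pow = np.array(r2, copy=True)
    for k in distortion.radial:
        radial = radial + k * r_pow
        r_pow = r_pow * r2
    p1, p2 = distortion.tangential
    du = u * radial + 2.0 * p1 * u * v + p2 * (r2 + 2.0 * u * u)
    dv = v * radial + p1 * (r2 + 2.0 * v * v) + 2.0 * p2 * u * v
    return np.stack([u + du, v + dv], axis=-1)


def undistort(
    distortion: Distortion,
    distorted_pt: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> np.ndarray:
    """Invert :func:`apply_distortion` by damped fixed-point iteration.

    Raises a numeric error (with the residual) if the iteration does not
    contract, e.g. for non-physically large coefficients.
    """
    pt = np.asarray(distorted_pt, dtype=float)
    if distortion.is_zero:
        return pt.copy()
    x = pt.copy()
    prev_res = np.inf
    for _ in range(max_iter):
        fx = apply_distortion(distortion, x)
        delta = fx - pt
        res = float(np.max(np.abs(delta)))
        if res < tol:
            return x
        if not np.isfinite(res) or res > max(10.0 * prev_res, 1e3):
            break
        prev_res = min(prev_res, res)
        # damped update: subtract the residual of the distortion displacement
        x = x - 0.7 * delta
    fx = apply_distortion(distortion, x)
    res = float(np.max(np.abs(fx - pt)))
    if res >= tol:
        raise ArithmeticError(
            f"undistortion did not converge after {max_iter} iterations "
            f"(residual {res:.3e}); coefficients may be non-invertible here"
        )
    return x


def project_point(device: PinholeDevice, point_global: np.ndarray) -> np.ndarray:
    """Project global 3D point(s) (mm) to pixel coordinates (u, v).

    Applies the extrinsic transform, perspective divide, distortion in
    normalized coordinates, then the intrinsic mapping.  Points at or behind
    the projection center (non-positive depth) raise
    :class:`DegenerateGeometryError`.
    """
    pts = np.asarray(point_global, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    dev = device.pose.to_device(pts)
    z = dev[:, 2]
    if np.any(z <= 0):
        raise DegenerateGeometryError(
            "point at or behind the projection center (scale factor s <= 0)"
        )
    norm = dev[:, :2] / z[:, None]
    dist = apply_distortion(device.distortion, norm)
    intr = device.intrinsics
    uv = np.stack([intr.fx * dist[:, 0] + intr.cx, intr.fy * dist[:, 1] + intr.cy], axis=-1)
    return uv[0] if single else uv


def pixel_ray(device: PinholeDevice, pixel: np.ndarray, check_bounds: bool = True) -> np.ndarray:
    """Unit direction(s) in the global frame of the ray through pixel (u, v).

    The ray passes through the device's projection center; undistortion is
    applied before back-projection.
    """
    px = np.asarray(pixel, dtype=float)
    single = px.ndim == 1
    px = np.atleast_2d(px)
    intr = device.intrinsics
    if check_bounds:
        n_cols, n_rows = intr.image_size
        u, v = px[:, 0], px[:, 1]
        if np.any((u < -0.5) | (u > n_cols - 0.5) | (v < -0.5) | (v > n_rows - 0.5)):
            raise IndexError("pixel outside chip bounds")
    norm_d = np.stack([(px[:, 0] - intr.cx) / intr.fx, (px[:, 1] - intr.cy) / intr.fy], axis=-1)
    norm = undistort(device.distortion, norm_d)
    d_dev = np.concatenate([norm, np.ones((len(norm), 1))], axis=1)
    d_glob = d_dev @ device.pose.rotation  # R^T @ d for each row
    d_glob /= np.linalg.norm(d_glob, axis=1, keepdims=True)
    return d_glob[0] if single else d_glob
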