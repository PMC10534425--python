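"""Phase-distance conversion, surface normals and projection/detection angles.

The calibrated geometry links the unwrapped global fringe phase seen by a
camera pixel to the metric distance l along that pixel's ray: each ray is
sampled on a set of virtual planes spanning the calibrated volume, the
model phase is evaluated at every sample, and a per-pixel cubic polynomial
l(phi) is fitted.  Applying the polynomial to a measured phase map yields a
3D point cloud; k-NN PCA normals and per-point local frames then give the
projection and detection angles used by the frequency and intensity
corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geom_calib import SystemGeometry, build_ray_fields

__all__ = [
    "PhaseDistanceModel",
    "SurfaceMap",
    "fit_phase_distance",
    "phase_to_points",
    "estimate_normals",
    "local_frame",
    "rays_to_angles",
    "compute_angle_maps",
]


@dataclass
class PhaseDistanceModel:
    """Per-pixel cubic polynomial mapping global phase -> distance l (mm)."""

    coefficients: np.ndarray  # (H, W, 4), a_0..a_3 in ascending powers
    phase_min: np.ndarray  # (H, W) valid phase range
    phase_max: np.ndarray
    f_model: float  # metric frequency (mm^-1) the phase refers to
    n_planes: int
    valid: np.ndarray  # (H, W) pixels with a trustworthy fit
    max_fit_residual_mm: float = 0.0

    def evaluate(self, phase: np.ndarray) -> np.ndarray:
        """Distance l(phase) by per-pixel Horner evaluation."""
        c = self.coefficients
        return ((c[..., 3] * phase + c[..., 2]) * phase + c[..., 1]) * phase + c[..., 0]


@dataclass
class SurfaceMap:
    """Per-pixel reconstructed surface and viewing geometry.

    ``phi_*`` are the polar (incidence/detection) angles between the ray
    toward the device and the surface normal; ``theta_*`` are the azimuths
    of the ray's in-surface component, measured from the local e_y axis
    (the in-surface fringe-normal direction) and folded into
    (-pi/2, pi/2], so that a flat sample at the reference plane has
    theta ~= 0.  All angles in radians.
    """

    points: np.ndarray  # (H, W, 3) mm
    distance: np.ndarray  # (H, W) mm
    normals: np.ndarray | None = None  # (H, W, 3), unit, oriented toward camera
    theta_pro: np.ndarray | None = None
    phi_pro: np.ndarray | None = None
    theta_cam: np.ndarray | None = None
    phi_cam: np.ndarray | None = None
    valid: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def fit_phase_distance(
    geometry: SystemGeometry,
    n_planes: int = 10,
    f_model: float = 0.45,
    ray_field: np.ndarray | None = None,
) -> PhaseDistanceModel:
    """Fit the per-pixel cubic phase-distance polynomial from virtual planes.

    ``n_planes`` z-planes uniformly spanning the calibrated volume are
    intersected with every camera ray; the predistorted-pattern phase of
    frequency ``f_model`` is evaluated at each intersection and l(phi)
    fitted by least squares.  Monotonicity over the sampled range is
    asserted per pixel at fit time.
    """
    if n_planes < 4:
        raise ValueError(f"a cubic fit needs at least 4 virtual planes, got {n_planes}")
    if ray_field is None:
        ray_field = build_ray_fields(geometry)["camera"]
    h, w, _ = ray_field.shape
    rays = ray_field.reshape(-1, 3)
    z_lo, z_hi = geometry.volume_min[2], geometry.volume_max[2]
    z_planes = np.linspace(z_lo, z_hi, n_planes)

    # distance along the unit ray to the plane z = z_i
    dz = rays[:, 2]
    ls = z_planes[:, None] / dz[None, :]  # (n_planes, N)
    pts = rays[None, :, :] * ls[:, :, None]  # (n_planes, N, 3)
    phis = geometry.pattern_phase_at(pts.reshape(-1, 3), f_model).reshape(n_planes, -1)

    # batched cubic least squares on the normal equations
    v = np.stack([np.ones_like(phis), phis, phis**2, phis**3], axis=-1)  # (n_planes, N, 4)
    ata = np.einsum("pni,pnj->nij", v, v)
    atl = np.einsum("pni,pn->ni", v, ls)
    coef = np.linalg.solve(ata, atl[..., None])[..., 0]  # (N, 4)

    fit = np.einsum("pni,ni->pn", v, coef)
    resid = np.max(np.abs(fit - ls), axis=0)

    # monotonicity of dl/dphi over the sampled range
    dcoef = coef[:, 1:] * np.array([1.0, 2.0, 3.0])
    phi_dense = np.linspace(phis.min(axis=0), phis.max(axis=0), 16)  # (16, N)
    deriv = (dcoef[:, 2] * phi_dense + dcoef[:, 1]) * phi_dense + dcoef[:, 0]
    monotonic = (np.all(deriv > 0, axis=0)) | (np.all(deriv < 0, axis=0))

    valid = monotonic & (resid < 1e-2)
    return PhaseDistanceModel(
        coefficients=coef.reshape(h, w, 4),
        phase_min=phis.min(axis=0).reshape(h, w),
        phase_max=phis.max(axis=0).reshape(h, w),
        f_model=f_model,
        n_planes=n_planes,
        valid=valid.reshape(h, w),
        max_fit_residual_mm=float(resid.max()),
    )


def phase_to_points(
    model: PhaseDistanceModel,
    phase_map: np.ndarray,
    ray_field: np.ndarray,
    phase_frequency: float | None = None,
    range_margin: float = 0.02,
) -> SurfaceMap:
    """Convert an unwrapped global phase map to a 3D point map.

    ``phase_frequency`` is the metric frequency the phase map was measured
    at; predistorted-pattern phases scale exactly with frequency, so the
    map is rescaled to the model's ``f_model`` before evaluation.  Pixels
    whose phase falls outside the per-pixel calibrated range are masked.
    """
    phase = np.asarray(phase_map, dtype=float)
    if phase_frequency is not None and phase_frequency != model.f_model:
        phase = phase * (model.f_model / phase_frequency)
    span = model.phase_max - model.phase_min
    inside = (phase >= model.phase_min - range_margin * span) & (
        phase <= model.phase_max + range_margin * span
    )
    valid = inside & model.valid
    l = model.evaluate(phase)
    points = ray_field * l[..., None]
    n_masked = int(np.sum(~inside))
    return SurfaceMap(
        points=points,
        distance=l,
        valid=valid,
        metadata={"n_out_of_range": n_masked},
    )


def estimate_normals(
    points: np.ndarray,
    k_neighbors: int = 16,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """k-NN PCA plane normals, unit length, oriented toward the camera.

    ``points`` is (H, W, 3) (or (N, 3)); the normal is the smallest
    principal axis of each point's k nearest neighbors.  The camera sits at
    the global origin, so orientation enforces ``n . P < 0``.
    """
    if k_neighbors < 3:
        raise ValueError("k_neighbors must be at least 3 for a PCA plane fit")
    pts = np.asarray(points, dtype=float)
    shape = pts.shape[:-1]
    flat = pts.reshape(-1, 3)
    if valid is not None:
        vmask = np.asarray(valid, dtype=bool).ravel()
    else:
        vmask = np.ones(len(flat), dtype=bool)
    idx_valid = np.flatnonzero(vmask)
    if len(idx_valid) <= k_neighbors:
        raise ValueError("not enough valid points for normal estimation")
    cloud = flat[idx_valid]
    tree = cKDTree(cloud)
    _, nn = tree.query(cloud, k=k_neighbors)
    neigh = cloud[nn]  # (M, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("mki,mkj->mij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest eigenvalue axis
    # orient toward the camera at the origin
    flip = np.einsum("mi,mi->m", normals, cloud) > 0
    normals[flip] *= -1
    out = np.zeros_like(flat)
    out[idx_valid] = normals
    return out.reshape(*shape, 3)


def local_frame(
    normal: np.ndarray,
    projector_ray: np.ndarray,
    pattern_direction: np.ndarray,
    eps: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Local surface frame(s) (e_x, e_y, e_z) for fringe-scaling geometry.

    ``e_z`` is the unit normal; ``e_x`` is the fringe-line direction
    projected along the projector ray onto the surface plane,
    ``e_y = e_z x e_x``.  Returns ``(e_x, e_y, e_z, degenerate_mask)``;
    degenerate pixels (projector ray in the surface plane, or pattern
    direction parallel to the normal's projection) are flagged.
    Broadcasts over leading dimensions.
    """
    n = np.asarray(normal, dtype=float)
    e_pro = np.asarray(projector_ray, dtype=float)
    e_pat = np.broadcast_to(np.asarray(pattern_direction, dtype=float), n.shape)
    denom = np.einsum("...i,...i->...", n, e_pro)
    degen = np.abs(denom) < eps
    safe = np.where(degen, 1.0, denom)
    e_x = e_pat - e_pro * (np.einsum("...i,...i->...", n, e_pat) / safe)[..., None]
    nx = np.linalg.norm(e_x, axis=-1)
    degen = degen | (nx < eps)
    e_x = e_x / np.where(degen, 1.0, nx)[..., None]
    nz = np.linalg.norm(n, axis=-1)
    degen = degen | (nz < eps)
    e_z = n / np.where(degen, 1.0, nz)[..., None]
    e_y = np.cross(e_z, e_x)
    ny = np.linalg.norm(e_y, axis=-1)
    degen = degen | (ny < eps)
    e_y = e_y / np.where(degen, 1.0, ny)[..., None]
    return e_x, e_y, e_z, degen


def rays_to_angles(
    ray: np.ndarray,
    e_x: np.ndarray,
    e_y: np.ndarray,
    e_z: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(theta, phi) of a ray in the local frame.

    ``phi`` is the polar angle between the ray (pointing from the surface
    toward the device) and the normal e_z, in [0, pi/2) for visible
    geometry; ``theta`` is the azimuth of the in-surface component measured
    from e_y, folded into (-pi/2, pi/2] (the fringe-scaling factors are
    pi-periodic in it).  Rays from below the surface (polar >= pi/2) should
    be masked by the caller via ``phi``.
    """
    x = np.einsum("...i,...i->...", ray, e_x)
    y = np.einsum("...i,...i->...", ray, e_y)
    z = np.einsum("...i,...i->...", ray, e_z)
    phi = np.arccos(np.clip(np.abs(z), 0.0, 1.0))
    theta = np.arctan2(x, y)
    theta = np.where(theta > np.pi / 2, theta - np.pi, theta)
    theta = np.where(theta <= -np.pi / 2, theta + np.pi, theta)
    return theta, phi


def compute_angle_maps(
    surface: SurfaceMap,
    geometry: SystemGeometry,
    k_neighbors: int = 16,
) -> SurfaceMap:
    """Fill a SurfaceMap with normals and projection/detection angles."""
    pts = surface.points
    valid = surface.valid if surface.valid is not None else np.ones(pts.shape[:2], dtype=bool)
    if surface.normals is None:
        surface.normals = estimate_normals(pts, k_neighbors=k_neighbors, valid=valid)
    n = surface.normals
    c_p = geometry.projector_center
    to_pro = c_p - pts
    to_pro /= np.linalg.norm(to_pro, axis=-1, keepdims=True)
    to_cam = -pts / np.linalg.norm(pts, axis=-1, keepdims=True)
    e_x, e_y, e_z, degen = local_frame(n, to_pro, geometry.fringe_axis)
    theta_pro, phi_pro = rays_to_angles(to_pro, e_x, e_y, e_z)
    theta_cam, phi_cam = rays_to_angles(to_cam, e_x, e_y, e_z)
    # self-occluded geometry: ray not above the surface
    above = (np.einsum("...i,...i->...", to_pro, e_z) > 0) & (
        np.einsum("...i,...i->...", to_cam, e_z) > 0
    )
    surface.theta_pro = theta_pro
    surface.phi_pro = phi_pro
    surface.theta_cam = theta_cam
    surface.phi_cam = phi_cam
    surface.valid = valid & ~degen & above
    return surface
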