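"""Spatial-frequency and intensity corrections for displaced/tilted samples.

An obliquely projected fringe field changes its metric spatial frequency
on a surface that is shifted (magnification, S_z) or tilted (angular
scaling, S_par / S_perp) relative to the reference plane on which the
predistorted patterns realize the nominal frequency.  The corrected
per-pixel frequency is

    f_corr = f_ref * S_z * S_par(P) / S_par(P_ref),

the ratio to the same camera ray's reference-plane factor making the
correction exactly 1 for a flat sample at the reference plane.  Intensity
is normalized by a Lambert factor (cosine of the detection angle times the
two angular scalings) and referenced to a per-pixel look-up hypersurface
MTF_ref(l, f) built from measurements of a reflectance standard at several
positions and frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demodulation import DemodResult
from .geom_calib import SystemGeometry
from .surface import SurfaceMap, local_frame, rays_to_angles

__all__ = [
    "FrequencyMap",
    "MtfLut",
    "ReflectanceMap",
    "scaling_parallel",
    "scaling_perpendicular",
    "magnification",
    "correct_frequency",
    "lambert_factor",
    "build_mtf_lut",
    "compute_reflectance",
]


def scaling_parallel(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Angular frequency scaling for tilts parallel to the fringes.

    ``theta`` is the polar (incidence) angle of the projector ray relative
    to the surface normal, ``phi`` the azimuth of its in-surface component
    measured from the local e_y axis (the in-surface fringe-normal
    direction): phi = 90 deg means the obliquity lies along the fringe
    lines and the spacing is unchanged (s = 1); phi = 0 compresses the
    spacing by cos(theta).  s = sqrt(cos^2 theta + sin^2 phi sin^2 theta),
    in (0, 1].
    """
    ct, st = np.cos(theta), np.sin(theta)
    return np.sqrt(ct * ct + np.sin(phi) ** 2 * st * st)


def scaling_perpendicular(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Angular frequency scaling for tilts perpendicular to the fringes.

    Same arguments as :func:`scaling_parallel`; the two coincide under the
    exchange phi -> 90 deg - phi.
    """
    ct, st = np.cos(theta), np.sin(theta)
    return np.sqrt(ct * ct + np.cos(phi) ** 2 * st * st)


def magnification(p_ref: np.ndarray, p: np.ndarray) -> np.ndarray:
    """S_z = |P_ref| / |P|: pattern magnification for a distance change."""
    nref = np.linalg.norm(np.asarray(p_ref, dtype=float), axis=-1)
    npt = np.linalg.norm(np.asarray(p, dtype=float), axis=-1)
    return nref / npt


@dataclass
class FrequencyMap:
    """Per-pixel corrected spatial frequency and its factor decomposition.

    ``s_ang_par``/``s_ang_perp`` are the tilt factors normalized by the
    same camera ray's reference-plane value, so a flat sample at the
    reference plane has all factors identically 1 and
    ``f_corr = f_ref * s_z * s_ang_par`` holds per pixel.
    """

    f_ref: float
    f_corr: np.ndarray
    s_ang_par: np.ndarray
    s_ang_perp: np.ndarray
    s_z: np.ndarray
    valid: np.ndarray
    metadata: dict = field(default_factory=dict)


def _raw_factors(points, normals, geometry):
    """(s_par_raw, s_perp_raw, cos_phi_cam) at the given surface points."""
    c_p = geometry.projector_center
    to_pro = c_p - points
    to_pro = to_pro / np.linalg.norm(to_pro, axis=-1, keepdims=True)
    e_x, e_y, e_z, degen = local_frame(normals, to_pro, geometry.fringe_axis)
    # the scaling formulas take the polar angle and the azimuth measured from
    # e_y: obliquity along the fringe lines (azimuth 90 deg) leaves the
    # fringe spacing unchanged, obliquity along e_y (azimuth 0) scales it by
    # cos(theta)
    x = np.einsum("...i,...i->...", to_pro, e_x)
    y = np.einsum("...i,...i->...", to_pro, e_y)
    z = np.einsum("...i,...i->...", to_pro, e_z)
    theta = np.arccos(np.clip(np.abs(z), 0.0, 1.0))
    phi = np.arctan2(x, y)
    s_par = scaling_parallel(theta, phi)
    s_perp = scaling_perpendicular(theta, phi)
    to_cam = -points / np.linalg.norm(points, axis=-1, keepdims=True)
    cos_cam = np.abs(np.einsum("...i,...i->...", to_cam, e_z))
    return s_par, s_perp, cos_cam, degen


def reference_points_for(surface_points: np.ndarray, geometry: SystemGeometry) -> np.ndarray:
    """Reference-plane piercing points of the camera rays through ``points``."""
    pts = np.asarray(surface_points, dtype=float)
    d = pts / np.linalg.norm(pts, axis=-1, keepdims=True)
    n = geometry.reference_plane_normal
    t = (geometry.reference_plane_point @ n) / (d @ n)
    return d * t[..., None]


def correct_frequency(
    f_ref: float,
    surface: SurfaceMap,
    geometry: SystemGeometry,
    reference_points: np.ndarray | None = None,
    include_perpendicular: bool = False,
) -> FrequencyMap:
    """Per-pixel corrected spatial frequency for a shifted/tilted surface.

    ``include_perpendicular`` additionally applies the normalized S_perp
    factor (off by default: a pure frequency change along the pattern axis
    is captured by S_par alone).
    """
    pts = surface.points
    if surface.normals is None:
        raise ValueError("surface needs normals; run compute_angle_maps first")
    if reference_points is None:
        reference_points = reference_points_for(pts, geometry)
    plane_n = -geometry.reference_plane_normal  # oriented toward the camera
    plane_normals = np.broadcast_to(plane_n, pts.shape)

    s_par, s_perp, _, degen = _raw_factors(pts, surface.normals, geometry)
    # tilt-only normalization: the reference factor is evaluated at the same
    # surface point but with the reference-plane orientation, so that a pure
    # z-shift is carried entirely by S_z and an untilted surface has
    # s_ang_par = 1 exactly
    s_par_ref, s_perp_ref, _, degen_r = _raw_factors(pts, plane_normals, geometry)

    s_ang_par = s_par / s_par_ref
    s_ang_perp = s_perp / s_perp_ref
    s_z = magnification(reference_points, pts)
    f_corr = f_ref * s_z * s_ang_par
    if include_perpendicular:
        f_corr = f_corr * s_ang_perp
    valid = (surface.valid if surface.valid is not None else np.ones(pts.shape[:2], bool)) & ~degen & ~degen_r
    return FrequencyMap(
        f_ref=f_ref,
        f_corr=f_corr,
        s_ang_par=s_ang_par,
        s_ang_perp=s_ang_perp,
        s_z=s_z,
        valid=valid,
        metadata={
            "include_perpendicular": include_perpendicular,
            "s_par_raw_mean": float(np.nanmean(s_par)),
            "s_par_ref_mean": float(np.nanmean(s_par_ref)),
        },
    )


def lambert_factor(
    theta_cam: np.ndarray,
    theta_pro: np.ndarray,
    phi_pro: np.ndarray,
) -> np.ndarray:
    """Lambert intensity factor s = cos(theta_cam) * S_perp * S_par, in (0, 1].

    ``theta_cam`` is the detection polar angle; ``theta_pro``/``phi_pro``
    the projection polar angle and azimuth-from-e_x as in
    :func:`scaling_parallel`.  Measured intensities are *divided* by this
    factor (the correction removes the cosine attenuation), identically on
    the reference and the sample side.
    """
    return (
        np.abs(np.cos(theta_cam))
        * scaling_perpendicular(theta_pro, phi_pro)
        * scaling_parallel(theta_pro, phi_pro)
    )


def lambert_map(surface: SurfaceMap, geometry: SystemGeometry) -> np.ndarray:
    """Per-pixel Lambert factor from a surface map with normals."""
    s_par, s_perp, cos_cam, _ = _raw_factors(surface.points, surface.normals, geometry)
    return cos_cam * s_perp * s_par


@dataclass
class MtfLut:
    """Per-pixel reference-intensity hypersurface over (distance l, frequency f).

    Node values are Lambert-normalized reference intensities: the AC
    amplitude at f != 0 and the DC offset on the f = 0 row.  ``l_nodes``
    and ``f_nodes`` are per-pixel (the corrected frequency of a nominal
    pattern varies slightly with position), so interpolation runs per
    nominal-frequency column along l first, then across frequency.
    """

    l_nodes: np.ndarray  # (N_pos, H, W)
    f_nodes: np.ndarray  # (N_pos, N_f, H, W) corrected frequencies, f_nodes[:,0]=0
    values: np.ndarray  # (N_pos, N_f, H, W)
    r_ref_table: tuple[np.ndarray, np.ndarray]  # (f, R_SFD_ref(f))
    metadata: dict = field(default_factory=dict)

    def r_ref(self, f: np.ndarray) -> np.ndarray:
        ft, rt = self.r_ref_table
        return np.interp(np.asarray(f, dtype=float), ft, rt)

    def query(self, l: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated reference intensity at (l, f) per pixel.

        Returns ``(values, inside)``; queries outside the node hull are
        flagged (and clamped to the hull for the returned value).
        """
        l = np.asarray(l, dtype=float)
        f = np.asarray(f, dtype=float)
        n_pos, n_f = self.values.shape[:2]
        # interpolate along l within each nominal-frequency column
        lo = self.l_nodes[0]
        hi = self.l_nodes[-1]
        inside_l = (l >= lo) & (l <= hi)
        lc = np.clip(l, lo, hi)
        idx = np.zeros(l.shape, dtype=int)
        for k in range(n_pos - 1):
            idx = np.where(lc >= self.l_nodes[k], k, idx)
        l0 = np.take_along_axis(self.l_nodes, idx[None], axis=0)[0]
        l1 = np.take_along_axis(self.l_nodes, idx[None] + 1, axis=0)[0]
        w = np.where(l1 > l0, (lc - l0) / np.where(l1 > l0, l1 - l0, 1.0), 0.0)
        f_at = (1 - w)[None] * np.take_along_axis(self.f_nodes, idx[None, None], axis=0)[0] + w[
            None
        ] * np.take_along_axis(self.f_nodes, idx[None, None] + 1, axis=0)[0]
        v_at = (1 - w)[None] * np.take_along_axis(self.values, idx[None, None], axis=0)[0] + w[
            None
        ] * np.take_along_axis(self.values, idx[None, None] + 1, axis=0)[0]
        # then interpolate across frequency columns (f_at is sorted along axis 0)
        inside_f = (f >= f_at[0]) & (f <= f_at[-1])
        fc = np.clip(f, f_at[0], f_at[-1])
        jdx = np.zeros(f.shape, dtype=int)
        for k in range(n_f - 1):
            jdx = np.where(fc >= f_at[k], k, jdx)
        f0 = np.take_along_axis(f_at, jdx[None], axis=0)[0]
        f1 = np.take_along_axis(f_at, jdx[None] + 1, axis=0)[0]
        wf = np.where(f1 > f0, (fc - f0) / np.where(f1 > f0, f1 - f0, 1.0), 0.0)
        v0 = np.take_along_axis(v_at, jdx[None], axis=0)[0]
        v1 = np.take_along_axis(v_at, jdx[None] + 1, axis=0)[0]
        return (1 - wf) * v0 + wf * v1, inside_l & inside_f

    def query_dc(self, l: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """The corrected DC reference (the f = 0 row) interpolated in l."""
        zeros = np.zeros(np.asarray(l, dtype=float).shape)
        return self.query(l, zeros)


@dataclass
class ReflectanceMap:
    """Per-pixel diffuse reflectance R_SFD for one wavelength."""

    frequencies: np.ndarray  # (N_f,) nominal frequencies (mm^-1), AC channels
    r_ac: np.ndarray  # (N_f, H, W)
    f_corr: np.ndarray  # (N_f, H, W) corrected frequency per channel
    r_dc: np.ndarray  # (H, W), frequency-averaged DC reflectance
    valid: np.ndarray  # (N_f, H, W)
    wavelength: str | None = None
    provenance: dict = field(default_factory=dict)


def build_mtf_lut(
    reference_measurements: list[dict],
    r_ref_table: tuple[np.ndarray, np.ndarray],
    geometry: SystemGeometry,
) -> MtfLut:
    """Assemble the per-pixel (l, f) reference hypersurface.

    ``reference_measurements`` is one dict per standard position:
    ``{"surface": SurfaceMap (with normals/angles), "demods": {f_nominal:
    DemodResult}}``.  Per position and pixel the Lambert-normalized DC is
    stored at f = 0 and the normalized AC at each nominal frequency's
    corrected per-pixel frequency.  Positions are sorted by distance l;
    coincident nodes are averaged.
    """
    n_pos = len(reference_measurements)
    if n_pos < 2:
        raise ValueError("at least two reference positions are required")
    f_nominal = sorted(k for k in reference_measurements[0]["demods"] if k > 0)
    n_f = len(f_nominal) + 1

    first = reference_measurements[0]["surface"]
    h, w = first.distance.shape
    l_nodes = np.zeros((n_pos, h, w))
    f_nodes = np.zeros((n_pos, n_f, h, w))
    values = np.zeros((n_pos, n_f, h, w))

    for k, meas in enumerate(reference_measurements):
        surf: SurfaceMap = meas["surface"]
        with np.errstate(divide="ignore", invalid="ignore"):  # masked pixels
            lam = lambert_map(surf, geometry)
            l_nodes[k] = surf.distance
            demods: dict[float, DemodResult] = meas["demods"]
            # DC row (f = 0): average the normalized DC over the acquired stacks
            dc = np.mean([d.i_dc for d in demods.values()], axis=0)
            values[k, 0] = dc / lam
            f_nodes[k, 0] = 0.0
            for j, fn in enumerate(f_nominal, start=1):
                fmap = correct_frequency(fn, surf, geometry)
                f_nodes[k, j] = fmap.f_corr
                values[k, j] = demods[fn].i_ac / lam

    # sort nodes by l per pixel; average duplicates
    order = np.argsort(l_nodes, axis=0)
    l_sorted = np.take_along_axis(l_nodes, order, axis=0)
    f_sorted = np.take_along_axis(f_nodes, order[:, None], axis=0)
    v_sorted = np.take_along_axis(values, order[:, None], axis=0)
    dup = np.diff(l_sorted, axis=0) < 1e-9
    n_dup = int(dup.sum())
    return MtfLut(
        l_nodes=l_sorted,
        f_nodes=f_sorted,
        values=v_sorted,
        r_ref_table=(np.asarray(r_ref_table[0], float), np.asarray(r_ref_table[1], float)),
        metadata={"f_nominal": f_nominal, "n_duplicate_nodes": n_dup},
    )


def compute_reflectance(
    sample_demods: dict[float, DemodResult],
    surface: SurfaceMap,
    freq_maps: dict[float, FrequencyMap],
    lut: MtfLut,
    geometry: SystemGeometry,
    out_of_domain: str = "mask",
    apply_lambert: bool = True,
) -> ReflectanceMap:
    """Diffuse reflectance R_SFD per pixel and acquired frequency.

    AC channels: ``R = (I_AC / S_Lambert) / MTF_ref(l, f_corr) *
    R_ref(f_corr)``; the DC channel averages the analogous f = 0 ratio over
    all acquired frequencies.  ``apply_lambert=False`` skips the
    sample-side Lambert normalization (the uncorrected baseline; the LUT
    keeps its own).  Out-of-LUT queries are masked (default) or clamped to
    the hull per ``out_of_domain``.
    """
    if out_of_domain not in ("mask", "clamp"):
        raise ValueError("out_of_domain must be 'mask' or 'clamp'")
    l = surface.distance
    f_list = sorted(k for k in sample_demods if k > 0)
    h, w = l.shape
    r_ac = np.zeros((len(f_list), h, w))
    f_corr = np.zeros_like(r_ac)
    valid = np.zeros(r_ac.shape, dtype=bool)
    base_valid = surface.valid if surface.valid is not None else np.ones((h, w), bool)

    with np.errstate(divide="ignore", invalid="ignore"):  # masked pixels divide by 0
        lam = lambert_map(surface, geometry) if apply_lambert else np.ones((h, w))
        mtf_dc, inside_dc = lut.query_dc(l)
        dc_terms = []
        for j, fn in enumerate(f_list):
            dm = sample_demods[fn]
            fmap = freq_maps[fn]
            f_corr[j] = fmap.f_corr
            mtf, inside = lut.query(l, fmap.f_corr)
            r = (dm.i_ac / lam) / mtf * lut.r_ref(fmap.f_corr)
            r_ac[j] = r
            ok = base_valid & fmap.valid
            if dm.validity_mask is not None:
                ok = ok & dm.validity_mask
            if out_of_domain == "mask":
                ok = ok & inside
            valid[j] = ok & np.isfinite(r)
            dc_terms.append((dm.i_dc / lam) / mtf_dc * lut.r_ref(0.0))
        r_dc = np.mean(dc_terms, axis=0)
        if out_of_domain == "mask":
            r_dc = np.where(inside_dc, r_dc, np.nan)
    return ReflectanceMap(
        frequencies=np.asarray(f_list),
        r_ac=r_ac,
        f_corr=f_corr,
        r_dc=r_dc,
        valid=valid,
        provenance={"corrections": ["lambert", "frequency", "mtf_lut"], "out_of_domain": out_of_domain},
    )
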