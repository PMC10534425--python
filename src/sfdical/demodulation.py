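"""Per-pixel phase-shift demodulation of fringe image stacks.

A stack of N >= 3 frames of a sinusoidal pattern, each shifted by a known
phase delta_i, is demodulated pixel-wise into the offset I_DC, the
modulation amplitude I_AC and the wrapped phase.  For the canonical three
shifts {0, 2pi/3, 4pi/3} the closed-form three-step estimator is used;
for a general shift set a linear least-squares estimator on the model
``I_i = DC + AC cos(phi + delta_i)`` is solved, which is exact for
noise-free sinusoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.restoration import unwrap_phase as _skimage_unwrap

__all__ = ["FringeStack", "DemodResult", "demodulate", "unwrap_phase", "load_fringe_stack"]


def load_fringe_stack(
    source,
    phase_shifts: tuple[float, ...],
    nominal_frequency: float = 0.0,
    pattern_direction: str = "rows",
) -> "FringeStack":
    """Read a fringe stack from a multipage TIFF or a sequence of TIFFs.

    ``source`` is one path (multipage, one page per phase shift) or a list
    of single-frame paths ordered like ``phase_shifts``.
    """
    import tifffile

    if isinstance(source, (list, tuple)):
        frames = [np.asarray(tifffile.imread(p), dtype=float) for p in source]
        images = np.stack(frames)
    else:
        images = np.asarray(tifffile.imread(source), dtype=float)
    return FringeStack(
        images=images,
        phase_shifts=tuple(phase_shifts),
        nominal_frequency=nominal_frequency,
        pattern_direction=pattern_direction,
    )

_THREE_STEP = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


@dataclass
class FringeStack:
    """N_phase same-shaped frames of one spatial frequency.

    ``nominal_frequency`` is the metric frequency (mm^-1) the pattern
    realizes on the reference plane; ``pattern_direction`` states whether
    the fringes run along image rows or columns.
    """

    images: np.ndarray  # (N_phase, H, W)
    phase_shifts: tuple[float, ...]
    nominal_frequency: float = 0.0
    pattern_direction: str = "rows"

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (N_phase, H, W) array")
        n = self.images.shape[0]
        if n < 3:
            raise ValueError(f"at least 3 phase shifts required, got {n}")
        if len(self.phase_shifts) != n:
            raise ValueError("number of phase shifts must match number of frames")
        shifts = np.mod(np.asarray(self.phase_shifts, dtype=float), 2.0 * np.pi)
        if np.min(np.abs(shifts[:, None] - shifts[None, :]) + np.eye(n) * 10) < 1e-9:
            raise ValueError("phase shifts must be distinct modulo 2 pi")


@dataclass
class DemodResult:
    """Per-pixel demodulation output for one spatial frequency."""

    i_dc: np.ndarray
    i_ac: np.ndarray
    phase_wrapped: np.ndarray
    phase_unwrapped: np.ndarray | None = None
    validity_mask: np.ndarray | None = None
    nominal_frequency: float = 0.0
    metadata: dict = field(default_factory=dict)

    @property
    def phase(self) -> np.ndarray:
        return self.phase_unwrapped if self.phase_unwrapped is not None else self.phase_wrapped


def demodulate(
    stack: FringeStack,
    eps_abs: float = 1e-6,
    eps_rel: float = 0.01,
) -> DemodResult:
    """Demodulate a fringe stack into I_DC, I_AC and wrapped phase.

    Pixels with modulation amplitude below ``max(eps_abs, eps_rel *
    median(i_ac))`` are masked invalid (their phase is undefined) rather
    than raising.
    """
    imgs = stack.images
    shifts = np.asarray(stack.phase_shifts, dtype=float)
    n = len(shifts)

    if n == 3 and np.allclose(np.sort(np.mod(shifts, 2 * np.pi)), _THREE_STEP, atol=1e-12):
        order = np.argsort(np.mod(shifts, 2 * np.pi))
        i1, i2, i3 = (imgs[k] for k in order)
        i_dc = (i1 + i2 + i3) / 3.0
        # I_i = DC + AC cos(phi + delta_i); cos/sin quadratures
        c = (2.0 * i1 - i2 - i3) / 3.0  # = AC cos(phi)
        s = (i3 - i2) / np.sqrt(3.0)  # = AC sin(phi)
        i_ac = np.hypot(c, s)
        phase = np.arctan2(s, c)
    else:
        # general least squares: basis [1, cos(delta), -sin(delta)]
        a = np.stack([np.ones(n), np.cos(shifts), -np.sin(shifts)], axis=1)
        flat = imgs.reshape(n, -1)
        coef, *_ = np.linalg.lstsq(a, flat, rcond=None)
        i_dc = coef[0].reshape(imgs.shape[1:])
        c = coef[1].reshape(imgs.shape[1:])
        s = coef[2].reshape(imgs.shape[1:])
        i_ac = np.hypot(c, s)
        phase = np.arctan2(s, c)

    thresh = max(eps_abs, eps_rel * float(np.median(i_ac)))
    valid = i_ac > thresh
    phase = np.where(valid, phase, 0.0)
    return DemodResult(
        i_dc=i_dc,
        i_ac=i_ac,
        phase_wrapped=phase,
        validity_mask=valid,
        nominal_frequency=stack.nominal_frequency,
        metadata={"ac_threshold": thresh, "n_phases": n},
    )


def _wrap(phase: np.ndarray) -> np.ndarray:
    return np.mod(phase + np.pi, 2.0 * np.pi) - np.pi


def unwrap_phase(
    phase_wrapped: np.ndarray,
    validity_mask: np.ndarray | None = None,
    anchor: np.ndarray | None = None,
    anchor_scale: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """Unwrap a wrapped phase map spatially or against a temporal anchor.

    Without an anchor the map is unwrapped spatially (reliability-sorted
    algorithm); disconnected valid regions are unwrapped independently and
    flagged in the returned metadata.  With an ``anchor`` (an already
    unwrapped lower-frequency phase map), each pixel independently picks the
    2-pi branch closest to ``anchor * anchor_scale`` (temporal unwrapping),
    where ``anchor_scale`` is the ratio of the two frequencies.

    Returns ``(phase_unwrapped, metadata)``; the result is congruent to the
    input modulo 2 pi on valid pixels.
    """
    phase = np.asarray(phase_wrapped, dtype=float)
    meta: dict = {"method": "temporal" if anchor is not None else "spatial"}

    if anchor is not None:
        target = np.asarray(anchor, dtype=float) * anchor_scale
        k = np.round((target - phase) / (2.0 * np.pi))
        return phase + 2.0 * np.pi * k, meta

    if validity_mask is None:
        valid = np.ones(phase.shape, dtype=bool)
    else:
        valid = np.asarray(validity_mask, dtype=bool)

    from scipy import ndimage

    labels, n_comp = ndimage.label(valid)
    meta["n_components"] = int(n_comp)
    meta["disconnected"] = bool(n_comp > 1)

    if np.all(valid):
        out = np.asarray(_skimage_unwrap(phase))
    else:
        masked = np.ma.masked_array(phase, mask=~valid)
        out = np.ma.filled(_skimage_unwrap(masked), 0.0)
        out = np.where(valid, out, phase)
    # keep congruence: unwrap_phase may shift by a global constant per component
    delta = _wrap(out - phase)
    out = out - delta  # remove any numerical drift from the wrapped branch
    return out, meta
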