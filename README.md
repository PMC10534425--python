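# sfdical

Model-based geometric and intensity calibration for **spatial frequency
domain imaging (SFDI)**, with the derived spatial-frequency and intensity
corrections that turn raw fringe images of displaced, tilted or curved
turbid samples into quantitative diffuse reflectance and optical
properties (μs′, μa).

SFDI projects sinusoidal patterns onto a scattering sample and demodulates
the diffusely reflected light per camera pixel into the offset I_DC, the
modulation amplitude I_AC and the phase. Quantitative evaluation rests on
two calibrations of the projector–camera pair, both built on the pinhole
camera model `s·p = A·[R|t]·P`:

1. **Geometric calibration** — a printed circle grid is imaged in several
   orientations; phase-shifted patterns along the DMD rows and columns
   encode, at every detected marker, the projector pixel that illuminates
   it, so camera *and* projector are solved as pinhole models (intrinsics
   `fx, fy, cx, cy`, radial/tangential distortion, pose) and unified in one
   frame. From this follow a reference plane, per-pixel ray fields,
   predistorted patterns that realize exact metric frequencies (mm⁻¹) on
   the reference plane, and a per-pixel cubic phase–distance polynomial
   `l(u,v) = Σ aₖ φᵏ` that converts an unwrapped phase map into a 3D surface.
2. **Intensity calibration** — a reflectance standard measured at several
   positions and spatial frequencies yields a per-pixel look-up
   hypersurface `MTF_ref(l, f)` capturing the system's frequency- and
   defocus-dependent response.

For a measured sample the surface, its k-NN PCA normals and the local
projection/detection angles give per-pixel corrections: the local spatial
frequency `f_corr = f_ref · S_z · S_ang,∥` (magnification plus tilt
scaling) and a Lambert cosine normalization; the diffuse reflectance
follows as `R_SFD = (I_AC / S_Lambert) / MTF_ref(l, f_corr) · R_ref(f_corr)`
and a semi-infinite diffusion forward model `R(f; μa, μs′)` is fitted per
16×16-binned pixel by bounded nonlinear least squares.

A **digital twin** renders the whole acquisition chain (distorted pinhole
devices, 35° oblique projection, 21.6 mm field at 320 mm, illumination
falloff, Lambertian foreshortening, defocus MTF, sensor noise) from known
ground truth, so every stage of the pipeline is testable without hardware.

## Worked example

```python
import numpy as np
from sfdical import twin as tw
from sfdical.geom_calib import build_ray_fields
from sfdical.surface import fit_phase_distance
from sfdical.pipeline import build_intensity_calibration, process_measurement
from sfdical.inversion import invert_map

config = tw.default_config(camera_shape=(128, 128), projector_shape=(128, 72))
geometry = tw.truth_geometry(config)           # or calibrate_from_poses(...)
rays = build_ray_fields(geometry)["camera"]
model = fit_phase_distance(geometry, n_planes=10, ray_field=rays)

# intensity calibration from a white standard at 6 positions
refs = tw.render_reference_stack(config)
f_tab = np.linspace(0, 1, 51)
lut = build_intensity_calibration(refs, geometry, model,
                                  (f_tab, np.full_like(f_tab, 0.95)), rays)

# measure a 40 mm hemispherical phantom (mu_s' = 1.98, mu_a = 0.18 mm^-1)
scene = tw.TwinScene(surface=tw.SphereCap(radius=40.0, apex=(0, 0, 320.0)),
                     reflectance=tw.SfdReflectance(mu_a=0.18, mu_s_prime=1.98))
meas = tw.render_measurement(scene, config, (0.01, 0.098, 0.186, 0.274, 0.362, 0.45))
refl, surface = process_measurement(meas.stacks, geometry, model, lut, rays)
props = invert_map(refl.r_ac, refl.f_corr, refl.valid, bin_factor=16)
print(f"median mu_s' = {np.nanmedian(props['mu_s_prime']):.3f} mm^-1  "
      f"(mean |error| {100*np.nanmean(abs(props['mu_s_prime']-1.98)/1.98):.1f} %)")
print(f"median mu_a  = {np.nanmedian(props['mu_a']):.3f} mm^-1  "
      f"(mean |error| {100*np.nanmean(abs(props['mu_a']-0.18)/0.18):.1f} %)")
print(f"corrected frequency range at 0.45 mm^-1: "
      f"{np.nanmin(refl.f_corr[-1][refl.valid[-1]]):.3f} - "
      f"{np.nanmax(refl.f_corr[-1][refl.valid[-1]]):.3f} mm^-1")
```

prints

```
median mu_s' = 2.052 mm^-1  (mean |error| 3.8 %)
median mu_a  = 0.181 mm^-1  (mean |error| 2.7 %)
corrected frequency range at 0.45 mm^-1: 0.345 - 0.513 mm^-1
```

The curvature and oblique projection spread the nominal 0.45 mm⁻¹ pattern
over roughly 0.35–0.51 mm⁻¹ on the sample surface; taking that (and the
Lambert and MTF normalizations) into account, the fitted scattering and
absorption maps recover the ground truth to a few percent, noise-free.
Skipping the corrections inflates these errors to tens of percent
(see `tests/test_pipeline.py`).

A thin CLI wraps the same pipeline: `sfdical twin`, `sfdical calib
geometry`, `sfdical run`, `sfdical invert` (see `sfdical --help`).

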