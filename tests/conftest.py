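"""Shared twin fixtures: a downscaled but metrically full-scale SFDI setup.

All fixtures are session-scoped and noise-free unless a test re-renders
with its own noise settings; images are 128x128 (camera) / 128x72 (DMD)
with the nominal tabletop geometry (21.6 mm field at 320 mm, 35 deg
oblique projection).
"""

from __future__ import annotations

import numpy as np
import pytest

from sfdical import twin as tw
from sfdical.geom_calib import build_ray_fields
from sfdical.pipeline import build_intensity_calibration
from sfdical.surface import fit_phase_distance

F_LIST = (0.01, 0.098, 0.186, 0.274, 0.362, 0.45)
MU_S_TRUE = 1.98
MU_A_TRUE = 0.18


@pytest.fixture(scope="session")
def config():
    return tw.default_config(camera_shape=(128, 128), projector_shape=(128, 72))


@pytest.fixture(scope="session")
def geometry(config):
    return tw.truth_geometry(config)


@pytest.fixture(scope="session")
def ray_field(geometry):
    return build_ray_fields(geometry)["camera"]


@pytest.fixture(scope="session")
def pd_model(geometry, ray_field):
    return fit_phase_distance(geometry, n_planes=10, f_model=0.45, ray_field=ray_field)


@pytest.fixture(scope="session")
def reference_renders(config):
    return tw.render_reference_stack(config)


@pytest.fixture(scope="session")
def r_ref_table():
    f = np.linspace(0.0, 1.0, 51)
    return f, np.full_like(f, 0.95)


@pytest.fixture(scope="session")
def mtf_lut(reference_renders, geometry, pd_model, r_ref_table, ray_field):
    return build_intensity_calibration(
        reference_renders, geometry, pd_model, r_ref_table, ray_field
    )


@pytest.fixture(scope="session")
def flat_measurement(config):
    scene = tw.TwinScene(surface=tw.Plane(point=(0.0, 0.0, 320.0)), reflectance=tw.LambertianAlbedo())
    return tw.render_measurement(scene, config, F_LIST)


@pytest.fixture(scope="session")
def hemisphere_measurement(config):
    scene = tw.TwinScene(
        surface=tw.SphereCap(radius=40.0, apex=(0.0, 0.0, 320.0)),
        reflectance=tw.SfdReflectance(mu_a=MU_A_TRUE, mu_s_prime=MU_S_TRUE),
    )
    return tw.render_measurement(scene, config, F_LIST)


def inner_mask(valid: np.ndarray, border: int = 5) -> np.ndarray:
    """Valid mask away from the image border (normals degrade at the rim)."""
    m = valid.copy()
    m[:border] = m[-border:] = False
    m[:, :border] = m[:, -border:] = False
    return m
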