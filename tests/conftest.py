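"""Shared fixtures: the expensive reference simulations are run once per
session and reused by the metric and acceptance tests."""

import warnings

import pytest
from hypothesis import settings as hyp_settings

import tfusim as tf
from tfusim.fixtures import make_fixture
from tfusim.scene import ACRYLIC, PlateSpec, reference_scene

hyp_settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=50)
hyp_settings.load_profile("ci")

#: pure-water focal pressure used to calibrate the drive amplitude [Pa]
TARGET_FOCAL_PA = 549.3e3


def run_quiet(scene, settings=None, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if settings is None:
            settings = tf.SolverSettings()
        return tf.run_to_steady(scene, settings, **kw)


@pytest.fixture(scope="session")
def calibrated_p0():
    scene = reference_scene(resolution="coarse")
    return tf.calibrate_source(scene, TARGET_FOCAL_PA)


@pytest.fixture(scope="session")
def water_field(calibrated_p0):
    """Nonlinear pure-water reference run at coarse resolution."""
    scene = reference_scene(resolution="coarse",
                            surface_pressure=calibrated_p0)
    return run_quiet(scene)


@pytest.fixture(scope="session")
def plate_scene(calibrated_p0):
    plate = PlateSpec(thickness=8e-3, curvature_radius=60e-3,
                      standoff=10e-3, material=ACRYLIC)
    return reference_scene(plate=plate, resolution="coarse",
                           surface_pressure=calibrated_p0)


@pytest.fixture(scope="session")
def plate_field(plate_scene):
    """Nonlinear run with the reference acrylic plate (T8/R60/D10)."""
    return run_quiet(plate_scene)


@pytest.fixture(scope="session")
def sweep_results(calibrated_p0):
    """All seven study sweeps at coarse resolution (the expensive part of
    the acceptance checks; a few minutes in total)."""
    out = {}
    for param in ("T", "R", "D", "rho", "c", "alpha", "combined"):
        spec = tf.paper_sweep_spec(param, surface_pressure=calibrated_p0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[param] = tf.run_sweep(spec)
    return out


@pytest.fixture(scope="session")
def mini_bowl_field():
    """Linear lossless miniature bowl at lambda/8 with quadrature amplitude
    extraction (the focal-gain verification field)."""
    scene = make_fixture("bowl_lossless")
    return run_quiet(scene, tf.SolverSettings(
        linear=True, lossless=True, amplitude_method="quadrature")), scene
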