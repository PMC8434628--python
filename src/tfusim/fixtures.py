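"""Miniature scenes that run in seconds, for verification and CI.

Every fixture is built programmatically (no data files) and is small enough
that a steady-state solve takes seconds on one CPU.  They are deliberately
not the study scene: a smaller bowl at a lower frequency keeps cell counts
tiny while preserving the physics each fixture isolates (focal gain,
interface transmission, absorption, plate aberration).
"""

from __future__ import annotations

from dataclasses import replace

from .exceptions import UnknownFixtureError
from .scene import (ACRYLIC, Material, PlateSpec, SceneConfig, TransducerSpec,
                    WATER, build_grid, choose_time_step)

#: lossless water (for linear focal-gain checks against the bowl oracle)
WATER_LOSSLESS = Material(density=WATER.density, sound_speed=WATER.sound_speed,
                          absorption=0.0, nonlinearity=0.0)
#: lossless acrylic (for impedance-step transmission checks)
ACRYLIC_LOSSLESS = Material(density=ACRYLIC.density,
                            sound_speed=ACRYLIC.sound_speed,
                            absorption=0.0, nonlinearity=0.0)

#: miniature bowl used by several fixtures: 0.45 MHz, 36 mm aperture,
#: 30 mm focal length, no hole
MINI_BOWL = TransducerSpec(frequency=0.45e6, aperture_diameter=0.036,
                           focal_length=0.030, hole_diameter=0.0,
                           surface_pressure=1.0e4)


def _mini_bowl_scene(medium: Material, ppw: int, plate=None,
                     mode: str = "axisymmetric") -> SceneConfig:
    tr = MINI_BOWL
    dx = tr.wavelength(medium) / ppw
    mats = [medium] + ([plate.material] if plate is not None else [])
    c_max = max(m.sound_speed for m in mats)
    d_max = max(m.effective_diffusivity(tr.frequency) for m in mats)
    dt = choose_time_step(dx, mode, c_max, d_max, tr.frequency)
    extents = ((0.045, 0.020) if mode == "axisymmetric"
               else (0.045, 0.040, 0.040))
    grid = build_grid(mode, dx, dt, extents, c_max=c_max)
    return SceneConfig(grid=grid, transducer=tr, background=medium,
                       plate=plate)


def _slab_1d_scene() -> SceneConfig:
    """1D water path with a 3.25 mm acrylic slab at z = 60 mm.

    The slab thickness sits near quarter-wave (quadrature) resonance so that
    steady transmission is within ~1.5% of the single-pass closed form
    T12 * T21 * exp(-alpha L) (internal multiples nearly cancel)."""
    tr = TransducerSpec(frequency=0.9e6, aperture_diameter=0.02,
                        focal_length=1.0, hole_diameter=0.0,
                        surface_pressure=1.0e4)
    dx = tr.wavelength(WATER) / 16
    c_max = ACRYLIC.sound_speed
    d_max = max(WATER.effective_diffusivity(tr.frequency),
                ACRYLIC.effective_diffusivity(tr.frequency))
    dt = choose_time_step(dx, "1d", c_max, d_max, tr.frequency)
    grid = build_grid("1d", dx, dt, (0.120,), c_max=c_max)
    plate = PlateSpec(thickness=3.25e-3, curvature_radius=1.0,
                      standoff=0.060, material=ACRYLIC)
    return SceneConfig(grid=grid, transducer=tr, background=WATER,
                       plate=plate)


def _plate_in_water_scene() -> SceneConfig:
    """Miniature bowl with a thin curved plate in the prefocal path."""
    plate = PlateSpec(thickness=3.0e-3, curvature_radius=0.025,
                      standoff=4.0e-3, material=ACRYLIC)
    return _mini_bowl_scene(WATER, ppw=6, plate=plate)


_FIXTURES = {
    "bowl_lossless": lambda: _mini_bowl_scene(WATER_LOSSLESS, ppw=8),
    "bowl_water": lambda: _mini_bowl_scene(WATER, ppw=6),
    "slab_1d": _slab_1d_scene,
    "plate_water": _plate_in_water_scene,
}


def fixture_names() -> tuple:
    return tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> SceneConfig:
    """Return a documented miniature scene by name.

    Available: ``bowl_lossless`` (linear lossless focal-gain reference at
    lambda/8), ``bowl_water`` (same bowl in absorbing water at lambda/6),
    ``slab_1d`` (plane-wave transmission through an acrylic slab), and
    ``plate_water`` (miniature bowl with a curved plate).
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    return builder()


def mini_bowl_scene(medium: Material = WATER_LOSSLESS, ppw: int = 8,
                    plate=None, mode: str = "axisymmetric") -> SceneConfig:
    """Parametrizable miniature bowl scene (used by convergence and
    axisymmetric-vs-3D agreement tests)."""
    return _mini_bowl_scene(medium, ppw, plate=plate, mode=mode)
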