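"""Scene definition: materials, transducer, skull-plate geometry, and their
rasterization onto the simulation grid.

The physical arrangement is a single-element focused bowl transducer radiating
along +z into water, with an optional spherical-shell plate (a homogeneous
skull phantom) inserted between the transducer rim and the focus.  Coordinates:
z = 0 at the bowl apex, beam along +z, cell-center convention on every axis.

Units are SI throughout (m, s, Hz, Pa, kg/m^3); absorption is stored in
Np/m/MHz with linear-in-frequency scaling.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from ._kernels import K2_MAX as _K2_MAX
from .exceptions import ConfigSchemaError, GeometryError, InvalidConfigError

DB_PER_NEPER = 20.0 / math.log(10.0)  # 8.6859 dB per Np

#: spatial dimensionality of the finite-difference stencil per grid mode
STENCIL_DIMS = {"1d": 1, "axisymmetric": 2, "3d": 3}

#: grid resolution presets, in points per wavelength in water at the drive
#: frequency.  "paper" matches a lambda/8 discretization, "coarse" (lambda/4)
#: is the desk-scale default for sweeps, "ci" is for miniature test scenes.
RESOLUTION_PPW = {"paper": 8, "coarse": 4, "ci": 6}


# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """Homogeneous acoustic medium.

    Parameters
    ----------
    density : float
        Equilibrium density rho [kg/m^3].
    sound_speed : float
        Small-signal sound speed c [m/s].
    absorption : float
        Amplitude absorption coefficient alpha0 [Np/m/MHz]; the absorption at
        frequency f is ``alpha0 * f_MHz`` (linear-in-frequency scaling).
    nonlinearity : float
        Coefficient of nonlinearity beta (dimensionless).
    """

    density: float
    sound_speed: float
    absorption: float = 0.0
    nonlinearity: float = 0.0

    def __post_init__(self) -> None:
        if self.density <= 0 or self.sound_speed <= 0:
            raise InvalidConfigError("density and sound_speed must be positive")
        if self.absorption < 0 or self.nonlinearity < 0:
            raise InvalidConfigError("absorption and nonlinearity must be >= 0")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance Z = rho * c [Pa s/m]."""
        return self.density * self.sound_speed

    def alpha_np(self, frequency: float) -> float:
        """Absorption [Np/m] at ``frequency`` [Hz]."""
        return self.absorption * frequency / 1e6

    def diffusivity(self, frequency: float) -> float:
        """Thermoviscous sound diffusivity delta [m^2/s] equivalent to the
        absorption at ``frequency``: delta = 2 alpha c^3 / omega^2."""
        omega = 2.0 * math.pi * frequency
        return 2.0 * self.alpha_np(frequency) * self.sound_speed**3 / omega**2

    def effective_diffusivity(self, frequency: float) -> float:
        """Loss coefficient delta' that makes the solver's d/dt grad^2 loss
        operator realize exactly this material's absorption at ``frequency``.

        The operator's dispersion relation is k = (omega/c)(1 - i X)^{-1/2}
        with X = omega delta'/c^2.  Requiring Im k = alpha (i.e. g = alpha
        c/omega) has the closed-form solution

            u = (1 - 2 g^2 + sqrt(1 - 8 g^2)) / 2,   X = 2 sqrt(u) g/(u+g^2)^2,

        which reduces to the standard delta = 2 alpha c^3/omega^2 as g -> 0
        but grows faster for strongly absorbing media (skull-like absorption
        reaches g ~ 0.2-0.35, where the uncorrected relation would fall short
        of the stated alpha by 10-25%).  The largest realizable absorption of
        this operator is g = 1/(2 sqrt(2)); beyond it the coefficient is
        capped and the realized absorption saturates slightly below target.
        """
        omega = 2.0 * math.pi * frequency
        g = self.alpha_np(frequency) * self.sound_speed / omega
        if g <= 0.0:
            return 0.0
        g = min(g, 0.999 / (2.0 * math.sqrt(2.0)))
        u = 0.5 * (1.0 - 2.0 * g**2 + math.sqrt(1.0 - 8.0 * g**2))
        x = 2.0 * math.sqrt(u) * g / (u + g**2) ** 2
        return x * self.sound_speed**2 / omega

    @classmethod
    def from_db_per_m(cls, density: float, sound_speed: float,
                      alpha_db_per_m: float, frequency: float,
                      nonlinearity: float = 0.0) -> "Material":
        """Build a material whose absorption is given in dB/m *at* the stated
        frequency (1 Np = 8.686 dB), e.g. skull-model sweep values."""
        alpha_np = alpha_db_per_m / DB_PER_NEPER
        return cls(density, sound_speed, alpha_np / (frequency / 1e6),
                   nonlinearity)


#: degassed water at room temperature
WATER = Material(density=998.2, sound_speed=1482.0, absorption=0.02,
                 nonlinearity=3.5)

#: acrylic (PMMA) skull phantom plate
ACRYLIC = Material(density=1203.0, sound_speed=2600.0, absorption=18.0,
                   nonlinearity=4.4)


# ---------------------------------------------------------------------------
# transducer / plate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransducerSpec:
    """Single-element spherically focused bowl transducer.

    The radiating surface is a spherical cap of curvature radius equal to
    ``focal_length`` whose apex sits at z = 0; a concentric circular hole may
    be cut out of the middle (annular aperture).  The drive is a continuous
    sine of amplitude ``surface_pressure`` at ``frequency``, in phase across
    the cap (geometric focusing arises from the cap curvature alone).
    """

    frequency: float = 0.9e6
    aperture_diameter: float = 0.100
    focal_length: float = 0.080
    hole_diameter: float = 0.050
    surface_pressure: float = 1.0e4

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.focal_length <= 0:
            raise InvalidConfigError("frequency and focal_length must be > 0")
        if not (0 <= self.hole_diameter < self.aperture_diameter):
            raise InvalidConfigError(
                "need 0 <= hole_diameter < aperture_diameter")
        if self.aperture_diameter / 2 > self.focal_length:
            raise GeometryError(
                "aperture radius exceeds focal length; spherical cap undefined")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency

    def wavelength(self, medium: Material = WATER) -> float:
        return medium.sound_speed / self.frequency

    def cap_z(self, r) -> np.ndarray:
        """Axial position of the cap surface at transverse radius ``r``."""
        rf = self.focal_length
        return rf - np.sqrt(rf**2 - np.asarray(r, dtype=float) ** 2)

    @property
    def rim_z(self) -> float:
        """z of the bowl rim plane (the transducer's "open end")."""
        return float(self.cap_z(self.aperture_diameter / 2))

    @property
    def half_angle(self) -> float:
        """Half-angle subtended by the outer aperture at the focus [rad]."""
        return math.asin(self.aperture_diameter / 2 / self.focal_length)


@dataclass(frozen=True)
class PlateSpec:
    """Spherical-shell skull-model plate.

    The shell lies between two concentric spheres of radii ``curvature_radius``
    (R) and R - ``thickness`` (T), centered on the beam axis.  Its convex face
    points toward the transducer, and ``standoff`` (D) is measured along the
    axis from the transducer rim plane to the nearest plate surface.
    """

    thickness: float
    curvature_radius: float
    standoff: float
    material: Material

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InvalidConfigError("plate thickness must be > 0")
        if self.curvature_radius < self.thickness:
            raise InvalidConfigError("curvature_radius must be >= thickness")
        if self.standoff < 0:
            raise InvalidConfigError("standoff must be >= 0")


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationGrid:
    """Uniform cell-centered grid.

    ``extents`` are physical side lengths ordered like the array shape:
    (z,) in 1d, (z, r) in axisymmetric mode, and (z, y, x) in 3d.  Cell
    centers sit at (i + 1/2) dx; in 3d the transverse axes are centered on
    the beam axis.
    """

    mode: str
    dx: float
    dt: float
    extents: tuple

    @property
    def shape(self) -> tuple:
        return tuple(int(round(e / self.dx)) for e in self.extents)

    def _centers(self, n: int) -> np.ndarray:
        return (np.arange(n) + 0.5) * self.dx

    @property
    def z(self) -> np.ndarray:
        return self._centers(self.shape[0])

    @property
    def r(self) -> np.ndarray:
        if self.mode != "axisymmetric":
            raise AttributeError("r axis only defined in axisymmetric mode")
        return self._centers(self.shape[1])

    @property
    def y(self) -> np.ndarray:
        if self.mode != "3d":
            raise AttributeError("y axis only defined in 3d mode")
        return self._centers(self.shape[1]) - self.extents[1] / 2

    @property
    def x(self) -> np.ndarray:
        if self.mode != "3d":
            raise AttributeError("x axis only defined in 3d mode")
        return self._centers(self.shape[2]) - self.extents[2] / 2

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def transverse_radius(self) -> np.ndarray:
        """Distance of every cell center from the beam axis, shaped like the
        transverse part of the grid (scalar 0 in 1d)."""
        if self.mode == "1d":
            return np.zeros(1)
        if self.mode == "axisymmetric":
            return self.r
        yy, xx = np.meshgrid(self.y, self.x, indexing="ij")
        return np.hypot(xx, yy)


def cfl_dt_max(dx: float, c_max: float, mode: str) -> float:
    """Classical CFL bound dt <= dx / (c_max sqrt(d)) for a d-dimensional
    3-point stencil (the reference bound quoted in stability reports)."""
    return dx / (c_max * math.sqrt(STENCIL_DIMS[mode]))


def loss_dt_max(dx: float, delta_max: float, mode: str) -> float:
    """Classical stability bound of the explicit thermoviscous-loss term,
    dt <= dx^2 / (2 d delta)."""
    if delta_max <= 0:
        return math.inf
    return dx**2 / (2.0 * STENCIL_DIMS[mode] * delta_max)


# The 8th-order spatial stencil has a larger peak eigenvalue than the
# classical 3-point one (K2_MAX vs 4, in 1/dx^2 units).
SCHEME_CFL_FACTOR = 2.0 / math.sqrt(_K2_MAX)     # ~0.784


def scheme_dt_max(dx: float, c_max: float, delta_max: float, mode: str,
                  margin: float = 1.0) -> float:
    """Largest stable dt of the implemented scheme.

    Von Neumann analysis of the explicit update with the loss term gives the
    *combined* condition s + 2 q <= 4 at the grid Nyquist mode, where
    s = c^2 dt^2 k2max and q = delta dt k2max with k2max = K2_MAX d / dx^2
    the stencil's largest eigenvalue.  (The two terms interact: enforcing
    the pure-wave and pure-loss bounds separately admits time steps that
    blow up when absorption and speed are both moderately large.)
    ``delta_max`` must be the solver's effective loss coefficient.
    """
    k2 = _K2_MAX * STENCIL_DIMS[mode] / dx**2
    a = c_max**2 * k2
    b = 2.0 * delta_max * k2
    return (-b + math.sqrt(b**2 + 16.0 * margin * a)) / (2.0 * a)


def choose_time_step(dx: float, mode: str, c_max: float,
                     delta_max: float = 0.0,
                     frequency: Optional[float] = None,
                     safety: float = 0.8) -> float:
    """Stable time step with a safety margin, additionally capped at 20
    samples per drive period when ``frequency`` is given.  ``delta_max``
    is the largest effective loss coefficient among the media."""
    dt = scheme_dt_max(dx, c_max, delta_max, mode, margin=safety)
    if frequency is not None:
        dt = min(dt, 1.0 / (20.0 * frequency))
    return dt


def build_grid(mode: str, dx: float, dt: float, extents: Sequence[float],
               c_max: float = 5000.0) -> SimulationGrid:
    """Construct a grid, rejecting time steps that violate the CFL bound for
    the fastest medium declared (``c_max``)."""
    if mode not in STENCIL_DIMS:
        raise InvalidConfigError(f"unknown grid mode {mode!r}")
    if dx <= 0 or dt <= 0:
        raise InvalidConfigError("dx and dt must be positive")
    extents = tuple(float(e) for e in extents)
    if len(extents) != STENCIL_DIMS[mode]:
        raise InvalidConfigError(
            f"{mode} grid needs {STENCIL_DIMS[mode]} extents, got {len(extents)}")
    if any(e <= 0 for e in extents):
        raise InvalidConfigError("extents must be positive")
    dt_max = cfl_dt_max(dx, c_max, mode)
    if dt > dt_max:
        raise InvalidConfigError(
            f"dt = {dt:.3e} s violates the stability bound "
            f"dx/(c_max sqrt(d)) = {dt_max:.3e} s for c_max = {c_max} m/s")
    return SimulationGrid(mode=mode, dx=dx, dt=dt, extents=extents)


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Complete definition of one simulation: grid, transducer, background
    medium (water) and an optional skull-model plate."""

    grid: SimulationGrid
    transducer: TransducerSpec
    background: Material = WATER
    plate: Optional[PlateSpec] = None

    @property
    def points_per_wavelength(self) -> float:
        """Spatial sampling of the drive wavelength in the background medium."""
        return self.transducer.wavelength(self.background) / self.grid.dx

    def materials(self):
        mats = [self.background]
        if self.plate is not None:
            mats.append(self.plate.material)
        return mats

    @property
    def c_max(self) -> float:
        return max(m.sound_speed for m in self.materials())

    @property
    def c_min(self) -> float:
        return min(m.sound_speed for m in self.materials())

    @property
    def delta_max(self) -> float:
        f = self.transducer.frequency
        return max(m.effective_diffusivity(f) for m in self.materials())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "grid": {
                "mode": self.grid.mode,
                "dx_m": self.grid.dx,
                "dt_s": self.grid.dt,
                "extents_m": list(self.grid.extents),
            },
            "transducer": {
                "frequency_hz": self.transducer.frequency,
                "aperture_diameter_m": self.transducer.aperture_diameter,
                "focal_length_m": self.transducer.focal_length,
                "hole_diameter_m": self.transducer.hole_diameter,
                "surface_pressure_pa": self.transducer.surface_pressure,
            },
            "background": _material_dict(self.background),
        }
        if self.plate is not None:
            d["plate"] = {
                "thickness_m": self.plate.thickness,
                "curvature_radius_m": self.plate.curvature_radius,
                "standoff_m": self.plate.standoff,
                "material": _material_dict(self.plate.material),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        try:
            g = d["grid"]
            grid = build_grid(g["mode"], g["dx_m"], g["dt_s"], g["extents_m"],
                              c_max=_scene_c_max(d))
            t = d["transducer"]
            transducer = TransducerSpec(
                frequency=t["frequency_hz"],
                aperture_diameter=t["aperture_diameter_m"],
                focal_length=t["focal_length_m"],
                hole_diameter=t.get("hole_diameter_m", 0.0),
                surface_pressure=t.get("surface_pressure_pa", 1.0e4),
            )
            background = _material_from_dict(d["background"])
            plate = None
            if d.get("plate") is not None:
                p = d["plate"]
                plate = PlateSpec(
                    thickness=p["thickness_m"],
                    curvature_radius=p["curvature_radius_m"],
                    standoff=p["standoff_m"],
                    material=_material_from_dict(p["material"]),
                )
        except KeyError as exc:
            raise ConfigSchemaError(
                f"missing required configuration key: {exc.args[0]!r}") from exc
        return cls(grid=grid, transducer=transducer, background=background,
                   plate=plate)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SceneConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(str(source))
        if not isinstance(d, dict):
            raise ConfigSchemaError("scene configuration must be a mapping")
        return cls.from_dict(d)

    def hash(self) -> str:
        """Stable content hash of the scene (key order independent)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_(self, **kwargs) -> "SceneConfig":
        return replace(self, **kwargs)


def _material_dict(m: Material) -> dict:
    return {
        "density_kg_m3": m.density,
        "sound_speed_m_s": m.sound_speed,
        "absorption_np_m_mhz": m.absorption,
        "nonlinearity": m.nonlinearity,
    }


def _material_from_dict(d: dict) -> Material:
    try:
        return Material(
            density=d["density_kg_m3"],
            sound_speed=d["sound_speed_m_s"],
            absorption=d.get("absorption_np_m_mhz", 0.0),
            nonlinearity=d.get("nonlinearity", 0.0),
        )
    except KeyError as exc:
        raise ConfigSchemaError(
            f"missing required material key: {exc.args[0]!r}") from exc


def _scene_c_max(d: dict) -> float:
    cs = [d.get("background", {}).get("sound_speed_m_s", WATER.sound_speed)]
    if d.get("plate") is not None:
        cs.append(d["plate"].get("material", {})
                  .get("sound_speed_m_s", cs[0]))
    return max(cs)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _plate_axis_origin(plate: PlateSpec, transducer: TransducerSpec,
                       mode: str) -> float:
    """z where the plate's near face crosses the axis.  In 1d mode the source
    is a piston at z = 0, so the rim plane is z = 0."""
    rim = 0.0 if mode == "1d" else transducer.rim_z
    return rim + plate.standoff


def rasterize_plate(plate: PlateSpec, grid: SimulationGrid,
                    transducer: TransducerSpec) -> np.ndarray:
    """Boolean occupancy mask of the spherical-shell plate.

    A cell belongs to the plate iff its center lies between the two concentric
    spheres of radii R and R - T whose center sits on the axis at
    z0 + R, where z0 is the near-face axis crossing (rim plane + standoff).
    In 1d mode the shell degenerates to a flat slab [z0, z0 + T).
    """
    z0 = _plate_axis_origin(plate, transducer, grid.mode)
    z = grid.z
    if z0 < 0 or z0 + plate.thickness > grid.extents[0]:
        raise GeometryError("plate does not fit inside the domain along z")
    if grid.mode == "1d":
        return (z >= z0) & (z < z0 + plate.thickness)

    zc = z0 + plate.curvature_radius
    r_out = plate.curvature_radius
    r_in = plate.curvature_radius - plate.thickness
    if grid.mode == "axisymmetric":
        dist = np.hypot(grid.r[None, :], z[:, None] - zc)
    else:
        rho_t = grid.transverse_radius()
        dist = np.sqrt(rho_t[None, :, :] ** 2 + (z[:, None, None] - zc) ** 2)
    mask = (dist >= r_in) & (dist <= r_out)

    # the shell must not cut through the radiating cap surface
    rs = np.linspace(transducer.hole_diameter / 2,
                     transducer.aperture_diameter / 2, 512)
    zs = transducer.cap_z(rs)
    cap_dist = np.hypot(rs, zs - zc)
    half = grid.dx / 2
    if np.any((cap_dist >= r_in - half) & (cap_dist <= r_out + half)):
        raise GeometryError("plate shell intersects the transducer surface")
    return mask


def mask_volume(mask: np.ndarray, grid: SimulationGrid) -> float:
    """Physical volume [m^3] of a cell mask (ring volumes in axisymmetric
    mode, cubes in 3d, lengths in 1d)."""
    if grid.mode == "1d":
        return float(mask.sum()) * grid.dx
    if grid.mode == "axisymmetric":
        ring = 2.0 * math.pi * grid.r * grid.dx**2
        return float((mask * ring[None, :]).sum())
    return float(mask.sum()) * grid.dx**3


@dataclass
class MediumMaps:
    """Per-cell material coefficient maps (piecewise constant)."""

    rho: np.ndarray
    c: np.ndarray
    delta: np.ndarray          # standard 2 alpha c^3 / omega^2
    delta_eff: np.ndarray      # solver loss coefficient (calibrated)
    beta: np.ndarray
    alpha: np.ndarray          # Np/m at the drive frequency
    plate_mask: np.ndarray

    @property
    def c_max(self) -> float:
        return float(self.c.max())

    @property
    def c_min(self) -> float:
        return float(self.c.min())

    @property
    def delta_max(self) -> float:
        """Largest effective loss coefficient (the stability-relevant one)."""
        return float(self.delta_eff.max())


def build_medium_maps(scene: SceneConfig) -> MediumMaps:
    """Assign every grid cell exactly one material's (rho, c, delta, beta)."""
    grid, f = scene.grid, scene.transducer.frequency
    shape = grid.shape
    if scene.plate is not None:
        mask = rasterize_plate(scene.plate, grid, scene.transducer)
    else:
        mask = np.zeros(shape, dtype=bool)

    def paint(attr_water, attr_plate):
        arr = np.full(shape, attr_water, dtype=np.float64)
        if scene.plate is not None:
            arr[mask] = attr_plate
        return arr

    bg, pm = scene.background, (scene.plate.material if scene.plate else None)
    return MediumMaps(
        rho=paint(bg.density, pm.density if pm else 0.0),
        c=paint(bg.sound_speed, pm.sound_speed if pm else 0.0),
        delta=paint(bg.diffusivity(f), pm.diffusivity(f) if pm else 0.0),
        delta_eff=paint(bg.effective_diffusivity(f),
                        pm.effective_diffusivity(f) if pm else 0.0),
        beta=paint(bg.nonlinearity, pm.nonlinearity if pm else 0.0),
        alpha=paint(bg.alpha_np(f), pm.alpha_np(f) if pm else 0.0),
        plate_mask=mask,
    )


# ---------------------------------------------------------------------------
# source
# ---------------------------------------------------------------------------

@dataclass
class SourceDrive:
    """Rasterized source surface with a monochromatic pressure drive.

    ``indices`` is a tuple of integer index arrays (fancy-indexable into the
    field array); the drive is ``amplitude * sin(omega t - phases)``, the
    per-cell ``phases`` compensating the sub-cell staircase offset between
    each cell center and the true cap surface (without it, the +-dx/2 axial
    rasterization error decoheres the focus by several percent at coarse
    resolution).  ``weights`` holds the per-cell surface obliquity factor
    sec(theta) (surface area represented per cell footprint), used by the
    transparent-source forcing so the radiated surface amplitude is uniform.
    """

    indices: tuple
    amplitude: float
    omega: float
    weights: np.ndarray
    phases: np.ndarray

    def value(self, t: float) -> np.ndarray:
        return self.amplitude * np.sin(self.omega * t - self.phases)

    @property
    def n_cells(self) -> int:
        return len(self.indices[0])


#: 1d-mode source cell offset: a few cells inside the domain so the
#: backward-radiated wave of a transparent source can leave through the Mur
#: face behind it
SOURCE_OFFSET_1D = 4


def build_source(transducer: TransducerSpec, grid: SimulationGrid,
                 sound_speed: Optional[float] = None) -> SourceDrive:
    """Rasterize the spherical-cap source surface (annular if a central hole
    is present).  In 1d mode the source is a plane sheet near the z = 0 face.
    ``sound_speed`` is the medium the cap radiates into (water by default),
    used for the sub-cell phase compensation."""
    c_ref = sound_speed if sound_speed is not None else WATER.sound_speed
    p0, omega = transducer.surface_pressure, transducer.omega
    if grid.mode == "1d":
        return SourceDrive(indices=(np.array([SOURCE_OFFSET_1D]),),
                           amplitude=p0, omega=omega, weights=np.ones(1),
                           phases=np.zeros(1))

    a_in = transducer.hole_diameter / 2
    a_out = transducer.aperture_diameter / 2
    rf = transducer.focal_length
    nz = grid.shape[0]

    def z_index(zvals):
        idx = np.rint(zvals / grid.dx - 0.5).astype(np.int64)
        return np.clip(idx, 0, nz - 1)

    def assemble(indices, radii, z_true):
        cos_t = np.sqrt(rf**2 - radii**2) / rf
        z_cell = (indices[0] + 0.5) * grid.dx
        # cell sits (z_cell - z_true) past the cap along z: its wave toward
        # the focus leads by that offset projected on the ray, so delay it
        phases = omega * (z_cell - z_true) * cos_t / c_ref
        return SourceDrive(indices=indices, amplitude=p0, omega=omega,
                           weights=1.0 / cos_t, phases=phases)

    if grid.mode == "axisymmetric":
        if a_out > grid.extents[1]:
            raise GeometryError("transducer aperture exceeds radial extent")
        jr = np.nonzero((grid.r >= a_in) & (grid.r <= a_out))[0]
        if jr.size == 0:
            raise GeometryError("source cap rasterized to zero cells")
        radii = grid.r[jr]
        zc = transducer.cap_z(radii)
        if np.any(zc > grid.extents[0]):
            raise GeometryError("transducer cap exits the domain")
        return assemble((z_index(zc), jr), radii, zc)

    rho_t = grid.transverse_radius()
    sel = (rho_t >= a_in) & (rho_t <= a_out)
    if not sel.any():
        raise GeometryError("source cap rasterized to zero cells")
    if a_out > min(grid.extents[1], grid.extents[2]) / 2:
        raise GeometryError("transducer aperture exceeds transverse extent")
    jy, kx = np.nonzero(sel)
    radii = rho_t[jy, kx]
    zc = transducer.cap_z(radii)
    if np.any(zc > grid.extents[0]):
        raise GeometryError("transducer cap exits the domain")
    return assemble((z_index(zc), jy, kx), radii, zc)


# ---------------------------------------------------------------------------
# reference scene factory
# ---------------------------------------------------------------------------

def default_transducer(surface_pressure: float = 1.0e4) -> TransducerSpec:
    """The study transducer: 0.9 MHz, 100 mm aperture, 80 mm focal length,
    50 mm central hole."""
    return TransducerSpec(surface_pressure=surface_pressure)


def reference_scene(plate: Optional[PlateSpec] = None,
                    resolution: str = "coarse",
                    mode: str = "axisymmetric",
                    surface_pressure: float = 1.0e4,
                    c_max: Optional[float] = None,
                    delta_max: Optional[float] = None) -> SceneConfig:
    """Build the reference 100 mm water-tank scene with the study transducer.

    ``c_max``/``delta_max`` override the stability-governing extremes (useful
    to keep dt identical across a parameter sweep); by default they are taken
    from the scene's own materials.
    """
    tr = default_transducer(surface_pressure)
    mats = [WATER] + ([plate.material] if plate is not None else [])
    cmx = c_max if c_max is not None else max(m.sound_speed for m in mats)
    dmx = delta_max if delta_max is not None else max(
        m.effective_diffusivity(tr.frequency) for m in mats)
    dx = tr.wavelength(WATER) / RESOLUTION_PPW[resolution]
    dt = choose_time_step(dx, mode, cmx, dmx, tr.frequency)
    extents = {"1d": (0.100,), "axisymmetric": (0.100, 0.050),
               "3d": (0.100, 0.100, 0.100)}[mode]
    grid = build_grid(mode, dx, dt, extents, c_max=cmx)
    return SceneConfig(grid=grid, transducer=tr, background=WATER, plate=plate)
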