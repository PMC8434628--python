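"""Parameter sweeps over the skull-model plate and the fitting/agreement
statistics derived from them.

Six sweeps are defined: three structural (plate thickness T, curvature radius
R, standoff distance D — acrylic plate) and three acoustic (density rho,
sound speed c, absorption alpha — skull-like material at fixed T8/R60/D10
geometry), plus a combined sweep that increases rho, c and alpha together by
pairing equal-index values of the three 11-point lists.  Focal pressures per
value feed a linear fit (structural/density/speed) or a three-parameter
power-law fit (absorption), from which per-unit attenuation in dB and
agreement statistics between fitted curves are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (DegenerateDataError, FitConvergenceError,
                         InvalidConfigError, UndefinedCorrelationError)
from .metrics import FocalMetrics, focal_search_floor, summarize
from .scene import (ACRYLIC, Material, PlateSpec, SceneConfig, WATER,
                    build_grid, choose_time_step, reference_scene)
from .solver import SolverSettings, run_to_steady

# ---------------------------------------------------------------------------
# study sweep ranges and fixed defaults
# ---------------------------------------------------------------------------

#: plate thickness sweep [mm]
THICKNESS_MM = [2.0, 6.0, 10.0, 14.0, 18.0, 22.0]
#: plate curvature-radius sweep [mm]
CURVATURE_MM = [60.0, 70.0, 80.0, 90.0, 100.0]
#: plate standoff-distance sweep [mm]
DISTANCE_MM = [float(d) for d in range(11, 21)]
#: skull-model density sweep [kg/m^3]
DENSITY_KG_M3 = [1700.0 + 30.0 * i for i in range(11)]
#: skull-model sound-speed sweep [m/s]
SPEED_M_S = [2000.0 + 300.0 * i for i in range(11)]
#: skull-model absorption sweep [dB/m at the drive frequency]
ABSORPTION_DB_M = [200.0 + 480.0 * i for i in range(11)]
#: combined sweep: equal-index (rho, c, alpha) triples
COMBINED = list(zip(DENSITY_KG_M3, SPEED_M_S, ABSORPTION_DB_M))

#: fixed plate geometry for the acoustic sweeps / reference plate scene [mm]
DEFAULT_T_MM, DEFAULT_R_MM, DEFAULT_D_MM = 8.0, 60.0, 10.0
#: fixed skull-model acoustics when a single acoustic parameter is swept
DEFAULT_RHO, DEFAULT_C, DEFAULT_ALPHA_DB = 1850.0, 3500.0, 2600.0

PARAMETERS = ("T", "R", "D", "rho", "c", "alpha", "combined")
PARAMETER_UNITS = {"T": "mm", "R": "mm", "D": "mm", "rho": "kg/m^3",
                   "c": "m/s", "alpha": "dB/m",
                   "combined": "(kg/m^3, m/s, dB/m)"}
DEFAULT_VALUES = {"T": THICKNESS_MM, "R": CURVATURE_MM, "D": DISTANCE_MM,
                  "rho": DENSITY_KG_M3, "c": SPEED_M_S,
                  "alpha": ABSORPTION_DB_M, "combined": COMBINED}

STRUCTURAL = ("T", "R", "D")


def skull_material(rho: float = DEFAULT_RHO, c: float = DEFAULT_C,
                   alpha_db_m: float = DEFAULT_ALPHA_DB,
                   frequency: float = 0.9e6,
                   nonlinearity: float = ACRYLIC.nonlinearity) -> Material:
    """Skull-model material from sweep-style parameters (absorption given in
    dB/m at the drive frequency)."""
    return Material.from_db_per_m(rho, c, alpha_db_m, frequency, nonlinearity)


def default_plate(material: Material = ACRYLIC) -> PlateSpec:
    """The reference plate: T = 8 mm, R = 60 mm, D = 10 mm."""
    return PlateSpec(thickness=DEFAULT_T_MM * 1e-3,
                     curvature_radius=DEFAULT_R_MM * 1e-3,
                     standoff=DEFAULT_D_MM * 1e-3, material=material)


# ---------------------------------------------------------------------------
# sweep orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepSpec:
    """One parameter sweep: which parameter, which values, and the base scene
    every value modifies."""

    parameter: str
    values: tuple
    base_scene: SceneConfig
    settings: SolverSettings = SolverSettings()

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise InvalidConfigError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"choose from {PARAMETERS}")
        if len(self.values) == 0:
            raise InvalidConfigError("sweep value list is empty")
        keys = [v if self.parameter != "combined" else v[0]
                for v in self.values]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise InvalidConfigError("sweep values must be strictly increasing")

    @property
    def units(self) -> str:
        return PARAMETER_UNITS[self.parameter]


def paper_sweep_spec(parameter: str, resolution: str = "coarse",
                     surface_pressure: float = 1.0e4,
                     settings: SolverSettings = SolverSettings(),
                     values: Optional[Sequence] = None) -> SweepSpec:
    """Standard sweep over the study ranges.

    The base scene carries the reference plate (acrylic for the structural
    sweeps, the fixed skull-model material for the acoustic ones); each value
    is then run with a time step chosen for its own stability limit (stiff
    high-absorption values need a several-times smaller dt than the rest, so
    a sweep-wide dt would make every run as slow as the stiffest one).
    """
    values = tuple(values if values is not None
                   else DEFAULT_VALUES[parameter])
    material = ACRYLIC if parameter in STRUCTURAL else skull_material()
    base = reference_scene(plate=default_plate(material),
                           resolution=resolution,
                           surface_pressure=surface_pressure)
    return SweepSpec(parameter=parameter, values=values, base_scene=base,
                     settings=settings)


def scene_for_value(spec: SweepSpec, value) -> SceneConfig:
    """The base scene with one swept value applied and the time step set to
    that value's own stability limit."""
    base = spec.base_scene
    plate = base.plate
    if plate is None:
        raise InvalidConfigError("sweep base scene has no plate")
    tr = base.transducer
    f = tr.frequency
    p = spec.parameter
    if p == "T":
        plate = replace(plate, thickness=value * 1e-3)
    elif p == "R":
        plate = replace(plate, curvature_radius=value * 1e-3)
    elif p == "D":
        plate = replace(plate, standoff=value * 1e-3)
    elif p == "rho":
        plate = replace(plate, material=skull_material(rho=value, frequency=f))
    elif p == "c":
        plate = replace(plate, material=skull_material(c=value, frequency=f))
    elif p == "alpha":
        plate = replace(plate, material=skull_material(alpha_db_m=value,
                                                       frequency=f))
    else:
        rho, c, alpha = value
        plate = replace(plate, material=skull_material(rho, c, alpha,
                                                       frequency=f))
    c_max = max(base.background.sound_speed, plate.material.sound_speed)
    delta_max = max(base.background.effective_diffusivity(f),
                    plate.material.effective_diffusivity(f))
    grid = base.grid
    dt = choose_time_step(grid.dx, grid.mode, c_max, delta_max, f)
    new_grid = build_grid(grid.mode, grid.dx, dt, grid.extents, c_max=c_max)
    return base.with_(plate=plate, grid=new_grid)


@dataclass
class SweepResult:
    """Per-value focal metrics of one sweep (ordered as the input values)."""

    parameter: str
    units: str
    values: tuple
    metrics: list            # FocalMetrics or None where a value failed
    failures: dict = field(default_factory=dict)   # value index -> message
    provenance: dict = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        if self.parameter == "combined":
            return np.arange(len(self.values), dtype=float)
        return np.asarray(self.values, dtype=float)

    @property
    def peaks_kpa(self) -> np.ndarray:
        return np.array([m.peak_kpa if m is not None else np.nan
                         for m in self.metrics])

    def percent_drop(self, i_from: int = 0, i_to: int = -1) -> float:
        """100 (1 - p[i_to]/p[i_from]): total drop across the sweep by
        default, or up to an intermediate value."""
        p = self.peaks_kpa
        return 100.0 * (1.0 - p[i_to] / p[i_from])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        p0 = next((m.peak_pa for m in self.metrics if m is not None), None)
        for v, m in zip(self.values, self.metrics):
            row = {f"{self.parameter}_{self.units.replace('/', '_')}": v}
            if m is None:
                row.update(peak_kpa=np.nan)
            else:
                row.update(peak_kpa=m.peak_kpa, z_focus_mm=m.z_mm,
                           minus6db_mm=m.minus6db_mm,
                           drop_pct=100.0 * (1.0 - m.peak_pa / p0),
                           drop_db=20.0 * math.log10(p0 / m.peak_pa))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run one solver pass per value and collect focal metrics.

    Per-value failures are recorded and the sweep continues; the result is
    deterministic and independent of the order the values are listed in.
    """
    metrics, failures = [], {}
    for i, v in enumerate(spec.values):
        try:
            scene = scene_for_value(spec, v)
            fld = run_to_steady(scene, spec.settings)
            metrics.append(summarize(fld, z_min=focal_search_floor(scene)))
        except Exception as exc:  # noqa: BLE001 - recorded, sweep continues
            metrics.append(None)
            failures[i] = f"{type(exc).__name__}: {exc}"
    return SweepResult(parameter=spec.parameter, units=spec.units,
                       values=spec.values, metrics=metrics, failures=failures,
                       provenance={"base_scene": spec.base_scene.hash(),
                                   "n_values": len(spec.values)})


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted trend of focal pressure versus a swept parameter."""

    kind: str                 # "linear" | "power"
    params: dict
    r_squared: float
    residuals: np.ndarray

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.kind == "linear":
            return p["slope"] * x + p["intercept"]
        return p["a"] * x ** p["b"] + p["c"]

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params),
                "r_squared": self.r_squared}


def _r_squared(y, yhat) -> float:
    y = np.asarray(y, float)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def linear_fit(x, y) -> FitResult:
    """Ordinary least squares y = m x + b."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise DegenerateDataError("linear fit needs >= 3 points")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all x values equal")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    return FitResult(kind="linear",
                     params={"slope": float(slope),
                             "intercept": float(intercept)},
                     r_squared=_r_squared(y, yhat), residuals=y - yhat)


def power_fit(x, y) -> FitResult:
    """Nonlinear least squares y = a x^b + c.

    Initialization: c0 slightly below min(y), b0 from the log-log slope of
    (y - c0), a0 matching the first point; b is bounded to [-2, 2] (the
    physically sensible range for these gently flattening decay curves).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise DegenerateDataError("power fit needs >= 4 points")
    if np.any(x <= 0):
        raise DegenerateDataError("power fit needs x > 0")

    c0 = y.min() - 0.05 * max(np.ptp(y), abs(y.min()), 1e-12)
    w = y - c0
    b0 = np.polyfit(np.log(x), np.log(np.maximum(w, 1e-12)), 1)[0]
    b0 = float(np.clip(b0, -1.9, 1.9))
    a0 = w[0] / x[0] ** b0

    def model(xx, a, b, c):
        return a * xx ** b + c

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=[a0, b0, c0],
            bounds=([-np.inf, -2.0, -np.inf], [np.inf, 2.0, np.inf]),
            maxfev=20000)
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"power-law fit did not converge (start a={a0:.3g}, b={b0:.3g}, "
            f"c={c0:.3g}): {exc}") from exc
    yhat = model(x, *popt)
    return FitResult(kind="power",
                     params={"a": float(popt[0]), "b": float(popt[1]),
                             "c": float(popt[2])},
                     r_squared=_r_squared(y, yhat), residuals=y - yhat)


def unit_attenuation(fit: FitResult, step: float = 1.0) -> float:
    """dB of focal-pressure loss per unit parameter step implied by a linear
    fit, referenced to the fitted intercept:

        20 log10( b / (b - |m| step) )

    with b the intercept (the fit's "initial" pressure) and m the slope.
    This intercept-referenced convention is the documented definition used
    throughout; see docs/methods.md for its rationale and limitations.
    """
    if fit.kind != "linear":
        raise DegenerateDataError("unit attenuation is defined on linear fits")
    m = abs(fit.params["slope"])
    b = fit.params["intercept"]
    denom = b - m * step
    if denom <= 0 or b <= 0:
        raise DegenerateDataError(
            "intercept-referenced attenuation undefined: b - |m| step <= 0")
    return 20.0 * math.log10(b / denom)


def pearson_fit_agreement(fit_a: FitResult, fit_b: FitResult, x) -> float:
    """Pearson correlation of two fitted curves evaluated at the sweep
    values (the agreement statistic between methods)."""
    x = np.asarray(x, float)
    ya, yb = fit_a.predict(x), fit_b.predict(x)
    for y in (ya, yb):
        if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
            raise UndefinedCorrelationError(
                "correlation undefined for a constant fitted curve")
    return float(stats.pearsonr(ya, yb)[0])


# ---------------------------------------------------------------------------
# published comparison curves (experiment / FEM reference arms)
# ---------------------------------------------------------------------------

#: Linear-fit formulas reported by the reference experimental and FEM
#: (Helmholtz) arms of the same study, kept solely for comparison output;
#: tuples are (slope, intercept) of focal pressure [kPa] vs parameter.
REFERENCE_FITS = {
    "T": {"experiment": (-15.09, 360.7), "fem": (-14.26, 346.0)},
    "R": {"experiment": (-0.868, 286.9), "fem": (-0.315, 258.9)},
    "D": {"experiment": (-2.695, 268.0), "fem": (-0.639, 248.2)},
    "rho": {"fem": (-0.022, 87.39)},
    "c": {"fem": (-0.011, 69.99)},
}


def reference_fit(parameter: str, arm: str) -> FitResult:
    """FitResult wrapping one published comparison formula."""
    slope, intercept = REFERENCE_FITS[parameter][arm]
    return FitResult(kind="linear",
                     params={"slope": slope, "intercept": intercept},
                     r_squared=float("nan"), residuals=np.array([]))
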