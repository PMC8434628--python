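"""Westervelt FDTD time stepping and steady-state amplitude extraction.

The solver advances the nonlinear Westervelt equation with an explicit
second-order scheme (see :mod:`tfusim._kernels` for the discretization),
first-order Mur absorbing boundaries on every outer face, a hard monochromatic
pressure source on the rasterized transducer surface, and extracts the
per-cell steady-state pressure amplitude from the final drive cycles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .exceptions import DivergenceError, InvalidConfigError
from .scene import (MediumMaps, SceneConfig, SimulationGrid, SourceDrive,
                    STENCIL_DIMS, build_medium_maps, build_source, cfl_dt_max,
                    loss_dt_max, scheme_dt_max)


@dataclass(frozen=True)
class SolverSettings:
    """Protocol parameters of a steady-state run.

    The run lasts ``traversal_factor`` domain traversals (diagonal length over
    the slowest sound speed, so every multipath has arrived) plus
    ``settle_cycles`` drive periods; the amplitude is extracted over the final
    ``window_cycles`` periods.  ``linear`` switches the beta (nonlinearity)
    term off; ``lossless`` switches the delta (absorption) term off.
    ``amplitude_method`` is ``"max"`` (max |p| in the window; includes
    harmonics) or ``"quadrature"`` (sine/cosine projection at the drive
    frequency; exact for a pure tone).

    ``source_kind`` selects how the rasterized cap drives the field:
    ``"transparent"`` (default) adds a calibrated sheet forcing that radiates
    the prescribed surface amplitude while letting waves reflected back from
    the plate pass through; ``"hard"`` overwrites the cap pressure, which
    also makes the cap a perfect mirror for returning waves.  The drive is
    ramped on smoothly over ``ramp_cycles`` periods.
    """

    settle_cycles: int = 15
    window_cycles: int = 2
    traversal_factor: float = 2.0
    steady_tol: float = 0.05
    linear: bool = False
    lossless: bool = False
    amplitude_method: str = "max"
    source_kind: str = "transparent"
    ramp_cycles: int = 3
    blowup_factor: float = 1.0e4
    check_every: int = 200

    def __post_init__(self) -> None:
        if self.settle_cycles < 1 or self.window_cycles < 1:
            raise InvalidConfigError("cycle counts must be >= 1")
        if self.amplitude_method not in ("max", "quadrature"):
            raise InvalidConfigError("amplitude_method must be max|quadrature")
        if self.source_kind not in ("transparent", "hard"):
            raise InvalidConfigError("source_kind must be transparent|hard")


@dataclass
class StabilityReport:
    """Stability assessment of a configured dt.

    ``dt_max_cfl`` is the classical bound dx/(c_max sqrt(d));
    ``dt_max_stable`` is the implemented scheme's actual bound (8th-order
    stencil eigenvalue plus the explicit-loss term), which governs ``passes``.
    """

    dt: float
    dt_max_cfl: float
    dt_max_loss: float
    dt_max_stable: float
    passes: bool

    @property
    def margin(self) -> float:
        """dt as a fraction of the scheme bound (< 1 is stable)."""
        return self.dt / self.dt_max_stable


def check_stability(grid: SimulationGrid, media: MediumMaps) -> StabilityReport:
    """Report the CFL and explicit-loss time-step bounds for the scene's
    media.  Reporting only; callers decide enforcement."""
    dt_cfl = cfl_dt_max(grid.dx, media.c_max, grid.mode)
    dt_loss = loss_dt_max(grid.dx, media.delta_max, grid.mode)
    dt_stable = scheme_dt_max(grid.dx, media.c_max, media.delta_max,
                              grid.mode)
    return StabilityReport(dt=grid.dt, dt_max_cfl=dt_cfl, dt_max_loss=dt_loss,
                           dt_max_stable=dt_stable,
                           passes=grid.dt <= dt_stable)


@dataclass
class SolverState:
    """Pressure at the three levels needed by the update (p0 = current), the
    stored heterogeneous-Laplacian values, and the elapsed step count."""

    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    lap: np.ndarray
    lap_prev: np.ndarray
    steps: int = 0

    @classmethod
    def zeros(cls, grid: SimulationGrid) -> "SolverState":
        shape = grid.shape
        return cls(*(np.zeros(shape) for _ in range(5)))


def _coefficients(media: MediumMaps, dt: float, settings: SolverSettings):
    W = media.c**2 * dt**2
    Ldt = np.zeros_like(W) if settings.lossless else media.delta_eff * dt
    NLc = (np.zeros_like(W) if settings.linear
           else media.beta / (media.rho * media.c**2))
    return W, Ldt, NLc, 1.0 / media.rho


def _source_coef(source: SourceDrive, media: MediumMaps,
                 grid: SimulationGrid) -> np.ndarray:
    """Per-cell forcing of the transparent sheet source.

    A monochromatic sheet source S(t) delta_n in the wave equation radiates a
    plane wave of amplitude S0/(2 c omega) to each side; the discrete sheet
    occupying one cell per surface footprint therefore needs
    S0 = 2 c omega p0 sec(theta) / dx to emit surface amplitude p0, entering
    the explicit update as dt^2 S0 sin(omega t)."""
    c_local = media.c[source.indices]
    return (2.0 * c_local * source.omega * source.amplitude * grid.dt**2
            / grid.dx) * source.weights


def _ramp(t: float, omega: float, ramp_cycles: int) -> float:
    """Smooth cosine turn-on envelope over the first ``ramp_cycles`` periods."""
    t_ramp = ramp_cycles * 2.0 * math.pi / omega
    if t >= t_ramp:
        return 1.0
    return 0.5 * (1.0 - math.cos(math.pi * t / t_ramp))


def step(state: SolverState, media: MediumMaps, source: Optional[SourceDrive],
         grid: SimulationGrid, settings: SolverSettings = SolverSettings(),
         _coef=None) -> SolverState:
    """Advance one time level in place and return the state.

    Interior cells get the explicit Westervelt update, boundary cells the Mur
    condition, and source cells are overwritten with the drive value for the
    new time level (hard source).
    """
    dt = grid.dt
    if _coef is None:
        _coef = _coefficients(media, dt, settings)
    W, Ldt, NLc, inv_rho = _coef
    p_next = np.zeros_like(state.p0)
    _kernels.STEP[grid.mode](p_next, state.p0, state.p1, state.p2,
                             state.lap, state.lap_prev, media.rho, inv_rho,
                             W, Ldt, NLc, 1.0 / grid.dx**2)
    _kernels.MUR[grid.mode](p_next, state.p0, media.c, dt, grid.dx)
    state.steps += 1
    if source is not None:
        t = state.steps * dt
        env = _ramp(t, source.omega, settings.ramp_cycles)
        if settings.source_kind == "hard":
            p_next[source.indices] = env * source.value(t)
        else:
            p_next[source.indices] += (_source_coef(source, media, grid) * env
                                       * np.sin(source.omega * t
                                                - source.phases))
    state.p2, state.p1, state.p0 = state.p1, state.p0, p_next
    state.lap, state.lap_prev = state.lap_prev, state.lap
    return state


@dataclass
class AmplitudeField:
    """Steady-state pressure amplitude on the grid (the solver's product)."""

    data: np.ndarray
    grid: SimulationGrid
    meta: dict = field(default_factory=dict)
    probes: dict = field(default_factory=dict)

    def on_axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(z [m], amplitude [Pa]) along the beam axis (nearest cell row)."""
        if self.grid.mode == "1d":
            prof = self.data
        elif self.grid.mode == "axisymmetric":
            prof = self.data[:, 0]
        else:
            _, ny, nx = self.data.shape
            prof = self.data[:, ny // 2, nx // 2]
        return self.grid.z, prof

    def scaled(self, factor: float) -> "AmplitudeField":
        return AmplitudeField(self.data * factor, self.grid, dict(self.meta))


def _nearest_index(grid: SimulationGrid, coords: Sequence[float]) -> tuple:
    if grid.mode == "1d":
        axes = [grid.z]
    elif grid.mode == "axisymmetric":
        axes = [grid.z, grid.r]
    else:
        axes = [grid.z, grid.y, grid.x]
    return tuple(int(np.argmin(np.abs(axis - coord)))
                 for coord, axis in zip(coords, axes))


def run_to_steady(scene: SceneConfig,
                  settings: SolverSettings = SolverSettings(),
                  probes: Optional[Sequence[Sequence[float]]] = None,
                  duration: Optional[float] = None) -> AmplitudeField:
    """Run a scene to periodic steady state and extract the amplitude field.

    Deterministic for a fixed scene and settings: there is no randomness
    anywhere in the solve path.  Raises :class:`InvalidConfigError` when the
    configured dt is unstable for the scene's media and
    :class:`DivergenceError` when the pressure blows up.
    """
    grid = scene.grid
    media = build_medium_maps(scene)
    source = build_source(scene.transducer, grid,
                          sound_speed=scene.background.sound_speed)
    report = check_stability(grid, media)
    if not report.passes:
        raise InvalidConfigError(
            f"dt = {grid.dt:.3e} s unstable: CFL bound {report.dt_max_cfl:.3e},"
            f" loss bound {report.dt_max_loss:.3e}")

    f = scene.transducer.frequency
    period = 1.0 / f
    dt = grid.dt
    if duration is None:
        diag = math.sqrt(sum(e**2 for e in grid.extents))
        duration = (settings.traversal_factor * diag / media.c_min
                    + settings.settle_cycles * period)
    n_steps = int(math.ceil(duration / dt))
    w_steps = max(1, int(math.ceil(settings.window_cycles * period / dt)))
    n_steps = max(n_steps, 2 * w_steps + 1)
    last_start = n_steps - w_steps
    prev_start = n_steps - 2 * w_steps

    state = SolverState.zeros(grid)
    p_next = np.zeros(grid.shape)
    coef = _coefficients(media, dt, settings)
    W, Ldt, NLc, inv_rho = coef
    inv_dx2 = 1.0 / grid.dx**2
    step_k = _kernels.STEP[grid.mode]
    mur_k = _kernels.MUR[grid.mode]

    quad = settings.amplitude_method == "quadrature"
    amp_last = np.zeros(grid.shape)
    amp_prev = np.zeros(grid.shape)
    if quad:
        acc = {k: np.zeros(grid.shape) for k in ("Il", "Ql", "Ip", "Qp")}
        cnt = {"l": 0, "p": 0}

    probe_idx = ([_nearest_index(grid, c) for c in probes] if probes else [])
    probe_data = np.zeros((n_steps, len(probe_idx))) if probe_idx else None

    blowup = settings.blowup_factor * max(abs(source.amplitude), 1.0)
    omega = source.omega
    hard = settings.source_kind == "hard"
    src_coef = None if hard else _source_coef(source, media, grid)
    for n in range(n_steps):
        t_next = (n + 1) * dt
        step_k(p_next, state.p0, state.p1, state.p2, state.lap,
               state.lap_prev, media.rho, inv_rho, W, Ldt, NLc, inv_dx2)
        mur_k(p_next, state.p0, media.c, dt, grid.dx)
        env = _ramp(t_next, omega, settings.ramp_cycles)
        if hard:
            p_next[source.indices] = env * source.value(t_next)
        else:
            p_next[source.indices] += (src_coef * env
                                       * np.sin(omega * t_next
                                                - source.phases))

        if probe_data is not None:
            for m, pi in enumerate(probe_idx):
                probe_data[n, m] = p_next[pi]

        if n >= last_start:
            if quad:
                acc["Il"] += p_next * math.sin(omega * t_next)
                acc["Ql"] += p_next * math.cos(omega * t_next)
                cnt["l"] += 1
            else:
                np.maximum(amp_last, np.abs(p_next), out=amp_last)
        elif n >= prev_start:
            if quad:
                acc["Ip"] += p_next * math.sin(omega * t_next)
                acc["Qp"] += p_next * math.cos(omega * t_next)
                cnt["p"] += 1
            else:
                np.maximum(amp_prev, np.abs(p_next), out=amp_prev)

        if (n + 1) % settings.check_every == 0:
            peak = np.abs(p_next).max()
            if not np.isfinite(peak) or peak > blowup:
                raise DivergenceError(
                    f"pressure blew up at step {n + 1}: max |p| = {peak:.3e}")

        state.p2, state.p1, state.p0, p_next = (state.p1, state.p0, p_next,
                                                state.p2)
        state.lap, state.lap_prev = state.lap_prev, state.lap
        state.steps = n + 1

    if quad:
        amp_last = 2.0 * np.hypot(acc["Il"], acc["Ql"]) / cnt["l"]
        amp_prev = 2.0 * np.hypot(acc["Ip"], acc["Qp"]) / cnt["p"]

    ref = amp_last.max()
    residual = (abs(amp_last.max() - amp_prev.max()) / ref if ref > 0 else 0.0)
    if residual > settings.steady_tol:
        warnings.warn(
            f"steady-state criterion unmet: relative amplitude change "
            f"{residual:.3f} > {settings.steady_tol}", RuntimeWarning,
            stacklevel=2)

    fld = AmplitudeField(
        data=amp_last, grid=grid,
        meta={
            "scene_hash": scene.hash(),
            "n_steps": n_steps,
            "dt_s": dt,
            "duration_s": n_steps * dt,
            "residual": residual,
            "stability_margin": report.margin,
            "settings": {
                "settle_cycles": settings.settle_cycles,
                "window_cycles": settings.window_cycles,
                "linear": settings.linear,
                "lossless": settings.lossless,
                "amplitude_method": settings.amplitude_method,
                "source_kind": settings.source_kind,
            },
        })
    if probe_data is not None:
        fld.probes = {"coords": [tuple(c) for c in probes],
                      "indices": probe_idx, "dt_s": dt, "series": probe_data}
    return fld


def linear_settings(**kwargs) -> SolverSettings:
    """Convenience: settings with the nonlinearity switched off."""
    return SolverSettings(linear=True, **kwargs)
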