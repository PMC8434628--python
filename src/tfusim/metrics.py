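"""Focal metrics: peak pressure, focal position, -6 dB axial length, and the
attenuation measures used to compare runs with and without a skull plate.

The -6 dB length is defined on pressure amplitude (the half-amplitude
convention standard in therapeutic ultrasound): the contiguous on-axis extent
around the focus where the amplitude stays at or above half its peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .exceptions import FlatFieldError, OpenRegionError, TfusimError
from .solver import AmplitudeField, SolverSettings, run_to_steady
from .scene import SceneConfig


@dataclass(frozen=True)
class FocalMetrics:
    """Summary of one amplitude field's focal region."""

    peak_pa: float
    z_mm: float
    r_mm: float
    minus6db_mm: float
    drop_pct: Optional[float] = None    # relative to a reference peak
    drop_db: Optional[float] = None

    @property
    def peak_kpa(self) -> float:
        return self.peak_pa / 1e3

    def to_dict(self) -> dict:
        return {
            "peak_pa": self.peak_pa,
            "peak_kpa": self.peak_kpa,
            "focus_z_mm": self.z_mm,
            "focus_r_mm": self.r_mm,
            "minus6db_length_mm": self.minus6db_mm,
            "drop_pct": self.drop_pct,
            "drop_db": self.drop_db,
        }


def _parabolic_refine(coord: np.ndarray, vals: np.ndarray, i: int) -> float:
    """Vertex of the parabola through three samples around index i."""
    if i == 0 or i == len(vals) - 1:
        return float(coord[i])
    denom = vals[i - 1] - 2.0 * vals[i] + vals[i + 1]
    if denom == 0:
        return float(coord[i])
    shift = 0.5 * (vals[i - 1] - vals[i + 1]) / denom
    return float(coord[i] + shift * (coord[1] - coord[0]))


def focal_search_floor(scene: SceneConfig) -> Optional[float]:
    """Lower z bound [m] of the focal-region search for a scene.

    With a strongly absorbing plate the global field maximum sits in the
    standing field *between* transducer and plate; the focal metrics concern
    the transmitted beam, so the search starts just past the plate's on-axis
    exit face.  Returns ``None`` (no restriction) for plate-free scenes.
    """
    if scene.plate is None:
        return None
    rim = 0.0 if scene.grid.mode == "1d" else scene.transducer.rim_z
    return rim + scene.plate.standoff + scene.plate.thickness + 2e-3


def find_focus(field: AmplitudeField,
               z_min: Optional[float] = None) -> tuple[tuple[float, float],
                                                       float]:
    """Locate the focal maximum.

    Returns ``((z_mm, r_mm), peak_pa)``.  The axial position is refined by
    three-point parabolic interpolation along z; exact ties are broken toward
    smaller z, but widely separated exact ties (a flat field) raise
    :class:`FlatFieldError`.  ``z_min`` (m) restricts the search to z >=
    z_min (see :func:`focal_search_floor`).
    """
    data = field.data
    if data.size == 0:
        raise TfusimError("empty amplitude field")
    grid = field.grid
    i0 = 0
    if z_min is not None:
        i0 = int(np.searchsorted(grid.z, z_min))
        if i0 >= data.shape[0]:
            raise TfusimError("focal search window is empty")
    win = data[i0:]
    peak = float(win.max())
    ties = np.argwhere(win == peak)
    if len(ties) > 1 and np.any(ties.max(axis=0) - ties.min(axis=0) > 2):
        raise FlatFieldError("amplitude maximum is not unique")
    idx = tuple(ties[np.argmin(ties[:, 0])])  # smallest z among ties
    idx = (idx[0] + i0,) + tuple(idx[1:])

    if grid.mode == "1d":
        axial = data
        r_mm = 0.0
    elif grid.mode == "axisymmetric":
        axial = data[:, idx[1]]
        r_mm = grid.r[idx[1]] * 1e3
    else:
        axial = data[:, idx[1], idx[2]]
        r_mm = math.hypot(grid.y[idx[1]], grid.x[idx[2]]) * 1e3
    z_mm = _parabolic_refine(grid.z, axial, idx[0]) * 1e3
    return (z_mm, r_mm), peak


def minus6db_length(field: AmplitudeField, focus: Optional[tuple] = None,
                    z_min: Optional[float] = None) -> float:
    """Axial -6 dB (half-amplitude) focal length [mm].

    Measures the contiguous on-axis region around the focal peak where the
    amplitude is >= half the peak, with linear interpolation at the two
    crossings.  Raises :class:`OpenRegionError` if the region touches the
    domain boundary.  ``z_min`` restricts the peak search as in
    :func:`find_focus`.
    """
    z, prof = field.on_axis()
    if focus is None:
        focus = find_focus(field, z_min=z_min)
    i0 = 0 if z_min is None else int(np.searchsorted(z, z_min))
    i_pk = i0 + int(np.argmax(prof[i0:]))
    half = 0.5 * prof[i_pk]
    if half <= 0:
        raise TfusimError("zero amplitude field")

    i_lo = i_pk
    while i_lo > 0 and prof[i_lo - 1] >= half:
        i_lo -= 1
    i_hi = i_pk
    while i_hi < len(prof) - 1 and prof[i_hi + 1] >= half:
        i_hi += 1
    if i_lo == 0 or i_hi == len(prof) - 1:
        raise OpenRegionError("-6 dB region touches the domain boundary")

    dz = z[1] - z[0]
    z_lo = z[i_lo] - dz * (prof[i_lo] - half) / (prof[i_lo] - prof[i_lo - 1])
    z_hi = z[i_hi] + dz * (prof[i_hi] - half) / (prof[i_hi] - prof[i_hi + 1])
    return (z_hi - z_lo) * 1e3


def percent_drop(p_ref: float, p: float) -> float:
    """Percent reduction 100 (1 - p/p_ref) of a pressure relative to a
    reference (e.g. plate run vs pure-water run)."""
    if p_ref <= 0:
        raise TfusimError("reference pressure must be positive")
    return 100.0 * (1.0 - p / p_ref)


def attenuation_db(p_ref: float, p: float) -> float:
    """Amplitude attenuation 20 log10(p_ref / p) [dB]."""
    if p_ref <= 0 or p <= 0:
        raise TfusimError("pressures must be positive")
    return 20.0 * math.log10(p_ref / p)


def summarize(field: AmplitudeField, reference_peak: Optional[float] = None,
              z_min: Optional[float] = None) -> FocalMetrics:
    """Bundle the focal metrics of one field (drops only when a reference
    peak is supplied); ``z_min`` restricts the focal search as in
    :func:`find_focus`."""
    (z_mm, r_mm), peak = find_focus(field, z_min=z_min)
    try:
        m6 = minus6db_length(field, z_min=z_min)
    except OpenRegionError:
        m6 = float("nan")
    drop = db = None
    if reference_peak is not None:
        drop = percent_drop(reference_peak, peak)
        db = attenuation_db(reference_peak, peak)
    return FocalMetrics(peak_pa=peak, z_mm=z_mm, r_mm=r_mm, minus6db_mm=m6,
                        drop_pct=drop, drop_db=db)


def calibrate_source(scene: SceneConfig, target_pa: float,
                     settings: SolverSettings = SolverSettings(),
                     refine_nonlinear: bool = False) -> float:
    """Surface pressure p0 such that the scene's focal peak equals
    ``target_pa``.

    The drive amplitude is unpublished in typical experimental setups; this
    replaces it by scaling a linear run (exact, because the linearized field
    is homogeneous of degree 1 in p0), optionally followed by one fixed-point
    refinement with the nonlinearity on.
    """
    if target_pa < 0:
        raise TfusimError("target pressure must be >= 0")
    if target_pa == 0:
        return 0.0
    lin = replace(settings, linear=True)
    fld = run_to_steady(scene, lin)
    _, peak = find_focus(fld)
    p0 = scene.transducer.surface_pressure * target_pa / peak
    if refine_nonlinear:
        scene2 = scene.with_(transducer=replace(scene.transducer,
                                                surface_pressure=p0))
        fld2 = run_to_steady(scene2, settings)
        _, peak2 = find_focus(fld2)
        p0 *= target_pa / peak2
    return p0
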