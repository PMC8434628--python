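"""Closed-form acoustics used as independent ground truth in tests.

These expressions are classical results (focused-radiator on-axis field,
plane-wave absorption, normal-incidence interface transmission, Fubini
harmonic series) evaluated directly from material and geometry scalars; they
never call the FDTD solver.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, special

from .exceptions import TfusimError
from .scene import Material, TransducerSpec


def _onaxis_complex(transducer: TransducerSpec, medium: Material, z):
    """Complex on-axis pressure of the uniformly driven spherical-cap bowl.

    For a cap of curvature radius R (the focal length) the on-axis Rayleigh
    integral has an exact antiderivative, giving

        p(z) = -p0 * R/(R - z) * (exp(i k r_out) - exp(i k r_in)),

    where r_out/r_in are the distances from the axial point to the outer and
    inner (hole) edges of the cap; for a full bowl r_in = z (the apex).  At
    the geometric center z = R the finite limit p = -i p0 k (h_out - h_in)
    e^{ikR} is used, with h the cap depths of the two edges.
    """
    z = np.asarray(z, dtype=float)
    R = transducer.focal_length
    k = transducer.omega / medium.sound_speed
    p0 = transducer.surface_pressure
    a_out = transducer.aperture_diameter / 2
    a_in = transducer.hole_diameter / 2
    if a_out == a_in:  # empty aperture
        return np.zeros_like(z, dtype=complex)

    def edge_dist(a):
        ze = R - math.sqrt(R**2 - a**2)
        return np.sqrt(a**2 + (z - ze) ** 2)

    r_out = edge_dist(a_out)
    r_in = edge_dist(a_in) if a_in > 0 else z
    h_out = R - math.sqrt(R**2 - a_out**2)
    h_in = R - math.sqrt(R**2 - a_in**2) if a_in > 0 else 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        p = -p0 * R / (R - z) * (np.exp(1j * k * r_out)
                                 - np.exp(1j * k * r_in))
    # finite limit at the geometric center
    focal = -1j * p0 * k * (h_out - h_in) * np.exp(1j * k * R)
    near = np.abs(R - z) < 1e-9 * R
    if np.any(near):
        p = np.where(near, focal, p)
    return p


def oneil_onaxis(transducer: TransducerSpec, medium: Material, z) -> np.ndarray:
    """On-axis pressure amplitude [Pa] of the focused bowl in a linear,
    lossless, homogeneous medium (annular aperture supported)."""
    return np.abs(_onaxis_complex(transducer, medium, np.asarray(z, float)))


def rayleigh_onaxis(transducer: TransducerSpec, medium: Material,
                    z: float) -> float:
    """Same on-axis amplitude by direct numerical quadrature of the surface
    integral over the cap (independent cross-check of the closed form)."""
    R = transducer.focal_length
    k = transducer.omega / medium.sound_speed
    p0 = transducer.surface_pressure
    a_out = transducer.aperture_diameter / 2
    a_in = transducer.hole_diameter / 2
    if a_out == a_in:
        return 0.0
    psi_in = math.asin(a_in / R) if a_in > 0 else 0.0
    psi_out = math.asin(a_out / R)

    def integrand(psi, trig):
        zs = R * (1.0 - math.cos(psi))
        rs = R * math.sin(psi)
        d = math.hypot(rs, z - zs)
        return trig(k * d) / d * math.sin(psi)

    re, _ = integrate.quad(integrand, psi_in, psi_out, args=(math.cos,),
                           limit=400)
    im, _ = integrate.quad(integrand, psi_in, psi_out, args=(math.sin,),
                           limit=400)
    # p = -i k p0 R^2 * integral(e^{ikd}/d sin psi dpsi)
    return abs(-1j * k * p0 * R**2 * (re + 1j * im))


def plane_wave_decay(alpha_np_per_m: float, distance: float) -> float:
    """Amplitude ratio e^{-alpha x} of a plane wave after ``distance`` [m]."""
    if alpha_np_per_m < 0 or distance < 0:
        raise TfusimError("alpha and distance must be non-negative")
    return math.exp(-alpha_np_per_m * distance)


def interface_transmission(m1: Material, m2: Material) -> float:
    """Normal-incidence pressure transmission coefficient
    T = 2 Z2 / (Z1 + Z2), Z = rho c."""
    z1, z2 = m1.impedance, m2.impedance
    return 2.0 * z2 / (z1 + z2)


def fubini_harmonics(sigma: float, n: int) -> float:
    """Normalized n-th harmonic amplitude B_n = 2 J_n(n sigma) / (n sigma) of
    an initially sinusoidal plane wave in the pre-shock region (0 < sigma < 1,
    sigma being the distance in units of the shock-formation length)."""
    if not 0 < sigma < 1:
        raise TfusimError("Fubini solution requires 0 < sigma < 1")
    if n < 1:
        raise TfusimError("harmonic index must be >= 1")
    x = n * sigma
    return 2.0 * special.jv(n, x) / x


def shock_parameter(p0: float, medium: Material, frequency: float,
                    distance: float) -> float:
    """sigma = beta eps k x with eps = p0/(rho c^2): normalized nonlinear
    propagation distance of a plane wave of source amplitude ``p0``."""
    eps = p0 / (medium.density * medium.sound_speed**2)
    k = 2.0 * math.pi * frequency / medium.sound_speed
    return medium.nonlinearity * eps * k * distance
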