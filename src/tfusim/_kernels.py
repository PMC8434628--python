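"""Numba-compiled finite-difference update kernels.

All kernels advance the Westervelt equation

    L(p) - c^-2 p_tt + (delta/c^2) d/dt L(p) + beta/(rho c^4) (p^2)_tt = 0,
    L(p) = rho div(rho^-1 grad p)

one explicit step.  The update for p at level n+1 is fully explicit:

    p[n+1] = 2 p[n] - p[n-1] + c^2 dt^2 L(p[n])
             + delta dt (L(p[n]) - L(p[n-1]))
             + beta/(rho c^2) (p[n]^2 - 2 p[n-1]^2 + p[n-2]^2)

The thermoviscous loss enters in its d/dt grad^2 form (equivalent to the
third time derivative to the order the equation is valid) so the scheme
stays explicit and stable up to skull-like absorption values; the quadratic
nonlinearity uses a backward second difference of p^2 over the three stored
pressure levels.

Spatial discretization
----------------------
The Laplacian uses 8th-order centered coefficients per axis — essential at
the coarse lambda/4 operating resolution, where a 2nd-order stencil would be
~10% slow on axial propagation and shift the focus by many millimetres.  The
stencil radius is clamped (8th -> 2nd order) approaching domain faces; in
axisymmetric mode the radial stencil is folded across the r = 0 axis by even
symmetry, so full order is retained on the beam axis and the axis needs no
special regularization (cell centers sit at (j + 1/2) dx, never at r = 0).

Density heterogeneity is handled by adding the difference between the
2nd-order conservative flux form of rho div(rho^-1 grad p) and the plain
2nd-order Laplacian: the correction is exactly zero wherever rho is uniform
and reproduces impedance-correct interface transmission where it jumps.

Boundary faces use the first-order Mur one-way condition with the local
sound speed.

Coefficient arrays expected by the step kernels:
  W   = c^2 dt^2            (wave term)
  Ldt = delta * dt          (loss term; zeros disable it)
  NLc = beta / (rho c^2)    (nonlinearity; zeros disable it)
"""

import numpy as np
from numba import njit

# centered second-derivative coefficients by half-width (order 2, 4, 6, 8):
# center value and offset weights for (p[i+m] + p[i-m])
D2_CENTER = np.array([-2.0, -5.0 / 2.0, -49.0 / 18.0, -205.0 / 72.0])
D2_OFF = np.array([
    [1.0, 0.0, 0.0, 0.0],
    [4.0 / 3.0, -1.0 / 12.0, 0.0, 0.0],
    [3.0 / 2.0, -3.0 / 20.0, 1.0 / 90.0, 0.0],
    [8.0 / 5.0, -1.0 / 5.0, 8.0 / 315.0, -1.0 / 560.0],
])
# centered first-derivative weights for (p[i+m] - p[i-m])
D1_OFF = np.array([
    [0.5, 0.0, 0.0, 0.0],
    [2.0 / 3.0, -1.0 / 12.0, 0.0, 0.0],
    [3.0 / 4.0, -3.0 / 20.0, 1.0 / 60.0, 0.0],
    [4.0 / 5.0, -1.0 / 5.0, 4.0 / 105.0, -1.0 / 280.0],
])

#: largest eigenvalue of the 8th-order 1D stencil, |symbol| at k dx = pi,
#: in units of 1/dx^2 (the classical 3-point value is 4).  Governs the CFL
#: and explicit-loss stability factors relative to the textbook bounds.
K2_MAX = 6.5015873015873


@njit(cache=True)
def step_1d(p_next, p0, p1, p2, lap, lap_prev, rho, inv_rho, W, Ldt, NLc,
            inv_dx2):
    n = p0.shape[0]
    for i in range(1, n - 1):
        rad = min(4, min(i, n - 1 - i))
        o = rad - 1
        d2 = D2_CENTER[o] * p0[i]
        for m in range(1, rad + 1):
            d2 += D2_OFF[o, m - 1] * (p0[i + m] + p0[i - m])
        # conservative-flux minus plain form: density correction
        fp = 0.5 * (inv_rho[i] + inv_rho[i + 1])
        fm = 0.5 * (inv_rho[i] + inv_rho[i - 1])
        flux = rho[i] * (fp * (p0[i + 1] - p0[i]) - fm * (p0[i] - p0[i - 1]))
        plain = p0[i + 1] - 2.0 * p0[i] + p0[i - 1]
        L = (d2 + flux - plain) * inv_dx2
        lap[i] = L
        nl = NLc[i] * (p0[i] * p0[i] - 2.0 * p1[i] * p1[i] + p2[i] * p2[i])
        p_next[i] = (2.0 * p0[i] - p1[i] + W[i] * L
                     + Ldt[i] * (L - lap_prev[i]) + nl)


@njit(cache=True)
def mur_1d(p_next, p0, c, dt, dx):
    n = p0.shape[0]
    k0 = (c[0] * dt - dx) / (c[0] * dt + dx)
    p_next[0] = p0[1] + k0 * (p_next[1] - p0[0])
    k1 = (c[n - 1] * dt - dx) / (c[n - 1] * dt + dx)
    p_next[n - 1] = p0[n - 2] + k1 * (p_next[n - 2] - p0[n - 1])


@njit(cache=True)
def step_axisymmetric(p_next, p0, p1, p2, lap, lap_prev, rho, inv_rho, W, Ldt,
                      NLc, inv_dx2):
    nz, nr = p0.shape
    for i in range(1, nz - 1):
        radz = min(4, min(i, nz - 1 - i))
        oz = radz - 1
        for j in range(nr - 1):
            # axial second derivative (clamped high order)
            d2z = D2_CENTER[oz] * p0[i, j]
            for m in range(1, radz + 1):
                d2z += D2_OFF[oz, m - 1] * (p0[i + m, j] + p0[i - m, j])
            # radial part folded across the axis: p(-r) = p(r), so the cell
            # at radius -(q + 1/2) dx is cell q
            radr = min(4, nr - 1 - j)
            orr = radr - 1
            d2r = D2_CENTER[orr] * p0[i, j]
            d1r = 0.0
            for m in range(1, radr + 1):
                jm = j - m
                if jm < 0:
                    jm = -jm - 1
                d2r += D2_OFF[orr, m - 1] * (p0[i, j + m] + p0[i, jm])
                d1r += D1_OFF[orr, m - 1] * (p0[i, j + m] - p0[i, jm])
            rr = 1.0 / (j + 0.5)
            ho = d2z + d2r + d1r * rr

            # 2nd-order conservative-minus-plain density correction
            # (exactly zero wherever rho is uniform)
            fp = 0.5 * (inv_rho[i, j] + inv_rho[i, j + 1])
            if j > 0:
                fm = 0.5 * (inv_rho[i, j] + inv_rho[i, j - 1])
                flux_r = ((j + 1.0) * fp * (p0[i, j + 1] - p0[i, j])
                          - j * fm * (p0[i, j] - p0[i, j - 1])) * rr
                plain_r = (p0[i, j + 1] - 2.0 * p0[i, j] + p0[i, j - 1]
                           + (p0[i, j + 1] - p0[i, j - 1]) * 0.5 * rr)
            else:
                flux_r = fp * (p0[i, 1] - p0[i, 0]) * 2.0
                plain_r = 2.0 * (p0[i, 1] - p0[i, 0])
            gp = 0.5 * (inv_rho[i, j] + inv_rho[i + 1, j])
            gm = 0.5 * (inv_rho[i, j] + inv_rho[i - 1, j])
            flux_z = (gp * (p0[i + 1, j] - p0[i, j])
                      - gm * (p0[i, j] - p0[i - 1, j]))
            plain_z = p0[i + 1, j] - 2.0 * p0[i, j] + p0[i - 1, j]
            corr = rho[i, j] * (flux_r + flux_z) - (plain_r + plain_z)

            L = (ho + corr) * inv_dx2
            lap[i, j] = L
            nl = NLc[i, j] * (p0[i, j] * p0[i, j]
                              - 2.0 * p1[i, j] * p1[i, j]
                              + p2[i, j] * p2[i, j])
            p_next[i, j] = (2.0 * p0[i, j] - p1[i, j] + W[i, j] * L
                            + Ldt[i, j] * (L - lap_prev[i, j]) + nl)


@njit(cache=True)
def mur_axisymmetric(p_next, p0, c, dt, dx):
    nz, nr = p0.shape
    for j in range(nr):
        k = (c[0, j] * dt - dx) / (c[0, j] * dt + dx)
        p_next[0, j] = p0[1, j] + k * (p_next[1, j] - p0[0, j])
        k = (c[nz - 1, j] * dt - dx) / (c[nz - 1, j] * dt + dx)
        p_next[nz - 1, j] = p0[nz - 2, j] + k * (p_next[nz - 2, j]
                                                 - p0[nz - 1, j])
    for i in range(nz):
        k = (c[i, nr - 1] * dt - dx) / (c[i, nr - 1] * dt + dx)
        p_next[i, nr - 1] = p0[i, nr - 2] + k * (p_next[i, nr - 2]
                                                 - p0[i, nr - 1])


@njit(cache=True)
def step_3d(p_next, p0, p1, p2, lap, lap_prev, rho, inv_rho, W, Ldt, NLc,
            inv_dx2):
    nz, ny, nx = p0.shape
    for i in range(1, nz - 1):
        radz = min(4, min(i, nz - 1 - i))
        oz = radz - 1
        for j in range(1, ny - 1):
            rady = min(4, min(j, ny - 1 - j))
            oy = rady - 1
            for k in range(1, nx - 1):
                radx = min(4, min(k, nx - 1 - k))
                ox = radx - 1
                ho = (D2_CENTER[oz] + D2_CENTER[oy]
                      + D2_CENTER[ox]) * p0[i, j, k]
                for m in range(1, radz + 1):
                    ho += D2_OFF[oz, m - 1] * (p0[i + m, j, k]
                                               + p0[i - m, j, k])
                for m in range(1, rady + 1):
                    ho += D2_OFF[oy, m - 1] * (p0[i, j + m, k]
                                               + p0[i, j - m, k])
                for m in range(1, radx + 1):
                    ho += D2_OFF[ox, m - 1] * (p0[i, j, k + m]
                                               + p0[i, j, k - m])

                azp = 0.5 * (inv_rho[i, j, k] + inv_rho[i + 1, j, k])
                azm = 0.5 * (inv_rho[i, j, k] + inv_rho[i - 1, j, k])
                ayp = 0.5 * (inv_rho[i, j, k] + inv_rho[i, j + 1, k])
                aym = 0.5 * (inv_rho[i, j, k] + inv_rho[i, j - 1, k])
                axp = 0.5 * (inv_rho[i, j, k] + inv_rho[i, j, k + 1])
                axm = 0.5 * (inv_rho[i, j, k] + inv_rho[i, j, k - 1])
                flux = rho[i, j, k] * (
                    azp * (p0[i + 1, j, k] - p0[i, j, k])
                    - azm * (p0[i, j, k] - p0[i - 1, j, k])
                    + ayp * (p0[i, j + 1, k] - p0[i, j, k])
                    - aym * (p0[i, j, k] - p0[i, j - 1, k])
                    + axp * (p0[i, j, k + 1] - p0[i, j, k])
                    - axm * (p0[i, j, k] - p0[i, j, k - 1]))
                plain = (p0[i + 1, j, k] + p0[i - 1, j, k]
                         + p0[i, j + 1, k] + p0[i, j - 1, k]
                         + p0[i, j, k + 1] + p0[i, j, k - 1]
                         - 6.0 * p0[i, j, k])

                L = (ho + flux - plain) * inv_dx2
                lap[i, j, k] = L
                nl = NLc[i, j, k] * (p0[i, j, k] * p0[i, j, k]
                                     - 2.0 * p1[i, j, k] * p1[i, j, k]
                                     + p2[i, j, k] * p2[i, j, k])
                p_next[i, j, k] = (2.0 * p0[i, j, k] - p1[i, j, k]
                                   + W[i, j, k] * L
                                   + Ldt[i, j, k] * (L - lap_prev[i, j, k])
                                   + nl)


@njit(cache=True)
def mur_3d(p_next, p0, c, dt, dx):
    nz, ny, nx = p0.shape
    for j in range(ny):
        for k in range(nx):
            q = (c[0, j, k] * dt - dx) / (c[0, j, k] * dt + dx)
            p_next[0, j, k] = p0[1, j, k] + q * (p_next[1, j, k] - p0[0, j, k])
            q = (c[nz - 1, j, k] * dt - dx) / (c[nz - 1, j, k] * dt + dx)
            p_next[nz - 1, j, k] = p0[nz - 2, j, k] + q * (
                p_next[nz - 2, j, k] - p0[nz - 1, j, k])
    for i in range(nz):
        for k in range(nx):
            q = (c[i, 0, k] * dt - dx) / (c[i, 0, k] * dt + dx)
            p_next[i, 0, k] = p0[i, 1, k] + q * (p_next[i, 1, k] - p0[i, 0, k])
            q = (c[i, ny - 1, k] * dt - dx) / (c[i, ny - 1, k] * dt + dx)
            p_next[i, ny - 1, k] = p0[i, ny - 2, k] + q * (
                p_next[i, ny - 2, k] - p0[i, ny - 1, k])
    for i in range(nz):
        for j in range(ny):
            q = (c[i, j, 0] * dt - dx) / (c[i, j, 0] * dt + dx)
            p_next[i, j, 0] = p0[i, j, 1] + q * (p_next[i, j, 1] - p0[i, j, 0])
            q = (c[i, j, nx - 1] * dt - dx) / (c[i, j, nx - 1] * dt + dx)
            p_next[i, j, nx - 1] = p0[i, j, nx - 2] + q * (
                p_next[i, j, nx - 2] - p0[i, j, nx - 1])


STEP = {"1d": step_1d, "axisymmetric": step_axisymmetric, "3d": step_3d}
MUR = {"1d": mur_1d, "axisymmetric": mur_axisymmetric, "3d": mur_3d}
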