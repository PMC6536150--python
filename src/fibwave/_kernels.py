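"""Numba inner loops for the monodomain stepper.

The kernels fuse the finite-volume diffusion stencil with the membrane
update (forward Euler on V, Rush–Larsen exponential update on the sodium
gates). They operate on full 3-D grids with a boolean inside-mask; voxels
outside the mask are never read or written, which realises the zero-flux
(homogeneous Neumann) boundary condition: a face with an outside neighbour
simply carries no flux.

The voltage-dependent membrane quantities (gate steady states, the h-gate
Rush–Larsen factor and the repolarising current) enter through uniformly
sampled lookup tables with linear interpolation, the standard device in
cardiac tissue solvers: the tables are built once per run from the exact
cell-model functions (:mod:`fibwave.cells`), and at 0.05 mV sampling the
interpolation error is far below the discretisation error. C_m = 1 uF/cm^2
is folded into the voltage equation (uA/cm^2 is mV/ms directly).

Table layout (``tabs``, shape (4, n)): rows are m_inf, h_inf,
exp(-dt/tau_h), I_K(V); sampled at ``V = v0 + j/inv_dv``.
"""

from __future__ import annotations

import math

from numba import njit

__all__ = ["advance_iso", "advance_aniso"]


@njit(cache=True, inline="always")
def _lerp_row(tabs, row, pos, n):
    j = int(pos)
    if j < 0:
        return tabs[row, 0]
    if j >= n - 1:
        return tabs[row, n - 1]
    f = pos - j
    return tabs[row, j] * (1.0 - f) + tabs[row, j + 1] * f


@njit(cache=True, inline="always")
def _membrane(v, mm, hh, stim, em_dt, gNa, ENa, tabs, v0, inv_dv):
    """One membrane step at a single voxel; returns (dVdt_reaction, m, h)."""
    pos = (v - v0) * inv_dv
    n = tabs.shape[1]
    minf = _lerp_row(tabs, 0, pos, n)
    hinf = _lerp_row(tabs, 1, pos, n)
    hrl = _lerp_row(tabs, 2, pos, n)
    ik = _lerp_row(tabs, 3, pos, n)
    ina = gNa * mm * mm * mm * hh * (v - ENa)
    dvdt = -(ina + ik) + stim
    m_new = minf + (mm - minf) * em_dt
    h_new = hinf + (hh - hinf) * hrl
    if m_new < 0.0:
        m_new = 0.0
    elif m_new > 1.0:
        m_new = 1.0
    if h_new < 0.0:
        h_new = 0.0
    elif h_new > 1.0:
        h_new = 1.0
    return dvdt, m_new, h_new


@njit(cache=True)
def advance_iso(V, Vbuf, m, h, inside, stim, n_steps, dt, d_iso, inv_dx2,
                gNa, ENa, em_dt, tabs, v0, inv_dv, react):
    """Advance ``n_steps`` with scalar diffusivity.

    Ping-pongs between the V/Vbuf buffers once per step (the caller swaps
    its references when ``n_steps`` is odd); gates are updated in place.
    """
    nx, ny, nz = V.shape
    dcoef = d_iso * inv_dx2
    A = V
    B = Vbuf
    for _ in range(n_steps):
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not inside[i, j, k]:
                        continue
                    v = A[i, j, k]
                    lap = 0.0
                    if i > 0 and inside[i - 1, j, k]:
                        lap += A[i - 1, j, k] - v
                    if i < nx - 1 and inside[i + 1, j, k]:
                        lap += A[i + 1, j, k] - v
                    if j > 0 and inside[i, j - 1, k]:
                        lap += A[i, j - 1, k] - v
                    if j < ny - 1 and inside[i, j + 1, k]:
                        lap += A[i, j + 1, k] - v
                    if k > 0 and inside[i, j, k - 1]:
                        lap += A[i, j, k - 1] - v
                    if k < nz - 1 and inside[i, j, k + 1]:
                        lap += A[i, j, k + 1] - v
                    dvdt = dcoef * lap
                    if react:
                        dr, mn, hn = _membrane(v, m[i, j, k], h[i, j, k],
                                               stim[i, j, k], em_dt,
                                               gNa, ENa, tabs, v0, inv_dv)
                        m[i, j, k] = mn
                        h[i, j, k] = hn
                        dvdt += dr
                    else:
                        dvdt += stim[i, j, k]
                    B[i, j, k] = v + dt * dvdt
        A, B = B, A
    return n_steps


@njit(cache=True)
def _grad_axis(A, inside, i, j, k, axis, inv_dx):
    """Masked centred derivative of A along axis at voxel (i,j,k)."""
    nx, ny, nz = A.shape
    if axis == 0:
        lo_ok = i > 0 and inside[i - 1, j, k]
        hi_ok = i < nx - 1 and inside[i + 1, j, k]
        lo = A[i - 1, j, k] if lo_ok else 0.0
        hi = A[i + 1, j, k] if hi_ok else 0.0
    elif axis == 1:
        lo_ok = j > 0 and inside[i, j - 1, k]
        hi_ok = j < ny - 1 and inside[i, j + 1, k]
        lo = A[i, j - 1, k] if lo_ok else 0.0
        hi = A[i, j + 1, k] if hi_ok else 0.0
    else:
        lo_ok = k > 0 and inside[i, j, k - 1]
        hi_ok = k < nz - 1 and inside[i, j, k + 1]
        lo = A[i, j, k - 1] if lo_ok else 0.0
        hi = A[i, j, k + 1] if hi_ok else 0.0
    c = A[i, j, k]
    if lo_ok and hi_ok:
        return (hi - lo) * 0.5 * inv_dx
    if hi_ok:
        return (hi - c) * inv_dx
    if lo_ok:
        return (c - lo) * inv_dx
    return 0.0


@njit(cache=True, inline="always")
def _face_flux(A, gy, gz, Dn, Dt1, Dt2, i, j, k, i2, j2, k2, inv_dx):
    """Flux through the face between voxel (i,j,k) and its inside
    neighbour (i2,j2,k2), directed from the first towards the second:
    normal derivative taken directly across the face, tangential
    derivatives (gy, gz = the two tangent axes of the face) averaged from
    the per-voxel centred arrays. Each face's value is evaluated once in
    the canonical low-to-high orientation and differenced by the caller,
    so the total divergence telescopes exactly."""
    dn = 0.5 * (Dn[i, j, k] + Dn[i2, j2, k2])
    dt1 = 0.5 * (Dt1[i, j, k] + Dt1[i2, j2, k2])
    dt2 = 0.5 * (Dt2[i, j, k] + Dt2[i2, j2, k2])
    normal = (A[i2, j2, k2] - A[i, j, k]) * inv_dx
    t1 = 0.5 * (gy[i, j, k] + gy[i2, j2, k2])
    t2 = 0.5 * (gz[i, j, k] + gz[i2, j2, k2])
    return dn * normal + dt1 * t1 + dt2 * t2


@njit(cache=True)
def advance_aniso(V, Vbuf, m, h, inside, stim, n_steps, dt,
                  Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, inv_dx,
                  gNa, ENa, em_dt, tabs, v0, inv_dv, react, gx, gy, gz):
    """Advance ``n_steps`` with a per-voxel diffusivity tensor, in
    conservative face-flux form (see :func:`_face_flux`)."""
    nx, ny, nz = V.shape
    A = V
    B = Vbuf
    for _ in range(n_steps):
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if inside[i, j, k]:
                        gx[i, j, k] = _grad_axis(A, inside, i, j, k, 0, inv_dx)
                        gy[i, j, k] = _grad_axis(A, inside, i, j, k, 1, inv_dx)
                        gz[i, j, k] = _grad_axis(A, inside, i, j, k, 2, inv_dx)
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not inside[i, j, k]:
                        continue
                    v = A[i, j, k]
                    # divergence = (high-face flux) - (low-face flux) per
                    # axis, every face evaluated low-to-high exactly once
                    div = 0.0
                    if i < nx - 1 and inside[i + 1, j, k]:
                        div += _face_flux(A, gy, gz, Dxx, Dxy, Dxz,
                                          i, j, k, i + 1, j, k, inv_dx)
                    if i > 0 and inside[i - 1, j, k]:
                        div -= _face_flux(A, gy, gz, Dxx, Dxy, Dxz,
                                          i - 1, j, k, i, j, k, inv_dx)
                    if j < ny - 1 and inside[i, j + 1, k]:
                        div += _face_flux(A, gx, gz, Dyy, Dxy, Dyz,
                                          i, j, k, i, j + 1, k, inv_dx)
                    if j > 0 and inside[i, j - 1, k]:
                        div -= _face_flux(A, gx, gz, Dyy, Dxy, Dyz,
                                          i, j - 1, k, i, j, k, inv_dx)
                    if k < nz - 1 and inside[i, j, k + 1]:
                        div += _face_flux(A, gx, gy, Dzz, Dxz, Dyz,
                                          i, j, k, i, j, k + 1, inv_dx)
                    if k > 0 and inside[i, j, k - 1]:
                        div -= _face_flux(A, gx, gy, Dzz, Dxz, Dyz,
                                          i, j, k - 1, i, j, k, inv_dx)
                    dvdt = div * inv_dx
                    if react:
                        dr, mn, hn = _membrane(v, m[i, j, k], h[i, j, k],
                                               stim[i, j, k], em_dt,
                                               gNa, ENa, tabs, v0, inv_dv)
                        m[i, j, k] = mn
                        h[i, j, k] = hn
                        dvdt += dr
                    else:
                        dvdt += stim[i, j, k]
                    B[i, j, k] = v + dt * dvdt
        A, B = B, A
    return n_steps
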