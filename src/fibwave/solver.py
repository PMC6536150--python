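"""Monodomain reaction–diffusion solver on voxelised domains.

Solves ``chi (C_m dV/dt + I_ion(u, V)) - div(sigma grad V) = 0`` with
zero-flux boundaries. With ``sigma = chi C_m D`` the voltage equation reads
``dV/dt = -(I_ion - I_stim)/C_m + div(D grad V)``, which is what the
finite-volume stepper advances: forward Euler on V, Rush–Larsen exponential
updates on the sodium gates, fused in numba kernels
(:mod:`fibwave._kernels`).

Defaults are the standard rabbit-ventricle constants: chi = 1400 1/cm, C_m = 1.0 uF/cm^2,
anisotropic D_L = 0.001 cm^2/ms with D_T = D_L/9, isotropic
sigma = 0.466 mS/cm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import _kernels
from .cells import CellParameters, rest_state
from .geometry import CHI, CM, Conductivity, Domain, conductivity_field

__all__ = ["SimulationConfig", "FieldMovie", "diffusion_term", "run",
           "stability_bound", "SolverError"]

log = logging.getLogger("fibwave.solver")


class SolverError(RuntimeError):
    """Raised when the integration produces non-finite fields."""

    def __init__(self, msg: str, last_good_frame: int):
        super().__init__(f"{msg} (last good frame index {last_good_frame})")
        self.last_good_frame = last_good_frame


@dataclass
class SimulationConfig:
    """Run parameters for :func:`run`.

    ``snapshot_interval`` defaults to 1 ms — phase mapping needs at least
    ~10 frames per rotation at fibrillatory cycle lengths of 55–130 ms.
    ``diffusion_only`` disables the membrane model (used for the analytic
    diffusion verification).
    """

    dt: float = 0.01
    duration: float = 1000.0
    snapshot_interval: float = 1.0
    chi: float = CHI
    cm: float = CM
    cell: str | CellParameters = "P2"
    diffusion_only: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.snapshot_interval < self.dt:
            raise ValueError("snapshot_interval must be >= dt")

    @property
    def cell_params(self) -> CellParameters:
        if isinstance(self.cell, CellParameters):
            return self.cell
        return CellParameters.from_label(self.cell)


@dataclass
class FieldMovie:
    """Time-stamped voltage snapshots on a domain.

    ``frames`` has shape ``(n_times,) + grid_shape`` (2-D grids stay 2-D),
    stored float32; ``provenance`` records the config, domain descriptor and
    protocol that produced it.
    """

    times: np.ndarray
    frames: np.ndarray
    spacing: float
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.frames):
            raise ValueError("times/frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def frame_at(self, t: float) -> np.ndarray:
        return self.frames[int(np.argmin(np.abs(self.times - t)))]

    def window(self, t0: float, t1: float) -> "FieldMovie":
        sel = (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)
        return FieldMovie(self.times[sel], self.frames[sel], self.spacing,
                          provenance=dict(self.provenance))


def _as3d(a: np.ndarray) -> np.ndarray:
    return a[..., None] if a.ndim == 2 else a


#: Lookup-table voltage range and resolution (mV); dynamics stay well inside.
TABLE_V0, TABLE_V1, TABLE_DV = -150.0, 150.0, 0.05


def _cell_args(params: CellParameters, dt: float):
    """Kernel arguments: I_Na constants plus the voltage lookup tables
    built from the exact cell-model functions."""
    from .cells import gate_steady_states, gate_time_constants, ik_current

    na = params.sodium
    V = np.arange(TABLE_V0, TABLE_V1 + TABLE_DV / 2, TABLE_DV)
    m_inf, h_inf = gate_steady_states(V, na)
    _, tau_h = gate_time_constants(V, na)
    tabs = np.ascontiguousarray(np.stack([
        m_inf, h_inf, np.exp(-dt / tau_h), ik_current(V, params)]))
    em_dt = float(np.exp(-dt / na["tau_m"]))
    return (na["g_Na"], na["E_Na"], em_dt, tabs, TABLE_V0, 1.0 / TABLE_DV)


def _dummy_cell_args():
    return (0.0, 0.0, 1.0, np.zeros((4, 2)), TABLE_V0, 1.0 / TABLE_DV)


def diffusion_term(V_field: np.ndarray, domain: Domain,
                   conductivity: Conductivity) -> np.ndarray:
    """One evaluation of ``div(D grad V)`` in mV/ms — the conductivity term
    of the monodomain equation already divided by chi*C_m.

    The isotropic branch is an independent pure-numpy implementation of the
    stencil (used as the oracle for the fused kernel); the anisotropic
    branch evaluates the conservative face-flux scheme via a single
    reaction-free kernel step.
    """
    if V_field.shape != domain.shape:
        raise ValueError(f"field shape {V_field.shape} != domain {domain.shape}")
    V = _as3d(np.asarray(V_field, dtype=float)).copy()
    inside = _as3d(domain.mask)
    dx = domain.spacing
    if conductivity.mode == "isotropic":
        out = np.zeros_like(V)
        d = conductivity.d_iso / dx ** 2
        for axis in range(3):
            for sgn in (+1, -1):
                Vn = np.roll(V, -sgn, axis=axis)
                In = np.roll(inside, -sgn, axis=axis)
                edge = np.zeros(V.shape, dtype=bool)
                idx = [slice(None)] * 3
                idx[axis] = -1 if sgn > 0 else 0
                edge[tuple(idx)] = True
                ok = inside & In & ~edge
                out += np.where(ok, d * (Vn - V), 0.0)
        out[~inside] = 0.0
        return out.reshape(V_field.shape)
    t6 = _as3d_tensor(conductivity.tensor)
    Dcomp = [np.ascontiguousarray(t6[..., c]) for c in range(6)]
    scratch = [np.zeros_like(V) for _ in range(3)]
    Vbuf = V.copy()
    zero = np.zeros_like(V)
    _kernels.advance_aniso(V, Vbuf, zero.copy(), zero.copy(),
                           inside.astype(np.uint8), zero, 1, 1.0,
                           *Dcomp, 1.0 / dx, *_dummy_cell_args(), False,
                           *scratch)
    out = Vbuf - _as3d(np.asarray(V_field, dtype=float))  # dt = 1, one step
    out[~inside] = 0.0
    return out.reshape(V_field.shape)


def _as3d_tensor(t: np.ndarray) -> np.ndarray:
    return t[:, :, None, :] if t.ndim == 3 else t


def stability_bound(config: SimulationConfig, domain: Domain,
                    conductivity: Conductivity) -> float:
    """Largest safe dt (ms): the explicit diffusion bound
    ``dx^2 / (2 * ndim * D_max)`` combined with a reaction cap that
    resolves the fastest gate time constant (tau_m) with >= 6 steps."""
    dmax = conductivity.max_diffusivity()
    ndim = domain.dimensionality
    diff_bound = domain.spacing ** 2 / (2.0 * ndim * dmax) if dmax > 0 else np.inf
    reaction_cap = float(config.cell_params.sodium["tau_m"]) / 6.0
    return float(min(diff_bound, reaction_cap))


def run(domain: Domain, config: SimulationConfig, protocol=None,
        conductivity: Optional[Conductivity] = None,
        progress: bool = False) -> FieldMovie:
    """Integrate the monodomain equation and return a :class:`FieldMovie`.

    ``protocol`` is a :class:`fibwave.protocols.StimulusProtocol` or a bare
    list of ``(mask, onset_ms, duration_ms, amplitude)`` events; None means
    an unstimulated run. Deterministic for fixed inputs on one machine.
    Warns if ``config.dt`` exceeds the estimated stability bound; raises
    :class:`SolverError` (recording the last good frame) on divergence.
    """
    from .protocols import StimulusProtocol  # runtime import, no cycle

    if conductivity is None:
        conductivity = conductivity_field(domain, "isotropic")
    bound = stability_bound(config, domain, conductivity)
    if config.dt > bound * (1 + 1e-9):
        warnings.warn(f"dt={config.dt} ms exceeds estimated stability bound "
                      f"{bound:.4g} ms", RuntimeWarning, stacklevel=2)
    params = config.cell_params
    inside = _as3d(domain.mask).astype(np.uint8)
    shape3 = inside.shape
    rest = rest_state(params)
    V = np.full(shape3, rest.V, dtype=float)
    m = np.full(shape3, rest.m, dtype=float)
    h = np.full(shape3, rest.h, dtype=float)
    Vbuf = V.copy()

    if protocol is None:
        events = []
    elif isinstance(protocol, StimulusProtocol):
        events = protocol.resolve(domain)
    else:
        events = [(_as3d(np.asarray(mk, dtype=bool)), on, du, am)
                  for (mk, on, du, am) in protocol]

    n_frames = int(np.floor(config.duration / config.snapshot_interval + 1e-9)) + 1
    steps_per_frame = int(round(config.snapshot_interval / config.dt))
    out_shape = domain.shape
    frames = np.empty((n_frames,) + out_shape, dtype=np.float32)
    times = np.arange(n_frames) * config.snapshot_interval

    def squeeze(a):
        return a[..., 0] if len(out_shape) == 2 else a

    frames[0] = squeeze(V)

    aniso = conductivity.mode == "anisotropic"
    if aniso:
        t6 = _as3d_tensor(conductivity.tensor)
        Dcomp = [np.ascontiguousarray(t6[..., c]) for c in range(6)]
        scratch = [np.zeros(shape3) for _ in range(3)]
    cargs = _cell_args(params, config.dt)
    react = not config.diffusion_only
    stim = np.zeros(shape3)

    for fi in range(1, n_frames):
        t0 = times[fi - 1]
        # split the frame wherever the set of active stimuli changes
        cuts = {0, steps_per_frame}
        for (_mk, on, du, _a) in events:
            for te in (on, on + du):
                s = int(round((te - t0) / config.dt))
                if 0 < s < steps_per_frame:
                    cuts.add(s)
        cuts = sorted(cuts)
        for a, b in zip(cuts[:-1], cuts[1:]):
            t_mid = t0 + (a + 0.5) * config.dt
            stim[:] = 0.0
            for (mk, on, du, amp) in events:
                if on - 1e-9 <= t_mid < on + du - 1e-9:
                    stim[mk] += amp
            n_sub = b - a
            if aniso:
                _kernels.advance_aniso(V, Vbuf, m, h, inside, stim, n_sub,
                                       config.dt, *Dcomp, 1.0 / domain.spacing,
                                       *cargs, react, *scratch)
            else:
                _kernels.advance_iso(V, Vbuf, m, h, inside, stim, n_sub,
                                     config.dt, conductivity.d_iso,
                                     1.0 / domain.spacing ** 2, *cargs, react)
            if n_sub % 2 == 1:  # kernels ping-pong buffers once per step
                V, Vbuf = Vbuf, V
        if not np.all(np.isfinite(V[inside == 1])):
            raise SolverError("non-finite voltage (integration diverged)", fi - 1)
        frames[fi] = squeeze(V)
        if progress and fi % 200 == 0:
            log.info("t = %.0f ms (frame %d/%d)", times[fi], fi, n_frames - 1)

    prov = {"config": {"dt": config.dt, "duration": config.duration,
                       "snapshot_interval": config.snapshot_interval,
                       "chi": config.chi, "cm": config.cm,
                       "cell": params.label,
                       "conductivity": conductivity.mode},
            "domain": domain.descriptor}
    return FieldMovie(times=times, frames=frames, spacing=domain.spacing,
                      provenance=prov)
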