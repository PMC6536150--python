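"""Parsimonious rabbit ventricular action-potential model.

Two ionic currents, three state variables:

* a Hodgkin–Huxley-type fast sodium current ``I_Na = g_Na m^3 h (V - E_Na)``
  responsible for the upstroke (parameters shipped as a packaged fixture,
  see :data:`SODIUM_FIXTURE_NAME`), and
* a closed-form, time-independent repolarising potassium current
  ``I_K = g_K (V - V_rest) exp(-beta (V - V_rest))`` with ``V_rest = -83 mV``.

Four named parameter sets vary only the potassium current:

========  =========  ==========
label     g_K        beta
          (mS/cm^2)  (1/mV)
========  =========  ==========
P1        0.5        0.030
P2        0.5        0.035
P3        0.5        0.040
P4        0.3        0.035
========  =========  ==========

In 2-D isotropic sheets these produce, respectively, stable reentry,
spiral-wave breakup, and (P3, P4) meandering spiral waves.

Sign convention: positive current = outward (repolarising); the membrane
equation is ``C_m dV/dt = -(I_Na + I_K) + I_stim`` with ``I_stim``
positive-depolarising.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "CellParameters",
    "CellState",
    "PARAMETER_SETS",
    "V_REST",
    "load_sodium_parameters",
    "ik_current",
    "ina_current",
    "ionic_current",
    "gate_steady_states",
    "gate_time_constants",
    "rest_state",
    "step_cell",
    "action_potential_trace",
    "diastolic_threshold",
]

SODIUM_FIXTURE_NAME = "ina_parsimonious_rabbit.json"

#: Resting (potassium reversal) potential, mV.
V_REST = -83.0

#: The named potassium-current parameter sets (g_K in mS/cm^2, beta in 1/mV).
PARAMETER_SETS: Mapping[str, tuple[float, float]] = {
    "P1": (0.5, 0.030),
    "P2": (0.5, 0.035),
    "P3": (0.5, 0.040),
    "P4": (0.3, 0.035),
}


def load_sodium_parameters() -> dict:
    """Load the sodium-current parameter bundle from the packaged fixture.

    Raises
    ------
    FileNotFoundError
        If the fixture is missing from the installation (configuration error).
    """
    ref = resources.files("fibwave.data").joinpath(SODIUM_FIXTURE_NAME)
    try:
        text = ref.read_text()
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover
        raise FileNotFoundError(
            f"sodium-current fixture {SODIUM_FIXTURE_NAME!r} not packaged"
        ) from exc
    return json.loads(text)["parameters"]


@dataclass(frozen=True)
class CellParameters:
    """Full parameter bundle of the cell model.

    ``g_K`` (mS/cm^2) and ``beta`` (1/mV) shape the repolarising current;
    ``sodium`` is the opaque I_Na bundle read from the packaged fixture.
    """

    g_K: float
    beta: float
    V_rest: float = V_REST
    label: str = "custom"
    sodium: Mapping[str, float] = field(default_factory=load_sodium_parameters)

    def __post_init__(self) -> None:
        if not (self.g_K > 0):
            raise ValueError(f"g_K must be positive, got {self.g_K}")
        if not (self.beta > 0):
            raise ValueError(f"beta must be positive, got {self.beta}")

    @classmethod
    def from_label(cls, label: str) -> "CellParameters":
        """Return one of the named sets P1–P4."""
        try:
            g_K, beta = PARAMETER_SETS[label]
        except KeyError:
            raise KeyError(
                f"unknown parameter set {label!r}; choose from {sorted(PARAMETER_SETS)}"
            ) from None
        return cls(g_K=g_K, beta=beta, label=label)

    def with_(self, **changes) -> "CellParameters":
        return replace(self, label="custom", **changes)


@dataclass
class CellState:
    """Membrane state: voltage ``V`` (mV) and sodium gates ``m``, ``h`` in [0,1]."""

    V: float | np.ndarray
    m: float | np.ndarray
    h: float | np.ndarray

    def copy(self) -> "CellState":
        return CellState(np.copy(self.V), np.copy(self.m), np.copy(self.h))


def ik_current(V, params: CellParameters):
    """Repolarising potassium current, uA/cm^2 (positive outward).

    ``I_K = g_K (V - V_rest) exp(-beta (V - V_rest))``: zero at rest,
    positive above rest, with a single interior maximum ``g_K/(beta e)``
    at ``V = V_rest + 1/beta``.
    """
    dv = np.asarray(V, dtype=float) - params.V_rest
    return params.g_K * dv * np.exp(-params.beta * dv)


def gate_steady_states(V, sodium: Mapping[str, float]):
    """Steady-state activation/inactivation (m_inf, h_inf) at voltage V."""
    V = np.asarray(V, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(V - sodium["E_m"]) / sodium["k_m"]))
    h_inf = 1.0 / (1.0 + np.exp((V - sodium["E_h"]) / sodium["k_h"]))
    return m_inf, h_inf


def gate_time_constants(V, sodium: Mapping[str, float]):
    """Gate time constants (tau_m, tau_h) in ms at voltage V.

    tau_m is voltage-independent; tau_h is a skewed bell peaking near the
    inactivation midpoint.
    """
    V = np.asarray(V, dtype=float)
    x = (V - sodium["E_h"]) / sodium["k_h"]
    tau_h = 2.0 * sodium["tau_h0"] * np.exp(sodium["delta_h"] * x) / (1.0 + np.exp(x))
    return np.broadcast_to(float(sodium["tau_m"]), V.shape).copy() if V.shape else float(sodium["tau_m"]), tau_h


def ina_current(state: CellState, params: CellParameters):
    """Fast sodium current, uA/cm^2 (negative = inward below E_Na)."""
    na = params.sodium
    m = np.clip(state.m, 0.0, 1.0)
    h = np.clip(state.h, 0.0, 1.0)
    return na["g_Na"] * m ** int(na["m_exponent"]) * h ** int(na["h_exponent"]) * (
        np.asarray(state.V, dtype=float) - na["E_Na"]
    )


def ionic_current(state: CellState, params: CellParameters):
    """Total ionic current ``I_ion = I_Na + I_K`` (uA/cm^2, positive outward)."""
    return ina_current(state, params) + ik_current(state.V, params)


def rest_state(params: CellParameters) -> CellState:
    """The quiescent fixed point: V_rest with gates at steady state."""
    m_inf, h_inf = gate_steady_states(params.V_rest, params.sodium)
    return CellState(V=float(params.V_rest), m=float(m_inf), h=float(h_inf))


def step_cell(state: CellState, dt: float, I_stim, params: CellParameters) -> CellState:
    """Advance one time step: forward Euler on V, Rush–Larsen on the gates.

    The exponential (Rush–Larsen) gate update
    ``g <- g_inf + (g - g_inf) exp(-dt/tau_g)`` is unconditionally stable and
    keeps gates inside [0,1] for any dt.
    ``C_m`` is 1 uF/cm^2 throughout (membrane equation in mV/ms).
    """
    na = params.sodium
    V = np.asarray(state.V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite voltage entering step_cell")
    dVdt = -(ionic_current(state, params)) + I_stim  # C_m = 1 uF/cm^2
    m_inf, h_inf = gate_steady_states(V, na)
    tau_m, tau_h = gate_time_constants(V, na)
    m = m_inf + (state.m - m_inf) * np.exp(-dt / tau_m)
    h = h_inf + (state.h - h_inf) * np.exp(-dt / np.asarray(tau_h))
    return CellState(V=V + dt * dVdt, m=np.clip(m, 0.0, 1.0), h=np.clip(h, 0.0, 1.0))


def _integrate(params: CellParameters, dt: float, n_steps: int,
               stim_fn=None, state: CellState | None = None):
    """Integrate a single cell; returns (times, V) sampled every step."""
    s = state.copy() if state is not None else rest_state(params)
    V = np.empty(n_steps + 1)
    V[0] = s.V
    for k in range(n_steps):
        t = k * dt
        I = stim_fn(t) if stim_fn is not None else 0.0
        s = step_cell(s, dt, I, params)
        V[k + 1] = s.V
    return np.arange(n_steps + 1) * dt, V, s


def action_potential_trace(params: CellParameters, pacing_cl: float = 300.0,
                           beats: int = 5, dt: float = 0.01,
                           stim_amplitude: float | None = None,
                           stim_duration: float = 2.0,
                           apd_fraction: float = 0.9):
    """Pace a single cell and return the final-beat trace and its APD.

    ``stim_amplitude`` defaults to twice the diastolic threshold. (The
    repolarising current decays exponentially above its maximum, so a
    grossly suprathreshold stimulus overdrives the cell into a
    slowly-recovering regime; 2x threshold is the convention throughout.)

    Returns a dict with keys ``t`` (ms, zeroed at the final stimulus),
    ``V`` (mV), ``apd`` (ms at the requested repolarisation fraction,
    default APD90), ``captured`` (bool; False flags loss of 1:1 capture,
    not an error).
    """
    if stim_amplitude is None:
        stim_amplitude = 2.0 * diastolic_threshold(params, stim_duration, dt)

    def stim(t):
        return stim_amplitude if (t % pacing_cl) < stim_duration else 0.0

    n_total = int(round(beats * pacing_cl / dt))
    t, V, _ = _integrate(params, dt, n_total, stim)
    i0 = int(round((beats - 1) * pacing_cl / dt))
    tb, Vb = t[i0:] - t[i0], V[i0:]
    peak = float(Vb.max())
    captured = peak > 0.0
    apd = np.nan
    if captured:
        v_cross = peak - apd_fraction * (peak - params.V_rest)
        ipk = int(Vb.argmax())
        below = np.nonzero(Vb[ipk:] <= v_cross)[0]
        if below.size:
            j = ipk + below[0]
            # linear interpolation across the crossing sample
            v1, v2 = Vb[j - 1], Vb[j]
            frac = (v1 - v_cross) / (v1 - v2) if v2 != v1 else 0.0
            apd = float(tb[j - 1] + frac * dt - tb[np.nonzero(Vb >= -40.0)[0][0]])
    return {"t": tb, "V": Vb, "apd": apd, "captured": captured}


def diastolic_threshold(params: CellParameters, stim_duration: float = 2.0,
                        dt: float = 0.01, tol: float = 0.5) -> float:
    """Diastolic excitation threshold (uA/cm^2) for a pulse of the given
    duration, found by bisection from rest. A stimulus "captures" if the
    voltage is still above 0 mV a few ms after the pulse ends — i.e. a
    regenerative sodium upstroke, not mere stimulus-driven charging."""

    def fires(amp: float) -> bool:
        stim = lambda t: amp if t < stim_duration else 0.0
        _, V, _ = _integrate(params, dt, int(20.0 / dt), stim)
        i0 = int((stim_duration + 3.0) / dt)
        return bool(V[i0:].max() > 0.0)

    lo, hi = 0.0, 8.0
    while not fires(hi):
        hi *= 2.0
        if hi > 512:  # pragma: no cover - inexcitable parameterisation
            raise RuntimeError("cell does not fire at any tested amplitude")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lo, hi = (lo, mid) if fires(mid) else (mid, hi)
    return hi
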