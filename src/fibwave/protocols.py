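"""Stimulation protocols: S1–S2 cross-field reentry induction and
vulnerable-window scans.

The whole-heart induction protocol: a conditioning stimulus (S1)
near the apex, then a second stimulus (S2) over a large ellipsoidal region
of the lateral-posterior left-ventricular wall, timed into the apex-to-base
repolarisation wave. On 2-D sheets the classic cross-field geometry is
used instead: S1 as a left-edge strip (planar wave along +x), S2 as the
bottom half-plane, fired while the S2 region straddles the recovery line so
that a wavebreak with a single phase singularity forms near the sheet
centre.

Stimulus amplitudes default to twice the diastolic threshold, 2 ms pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cells import CellParameters, diastolic_threshold
from .geometry import Conductivity, Domain, conductivity_field, make_sheet

__all__ = ["Region", "Box", "Sphere", "Ellipsoid", "Named", "StimulusEvent",
           "StimulusProtocol", "s1s2_protocol", "find_s2_time",
           "induce_sheet_reentry", "vulnerable_window_scan",
           "default_s2_amplitude"]


class Region:
    """Geometric stimulus region resolvable to a voxel mask on a domain."""

    def mask(self, domain: Domain) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def to_dict(self) -> dict:  # pragma: no cover
        raise NotImplementedError


def _coords(domain: Domain):
    idx = np.indices(domain.shape, dtype=float)
    return [a * domain.spacing for a in idx]


@dataclass
class Box(Region):
    lo: tuple
    hi: tuple

    def mask(self, domain: Domain) -> np.ndarray:
        cs = _coords(domain)
        m = np.ones(domain.shape, dtype=bool)
        for c, l, u in zip(cs, self.lo, self.hi):
            m &= (c >= l) & (c <= u)
        return m & domain.mask

    def to_dict(self):
        return {"kind": "box", "lo": list(self.lo), "hi": list(self.hi)}


@dataclass
class Sphere(Region):
    center: tuple
    radius: float

    def mask(self, domain: Domain) -> np.ndarray:
        cs = _coords(domain)
        r2 = sum((c - x0) ** 2 for c, x0 in zip(cs, self.center))
        return (r2 <= self.radius ** 2) & domain.mask

    def to_dict(self):
        return {"kind": "sphere", "center": list(self.center),
                "radius": self.radius}


@dataclass
class Ellipsoid(Region):
    center: tuple
    semi_axes: tuple

    def mask(self, domain: Domain) -> np.ndarray:
        cs = _coords(domain)
        r2 = sum(((c - x0) / s) ** 2
                 for c, x0, s in zip(cs, self.center, self.semi_axes))
        return (r2 <= 1.0) & domain.mask

    def to_dict(self):
        return {"kind": "ellipsoid", "center": list(self.center),
                "semi_axes": list(self.semi_axes)}


@dataclass
class Named(Region):
    """Named anchors: 'left_edge' / 'bottom_half' on sheets, 'apex' /
    'lateral_posterior' on shells."""

    name: str

    def mask(self, domain: Domain) -> np.ndarray:
        ext = [(s - 1) * domain.spacing for s in domain.shape]
        if self.name == "left_edge":
            return Box((0, 0) if domain.dimensionality == 2 else (0, 0, 0),
                       (0.06,) + tuple(ext[1:])).mask(domain)
        if self.name == "bottom_half":
            lo = [0.0] * domain.dimensionality
            hi = list(ext)
            hi[1] = 0.5 * ext[1]
            return Box(tuple(lo), tuple(hi)).mask(domain)
        if self.name == "apex":
            # lowest-z cap of the shell
            zs = np.argwhere(domain.mask)[:, 2]
            z0 = zs.min() * domain.spacing
            lo = (0.0, 0.0, z0)
            hi = (ext[0], ext[1], z0 + 0.15 * (ext[2] - z0))
            return Box(lo, hi).mask(domain)
        if self.name == "lateral_posterior":
            # ellipsoid patch on the high-y wall at mid-height, spanning
            # roughly a quarter of the free wall
            ys = np.argwhere(domain.mask)[:, 1]
            y1 = ys.max() * domain.spacing
            c = (0.5 * ext[0], y1, 0.55 * ext[2])
            semi = (0.35 * ext[0], 0.3 * ext[1], 0.35 * ext[2])
            return Ellipsoid(c, semi).mask(domain)
        raise ValueError(f"unknown named region {self.name!r}")

    def to_dict(self):
        return {"kind": "named", "name": self.name}


def region_from_dict(d: dict) -> Region:
    kind = d["kind"]
    if kind == "box":
        return Box(tuple(d["lo"]), tuple(d["hi"]))
    if kind == "sphere":
        return Sphere(tuple(d["center"]), d["radius"])
    if kind == "ellipsoid":
        return Ellipsoid(tuple(d["center"]), tuple(d["semi_axes"]))
    if kind == "named":
        return Named(d["name"])
    raise ValueError(f"unknown region kind {kind!r}")


@dataclass
class StimulusEvent:
    region: Region
    onset: float  # ms
    duration: float = 2.0  # ms
    amplitude: float = 45.0  # uA/cm^2


@dataclass
class StimulusProtocol:
    """Time-ordered stimulus events; every region must intersect the mask."""

    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("stimulus events must be time-ordered")

    def resolve(self, domain: Domain):
        """Materialise events to (mask3d, onset, duration, amplitude)."""
        out = []
        for e in self.events:
            mk = e.region.mask(domain)
            if not mk.any():
                raise ValueError(f"stimulus region {e.region} misses the mask")
            mk3 = mk[..., None] if mk.ndim == 2 else mk
            out.append((mk3, e.onset, e.duration, e.amplitude))
        return out

    def to_dict(self) -> dict:
        return {"events": [{"region": e.region.to_dict(), "onset": e.onset,
                            "duration": e.duration, "amplitude": e.amplitude}
                           for e in self.events]}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(events=[StimulusEvent(region_from_dict(e["region"]),
                                         e["onset"], e["duration"],
                                         e["amplitude"])
                           for e in d["events"]])


def default_s2_amplitude(params: CellParameters, duration: float = 2.0) -> float:
    """Twice the diastolic threshold for a pulse of the given duration."""
    return 2.0 * diastolic_threshold(params, stim_duration=duration)


def s1s2_protocol(domain: Domain, t2: float, amplitude: Optional[float] = None,
                  params: Optional[CellParameters] = None,
                  s1_region: Optional[Region] = None,
                  s2_region: Optional[Region] = None,
                  duration: float = 2.0) -> StimulusProtocol:
    """Build the S1–S2 protocol for a sheet (cross-field) or shell (apex +
    lateral-posterior ellipsoid). ``t2`` must follow the S1 onset (0 ms);
    amplitude defaults to 2x diastolic threshold for ``params``."""
    if t2 <= 0:
        raise ValueError("t2 must be after the S1 onset (t=0)")
    if amplitude is None:
        if params is None:
            raise ValueError("give either amplitude or params")
        amplitude = default_s2_amplitude(params, duration)
    if s1_region is None:
        s1_region = Named("left_edge" if domain.dimensionality == 2 else "apex")
    if s2_region is None:
        s2_region = Named("bottom_half" if domain.dimensionality == 2
                          else "lateral_posterior")
    return StimulusProtocol(events=[
        StimulusEvent(s1_region, onset=0.0, duration=duration, amplitude=amplitude),
        StimulusEvent(s2_region, onset=t2, duration=duration, amplitude=amplitude),
    ])


def find_s2_time(domain: Domain, params: CellParameters,
                 conductivity: Optional[Conductivity] = None,
                 dt: float = 0.02, recovery_voltage: float = -70.0,
                 probe: Optional[tuple] = None, t_max: float = 500.0,
                 amplitude: Optional[float] = None) -> float:
    """Operationalise "S2 timed into the repolarisation wave": simulate the
    S1 beat alone and return the time at which the probe site (default: the
    domain centroid) repolarises through ``recovery_voltage``. Firing S2
    then places the S2-region boundary across the recovery line."""
    from .solver import SimulationConfig, run

    if conductivity is None:
        conductivity = conductivity_field(domain, "isotropic")
    if amplitude is None:
        amplitude = default_s2_amplitude(params)
    s1 = StimulusProtocol(events=[StimulusEvent(
        Named("left_edge" if domain.dimensionality == 2 else "apex"),
        onset=0.0, amplitude=amplitude)])
    cfg = SimulationConfig(dt=dt, duration=t_max, snapshot_interval=1.0,
                           cell=params)
    movie = run(domain, cfg, protocol=s1, conductivity=conductivity)
    if probe is None:
        idx = np.argwhere(domain.mask)
        centroid = idx.mean(axis=0)
        probe = tuple(idx[np.argmin(((idx - centroid) ** 2).sum(axis=1))])
    trace = movie.frames[(slice(None),) + probe]
    active = np.nonzero(trace > 0.0)[0]
    if active.size == 0:
        raise RuntimeError("S1 did not excite the probe site")
    rec = np.nonzero(trace[active[0]:] < recovery_voltage)[0]
    if rec.size == 0:
        raise RuntimeError(f"probe did not recover below {recovery_voltage} mV "
                           f"within {t_max} ms")
    return float(movie.times[active[0] + rec[0]])


def induce_sheet_reentry(params: CellParameters | str, side: float = 3.5,
                         spacing: float = 0.0125, dt: float = 0.01,
                         duration_after_s2: float = 2200.0,
                         snapshot_interval: float = 1.0,
                         s2_radius: float = 0.6, s2_center_y: float = 1.2,
                         probe_frac: float = 0.3,
                         recovery_voltage: float = -70.0,
                         probe_dt: Optional[float] = None):
    """Standard 2-D spiral-wave initiation used for the sheet experiments.

    S1 (left-edge strip, 2x diastolic threshold) launches a planar wave;
    S2 is a circular patch (radius ``s2_radius``) at x = ``probe_frac *
    side``, fired at 1.3x threshold when the probe site repolarises through
    ``recovery_voltage`` — the patch then straddles the recovery line and
    breaks into a counter-rotating tip pair. The patch is offset from the
    sheet midline (``s2_center_y``) so that one tip is born within a
    wavelength of the bottom boundary and is absorbed by it, leaving the
    surviving spiral centred in the sheet.

    Returns ``(movie, info)`` with ``info`` holding t2, the threshold and
    the resolved protocol. Deterministic end to end.
    """
    from .solver import SimulationConfig, run

    if isinstance(params, str):
        params = CellParameters.from_label(params)
    dom = make_sheet(side, spacing)
    cond = conductivity_field(dom, "isotropic")
    n = dom.shape[0]
    thr = diastolic_threshold(params)
    # the S1 timing probe is a separate short run at the same dt
    t2 = find_s2_time(dom, params, cond, dt=probe_dt or dt, t_max=300.0,
                      recovery_voltage=recovery_voltage,
                      probe=(int(probe_frac * n), n // 2))
    proto = StimulusProtocol(events=[
        StimulusEvent(Named("left_edge"), onset=0.0, duration=2.0,
                      amplitude=2.0 * thr),
        StimulusEvent(Ellipsoid((probe_frac * side, s2_center_y),
                                (s2_radius, s2_radius)), onset=t2,
                      duration=2.0, amplitude=1.3 * thr)])
    cfg = SimulationConfig(dt=dt, duration=t2 + duration_after_s2,
                           snapshot_interval=snapshot_interval, cell=params)
    movie = run(dom, cfg, protocol=proto, conductivity=cond)
    movie.provenance["t2"] = t2
    movie.provenance["protocol"] = proto.to_dict()
    info = {"t2": t2, "threshold": thr, "protocol": proto, "domain": dom,
            "conductivity": cond}
    return movie, info


def vulnerable_window_scan(domain: Domain, params: CellParameters,
                           t2_list: Sequence[float],
                           conductivity: Optional[Conductivity] = None,
                           dt: float = 0.02, duration_after_s2: float = 1000.0,
                           amplitude: Optional[float] = None):
    """Run one S1–S2 simulation per S2 timing, identical otherwise, and
    label the outcome of each: 'no_reentry' (no phase singularity after the
    S2 transient), 'sustained' (PS present throughout the final 200 ms) or
    'self_terminated'. Returns a list of dicts with the PS-count series.

    Solver failures are recorded per run without aborting the scan.
    """
    from .phase import compute_phase, detect_phase_singularities
    from .solver import SimulationConfig, run

    if len(t2_list) < 2:
        raise ValueError("scan needs at least two S2 timings")
    if conductivity is None:
        conductivity = conductivity_field(domain, "isotropic")
    if amplitude is None:
        amplitude = default_s2_amplitude(params)
    rows = []
    for t2 in t2_list:
        proto = s1s2_protocol(domain, t2, amplitude=amplitude)
        cfg = SimulationConfig(dt=dt, duration=t2 + duration_after_s2,
                               cell=params)
        try:
            movie = run(domain, cfg, protocol=proto, conductivity=conductivity)
        except Exception as exc:  # propagate per-run, keep scanning
            rows.append({"t2": t2, "outcome": "error", "error": str(exc),
                         "times": None, "ps_counts": None})
            continue
        pm = compute_phase(movie)
        counts = np.array([len(detect_phase_singularities(fr))
                           for fr in pm.frames])
        tail = counts[pm.times >= pm.times[-1] - 200.0]
        post = counts[pm.times >= t2 + 50.0]
        if tail.size and tail.min() > 0:
            outcome = "sustained"
        elif post.max(initial=0) == 0:
            outcome = "no_reentry"
        else:
            outcome = "self_terminated"
        rows.append({"t2": t2, "outcome": outcome, "times": pm.times,
                     "ps_counts": counts})
    return rows
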