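"""Scroll-wave filament detection, linking and classification in 3-D.

A scroll wave rotates around a 1-D curve (the filament). Filaments are
located by applying the 2-D topological-charge test to every voxel-grid
plaquette in all three orientations: a plaquette whose phase winds by
+/-2pi is punctured by a filament. Punctures that lie on the faces of the
same elementary grid cube are linked (a filament entering a cube must
leave it — face-charge conservation), which chains punctures into
polylines: closed loops (O-shaped, fully intramural, no surface phase
singularities) or open curves whose two endpoints lie on the domain
boundary — transmurally (linear, one spiral on each surface) or on the
same surface (U-shaped, a figure-of-eight on that surface with a
breakthrough pattern opposite).

Filament counts over time, windowed means per experiment label, and the
divergence of two count series (for sensitivity analyses) are provided
here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import Domain, SURFACE_ENDO, SURFACE_EPI
from .phase import wrap_angle

__all__ = ["FilamentPoint", "Filament", "FilamentSet", "FilamentCountSeries",
           "detect_filaments", "count_series", "classify_filament",
           "divergence", "surface_phase_singularities"]


@dataclass
class FilamentPoint:
    """A singular plaquette: centre position (voxel units), orientation
    axis (0/1/2 = normal of the plaquette), and charge (winding sign along
    +axis)."""

    position: tuple  # (x, y, z) in voxel units (plaquette centre)
    axis: int
    charge: int
    face_id: tuple  # (axis, i, j, k) lowest-corner index, for tie-breaks


@dataclass
class Filament:
    """An ordered polyline of punctures."""

    points: list  # FilamentPoint, ordered along the curve
    closed: bool
    endpoint_labels: tuple = ("none", "none")  # surface labels of the two ends

    def __len__(self) -> int:
        return len(self.points)

    def positions_cm(self, spacing: float) -> np.ndarray:
        return np.asarray([p.position for p in self.points], dtype=float) * spacing


@dataclass
class FilamentSet:
    """Filaments of one frame."""

    filaments: list
    time: float = 0.0

    @property
    def count(self) -> int:
        return len(self.filaments)

    def count_excluding_fragments(self, min_points: int = 2) -> int:
        """Count excluding sub-voxel fragments (single-puncture chains);
        fragments are retained in ``filaments`` but flagged by length."""
        return sum(1 for f in self.filaments if len(f) >= min_points)


@dataclass
class FilamentCountSeries:
    """Filament counts per movie frame, with the experiment label."""

    times: np.ndarray
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.times.shape != self.counts.shape:
            raise ValueError("times/counts shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("filament counts must be non-negative")

    def windowed_mean(self, t0: float, t1: float) -> float:
        sel = (self.times >= t0) & (self.times <= t1)
        return float(self.counts[sel].mean()) if sel.any() else float("nan")


def _plaquette_windings(phase: np.ndarray, axis: int) -> np.ndarray:
    """Winding number of every plaquette normal to ``axis``.

    The loop is taken counter-clockwise when viewed from +axis, so the
    winding sign is the topological charge along +axis: the in-plane axes
    (a1, a2) are ordered so that a1 x a2 = +axis (cyclically), keeping the
    orientation convention consistent across the three face families —
    required for the in/out pairing inside cubes.
    """
    a1, a2 = ((1, 2), (2, 0), (0, 1))[axis]

    def sh(arr, d1, d2):
        sl = [slice(0, -1)] * 3
        sl[axis] = slice(None)
        sl[a1] = slice(1, None) if d1 else slice(0, -1)
        sl[a2] = slice(1, None) if d2 else slice(0, -1)
        return arr[tuple(sl)]

    p00, p10 = sh(phase, 0, 0), sh(phase, 1, 0)
    p11, p01 = sh(phase, 1, 1), sh(phase, 0, 1)
    s = (wrap_angle(p10 - p00) + wrap_angle(p11 - p10)
         + wrap_angle(p01 - p11) + wrap_angle(p00 - p01))
    return np.round(s / (2 * np.pi)).astype(np.int8)


def detect_filaments(phase_frame: np.ndarray, domain: Domain,
                     time: float = 0.0) -> FilamentSet:
    """Detect and link filaments in one volumetric phase frame.

    Punctured plaquettes sharing an elementary grid cube are linked; within
    a cube holding more than two punctures, pairing is deterministic by
    lowest face index. Every chain is either closed or ends on the domain
    boundary.
    """
    if phase_frame.ndim != 3:
        raise ValueError("detect_filaments expects a 3-D phase frame")
    mask = domain.mask
    if mask.ndim != 3:
        raise ValueError("detect_filaments expects a 3-D domain")
    pts: list[FilamentPoint] = []
    # all-corners-inside test per plaquette, per orientation
    for axis in range(3):
        w = _plaquette_windings(phase_frame, axis)
        a1, a2 = [a for a in (0, 1, 2) if a != axis]

        def shm(d1, d2):
            sl = [slice(0, -1)] * 3
            sl[axis] = slice(None)
            sl[a1] = slice(1, None) if d1 else slice(0, -1)
            sl[a2] = slice(1, None) if d2 else slice(0, -1)
            return mask[tuple(sl)]

        ok = shm(0, 0) & shm(1, 0) & shm(1, 1) & shm(0, 1)
        w = np.where(ok, w, 0)
        for idx in np.argwhere(w != 0):
            pos = idx.astype(float)
            pos[a1] += 0.5
            pos[a2] += 0.5
            pts.append(FilamentPoint(position=tuple(pos), axis=axis,
                                     charge=int(w[tuple(idx)]),
                                     face_id=(axis, *map(int, idx))))
    return FilamentSet(filaments=_link_punctures(pts, domain), time=time)


def _cubes_of_face(p: FilamentPoint, shape3):
    """The one or two elementary cubes bounded by this plaquette.

    Cube (i,j,k) spans sites [i,i+1]x[j,j+1]x[k,k+1]; a plaquette normal to
    ``axis`` at slice s bounds cubes s-1 and s along that axis.
    """
    axis, *idx = p.face_id
    cubes = []
    for d in (-1, 0):
        c = list(idx)
        c[axis] += d
        if all(0 <= c[a] <= shape3[a] - 2 for a in range(3)):
            cubes.append(tuple(c))
    return cubes


def _link_punctures(pts: list, domain: Domain) -> list:
    """Pair punctures through shared cubes and trace the resulting chains."""
    shape3 = domain.shape
    by_cube: dict[tuple, list[int]] = {}
    boundary_end: list[bool] = []
    for n, p in enumerate(pts):
        cubes = _cubes_of_face(p, shape3)
        for c in cubes:
            by_cube.setdefault(c, []).append(n)
        # a puncture on the grid edge (single adjacent cube) is a boundary end
        boundary_end.append(len(cubes) < 2)
    # adjacency: within each cube, pair in-flux with out-flux punctures;
    # deterministic tie-break by face_id order
    adj: dict[int, list[int]] = {n: [] for n in range(len(pts))}
    for cube, members in sorted(by_cube.items()):
        if len(members) < 2:
            # the chain ends inside this cube only if the face is a mask
            # boundary; flag handled via endpoint labelling later
            continue
        members = sorted(members, key=lambda n: pts[n].face_id)
        # outward flux sign of each puncture w.r.t. this cube
        outs, ins = [], []
        for n in members:
            axis, *idx = pts[n].face_id
            on_high_side = idx[axis] == cube[axis] + 1
            flux = pts[n].charge * (1 if on_high_side else -1)
            (outs if flux > 0 else ins).append(n)
        for a, b in zip(ins, outs):
            adj[a].append(b)
            adj[b].append(a)
    # trace chains
    seen = set()
    filaments = []
    order = sorted(range(len(pts)), key=lambda n: (len(adj[n]) != 1, pts[n].face_id))
    for start in order:
        if start in seen:
            continue
        chain = [start]
        seen.add(start)
        closed = False
        while True:
            nxt = [n for n in adj[chain[-1]] if n not in seen]
            if not nxt:
                if chain[0] in adj[chain[-1]] and len(chain) > 2:
                    closed = True
                break
            chain.append(nxt[0])
            seen.add(nxt[0])
        if len(chain) > 1 and not closed:
            # extend from the start end if it was mid-chain
            while True:
                prv = [n for n in adj[chain[0]] if n not in seen]
                if not prv:
                    break
                chain.insert(0, prv[0])
                seen.add(prv[0])
        f_pts = [pts[n] for n in chain]
        labels = ("none", "none") if closed else (
            _endpoint_label(pts[chain[0]], domain),
            _endpoint_label(pts[chain[-1]], domain))
        filaments.append(Filament(points=f_pts, closed=closed,
                                  endpoint_labels=labels))
    return filaments


def _endpoint_label(p: FilamentPoint, domain: Domain) -> str:
    """Surface label nearest an open-filament endpoint."""
    if domain.surfaces is None:
        return "cut"
    axis, *idx = p.face_id
    a1, a2 = [a for a in (0, 1, 2) if a != axis]
    best = "cut"
    for d1 in (0, 1):
        for d2 in (0, 1):
            c = list(idx)
            c[a1] += d1
            c[a2] += d2
            c = tuple(np.clip(c, 0, np.array(domain.shape) - 1))
            lab = domain.surfaces[c]
            if lab == SURFACE_EPI:
                return "epi"
            if lab == SURFACE_ENDO:
                best = "endo"
    return best


def classify_filament(filament: Filament, domain: Domain) -> str:
    """Shape class: O (closed ring), linear-transmural (endpoints on
    opposite surface labels), U (both endpoints on the same label), else
    'other'."""
    if filament.closed:
        return "O"
    la, lb = filament.endpoint_labels
    if {la, lb} == {"epi", "endo"}:
        return "linear-transmural"
    if la == lb and la in ("epi", "endo"):
        return "U"
    return "other"


def count_series(movie, domain: Domain, label: str = "",
                 tau: float = 5.0, v_star: float = -40.0,
                 include_fragments: bool = True,
                 frame_step: int = 1) -> FilamentCountSeries:
    """Per-frame filament count of a volumetric movie.

    The phase of each voxel is computed by the same time-delay embedding as
    the surface maps; counts optionally exclude single-puncture fragments.
    ``frame_step`` subsamples the frames (counts every n-th frame).
    """
    interval = movie.interval
    k = int(round(tau / interval))
    if k < 1:
        raise ValueError("movie sampled more coarsely than tau")
    counts, times = [], []
    V = movie.frames
    for fi in range(0, len(V) - k, frame_step):
        ph = np.arctan2(V[fi + k] - np.float32(v_star),
                        V[fi] - np.float32(v_star))
        fs = detect_filaments(ph, domain, time=movie.times[fi])
        counts.append(fs.count if include_fragments
                      else fs.count_excluding_fragments())
        times.append(movie.times[fi])
    return FilamentCountSeries(times=np.asarray(times),
                               counts=np.asarray(counts), label=label)


def surface_phase_singularities(phase_frame: np.ndarray, domain: Domain,
                                axis: int = 2, side: str = "high"):
    """PS detections on one boundary layer of a 3-D phase frame (the
    surface facing +axis if side='high'). Used for the open-filament /
    surface-PS consistency check and shell surface maps."""
    sl = [slice(None)] * 3
    sl[axis] = -1 if side == "high" else 0
    from .phase import detect_phase_singularities

    layer_phase = phase_frame[tuple(sl)]
    layer_mask = domain.mask[tuple(sl)]
    return detect_phase_singularities(layer_phase, mask=layer_mask,
                                      spacing=domain.spacing)


def divergence(series_a: FilamentCountSeries, series_b: FilamentCountSeries,
               persist: float = 50.0):
    """Absolute count difference over the common time grid plus the first
    time the two series differ persistently (for longer than ``persist``
    ms); symmetric in its arguments.

    Returns ``(times, |a-b|, first_divergence_time_or_None)``.
    """
    t0 = max(series_a.times[0], series_b.times[0])
    t1 = min(series_a.times[-1], series_b.times[-1])
    if t1 <= t0:
        raise ValueError("series have disjoint time ranges")
    n = int(min(len(series_a.times), len(series_b.times)))
    t = np.linspace(t0, t1, n)
    ca = np.interp(t, series_a.times, series_a.counts)
    cb = np.interp(t, series_b.times, series_b.counts)
    d = np.abs(ca - cb)
    first = None
    dt = t[1] - t[0] if n > 1 else 0.0
    need = max(1, int(round(persist / dt))) if dt > 0 else 1
    nz = d > 0
    run = 0
    for i, flag in enumerate(nz):
        run = run + 1 if flag else 0
        if run >= need:
            first = float(t[i - run + 1])
            break
    return t, d, first
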