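"""Phase maps, phase-singularity detection and spiral-tip analysis.

Phase is built by time-delay state-space embedding of the voltage movie:
``phase(t) = atan2(V(t+tau) - V*, V(t) - V*)`` per site, with defaults
tau = 5 ms and V* = -40 mV. A phase singularity (PS, the spiral tip) is a
point where all phases converge; it is detected by its topological charge —
the winding of the phase around an elementary 2x2 plaquette of grid sites:
a wrapped loop sum of +/-2pi marks a PS of charge +/-1.

Tips are linked across frames by greedy nearest-neighbour matching to give
trajectories, from which meander extent (bounding box after a transient
discard) and the core area of stable rotors are measured; PS density uses
a 1.5 x 1.5 cm counting window, the convention in rabbit optical mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .solver import FieldMovie

__all__ = ["PhaseMovie", "TipTrajectory", "compute_phase",
           "detect_phase_singularities", "wrap_angle", "track_tips",
           "meander_extent", "core_area", "ps_density"]


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


@dataclass
class PhaseMovie:
    """Per-frame phase fields (radians, (-pi, pi]) on a 2-D grid."""

    times: np.ndarray
    frames: np.ndarray  # (n_t, nx, ny)
    spacing: float
    tau: float
    v_star: float
    mask: Optional[np.ndarray] = None

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class TipTrajectory:
    """One tracked phase singularity: times (ms), positions (cm), charge."""

    times: list = field(default_factory=list)
    positions: list = field(default_factory=list)  # (x, y) cm
    charge: int = 0

    @property
    def duration(self) -> float:
        return self.times[-1] - self.times[0] if len(self.times) > 1 else 0.0

    def xy(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=float)


def compute_phase(movie: FieldMovie, tau: float = 5.0,
                  v_star: float = -40.0) -> PhaseMovie:
    """Time-delay embedding phase of a (2-D) voltage movie.

    The final ``tau`` of the movie has no phase (no delayed sample).
    Raises if ``tau`` is below the snapshot interval.
    """
    if movie.frames.ndim != 3:
        raise ValueError("compute_phase expects a 2-D movie (frames (t, nx, ny))")
    interval = movie.interval
    if interval <= 0 or tau < interval:
        raise ValueError(f"tau={tau} ms must be >= snapshot interval {interval} ms")
    k = int(round(tau / interval))
    V = movie.frames  # keep the movie's dtype (float32 movies stay float32)
    ph = np.arctan2(V[k:] - np.float32(v_star), V[:-k] - np.float32(v_star))
    return PhaseMovie(times=movie.times[:-k], frames=ph, spacing=movie.spacing,
                      tau=k * interval, v_star=v_star)


def detect_phase_singularities(phase_frame: np.ndarray,
                               mask: Optional[np.ndarray] = None,
                               spacing: float = 1.0):
    """Detect phase singularities on a 2-D phase frame by topological charge.

    For every 2x2 plaquette of grid sites the wrapped phase differences are
    summed counter-clockwise around the loop; a total of +/-2pi marks a
    singularity of charge +/-1 at the plaquette centre. Returns a list of
    ``(x, y, charge)`` with positions in units of ``spacing`` (plaquette
    centres, i.e. offset by half a voxel from site coordinates).
    """
    p = np.asarray(phase_frame)
    if p.ndim != 2:
        raise ValueError("phase frame must be 2-D")
    d1 = wrap_angle(p[1:, :-1] - p[:-1, :-1])   # (i,j)   -> (i+1,j)
    d2 = wrap_angle(p[1:, 1:] - p[1:, :-1])     # (i+1,j) -> (i+1,j+1)
    d3 = wrap_angle(p[:-1, 1:] - p[1:, 1:])     # (i+1,j+1) -> (i,j+1)
    d4 = wrap_angle(p[:-1, :-1] - p[:-1, 1:])   # (i,j+1) -> (i,j)
    w = (d1 + d2 + d3 + d4) / (2 * np.pi)
    if mask is not None:
        ok = mask[1:, :-1] & mask[:-1, :-1] & mask[1:, 1:] & mask[:-1, 1:]
        w = np.where(ok, w, 0.0)
    out = []
    for i, j in zip(*np.nonzero(np.round(w) != 0)):
        out.append(((i + 0.5) * spacing, (j + 0.5) * spacing,
                    int(np.round(w[i, j]))))
    return out


def track_tips(pm: PhaseMovie, gate: float = 0.25,
               min_duration: float = 0.0) -> list[TipTrajectory]:
    """Link per-frame PS detections into trajectories by greedy
    nearest-neighbour matching with a distance gate (cm per frame);
    unmatched detections open new tracks (births), unmatched tracks close
    (deaths). With ``gate=0`` every detection is its own trajectory.
    """
    open_tracks: list[TipTrajectory] = []
    done: list[TipTrajectory] = []
    for t, frame in zip(pm.times, pm.frames):
        dets = detect_phase_singularities(frame, mask=pm.mask,
                                          spacing=pm.spacing)
        used = [False] * len(dets)
        still_open = []
        # greedy: globally closest (track, detection) pairs first
        pairs = []
        for ti, tr in enumerate(open_tracks):
            p0 = tr.positions[-1]
            for di, (x, y, q) in enumerate(dets):
                if q != tr.charge:
                    continue
                d = np.hypot(x - p0[0], y - p0[1])
                if d < gate:  # strict: gate 0 fragments every detection
                    pairs.append((d, ti, di))
        pairs.sort()
        matched_tracks = set()
        for d, ti, di in pairs:
            if ti in matched_tracks or used[di]:
                continue
            tr = open_tracks[ti]
            x, y, _q = dets[di]
            tr.times.append(float(t))
            tr.positions.append((x, y))
            matched_tracks.add(ti)
            used[di] = True
        for ti, tr in enumerate(open_tracks):
            (still_open if ti in matched_tracks else done).append(tr)
        for di, (x, y, q) in enumerate(dets):
            if not used[di]:
                still_open.append(TipTrajectory(times=[float(t)],
                                                positions=[(x, y)], charge=q))
        open_tracks = still_open
    done.extend(open_tracks)
    return [tr for tr in done if tr.duration >= min_duration]


def meander_extent(trajectory: TipTrajectory, discard: float = 200.0):
    """Axis-aligned bounding-box side lengths (cm) of the tip positions
    after discarding the initial transient (first ``discard`` ms of the
    track)."""
    t = np.asarray(trajectory.times)
    if t.size == 0 or t[-1] - t[0] <= discard:
        raise ValueError("trajectory shorter than the discard window")
    xy = trajectory.xy()[t >= t[0] + discard]
    ext = xy.max(axis=0) - xy.min(axis=0)
    return float(ext[0]), float(ext[1])


def core_area(trajectory: TipTrajectory, discard: float = 200.0,
              n_phase_bins: int = 64):
    """Area (cm^2) enclosed by one period of a stably rotating tip.

    The tip orbit is cycle-averaged: the angular position about the orbit
    centroid is unwrapped to estimate the rotation period, positions are
    binned by rotation phase, and the shoelace formula is applied to the
    bin-averaged loop. Non-periodic trajectories are flagged: the convex
    hull area is returned with ``periodic=False``.
    Returns ``(area, periodic)``.
    """
    from scipy.spatial import ConvexHull

    t = np.asarray(trajectory.times)
    xy = trajectory.xy()
    sel = t >= t[0] + min(discard, max(0.0, (t[-1] - t[0]) - 100.0))
    xy = xy[sel]
    if len(xy) < 8 or np.ptp(xy, axis=0).max() < 1e-9:
        return 0.0, True  # degenerate / stationary tip
    c = xy.mean(axis=0)
    ang = np.unwrap(np.arctan2(xy[:, 1] - c[1], xy[:, 0] - c[0]))
    total_turns = abs(ang[-1] - ang[0]) / (2 * np.pi)
    if total_turns < 2.0:
        try:
            return float(ConvexHull(xy).volume), False
        except Exception:
            return 0.0, False
    bins = ((ang % (2 * np.pi)) / (2 * np.pi) * n_phase_bins).astype(int)
    loop = np.array([xy[bins == b].mean(axis=0)
                     for b in range(n_phase_bins) if np.any(bins == b)])
    x, y = loop[:, 0], loop[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area), True


def ps_density(pm: PhaseMovie, window_cm: float = 1.5,
               t_window: Optional[tuple[float, float]] = None,
               origin_cm: Optional[tuple[float, float]] = None):
    """Mean PS count inside a square window divided by its area (PS/cm^2),
    averaged over frames in ``t_window``; the conventional window is
    1.5 x 1.5 cm (area 2.25 cm^2) on the posterior epicardial surface.

    Returns ``(density, per_frame_counts, times)``.
    """
    extent = ((np.array(pm.frames.shape[1:]) - 1) * pm.spacing)
    if window_cm > min(extent) + 1e-9:
        raise ValueError(f"{window_cm} cm window exceeds surface extent {extent}")
    if origin_cm is None:
        origin_cm = tuple(0.5 * (extent - window_cm))
    x0, y0 = origin_cm
    sel = np.ones(pm.n_frames, dtype=bool)
    if t_window is not None:
        sel = (pm.times >= t_window[0]) & (pm.times <= t_window[1])
    counts = []
    for frame in pm.frames[sel]:
        dets = detect_phase_singularities(frame, mask=pm.mask,
                                          spacing=pm.spacing)
        counts.append(sum(1 for (x, y, _q) in dets
                          if x0 <= x <= x0 + window_cm
                          and y0 <= y <= y0 + window_cm))
    counts = np.asarray(counts)
    dens = counts.mean() / window_cm ** 2 if counts.size else 0.0
    return float(dens), counts, pm.times[sel]
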