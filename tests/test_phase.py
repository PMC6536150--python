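"""Phase mapping, phase-singularity detection and tip analysis."""

import numpy as np
import pytest

from fibwave.phase import (PhaseMovie, TipTrajectory, compute_phase, core_area,
                           detect_phase_singularities, meander_extent,
                           ps_density, track_tips, wrap_angle)
from fibwave.solver import FieldMovie


def boundary_winding(phase: np.ndarray) -> int:
    """Independent oracle: wrapped phase integral along the outer boundary
    of the frame (counter-clockwise), in units of 2*pi."""
    p = phase
    loop = np.concatenate([p[:, 0], p[-1, 1:], p[-2::-1, -1], p[0, -2::-1]])
    return int(np.round(wrap_angle(np.diff(loop)).sum() / (2 * np.pi)))


def rotor_phase(n, centers_charges, spacing=1.0, smooth=None):
    """Constructed phase field: sum of q_i * angle(r - r_i) plus an optional
    smooth single-valued field."""
    x = np.arange(n)[:, None] * spacing
    y = np.arange(n)[None, :] * spacing
    ph = np.zeros((n, n))
    for (cx, cy, q) in centers_charges:
        ph = ph + q * np.arctan2(y - cy, x - cx)
    if smooth is not None:
        ph = ph + smooth
    return wrap_angle(ph)


def rotor_movie(n=40, frames=30, omega=2 * np.pi / 20, v_star=-40.0,
                center=None, spacing=0.05):
    """Voltage movie of a rigidly rotating spiral-like pattern whose
    time-delay phase is exactly the rotor angle when omega*tau = pi/2.
    The centre is kept off the lattice sites (a singularity exactly on a
    site makes the four surrounding plaquettes degenerate)."""
    cx, cy = center if center is not None else ((n - 1) / 2 + 0.3,
                                                (n - 1) / 2 - 0.2)
    x = np.arange(n)[:, None]
    y = np.arange(n)[None, :]
    theta = np.arctan2(y - cy, x - cx)
    t = np.arange(frames)[:, None, None]
    V = v_star + 30.0 * np.cos(theta[None] - omega * t)
    return FieldMovie(times=np.arange(frames, dtype=float), frames=V,
                      spacing=spacing)


class TestComputePhase:
    def test_constant_offset_gives_quarter_pi(self):
        mv = FieldMovie(times=np.arange(10.0),
                        frames=np.full((10, 8, 8), -30.0), spacing=0.1)
        pm = compute_phase(mv, tau=2.0, v_star=-40.0)
        np.testing.assert_allclose(pm.frames, np.pi / 4, atol=1e-7)
        assert pm.n_frames == 8  # trailing tau has no phase

    def test_tau_below_interval_rejected(self):
        mv = FieldMovie(times=np.arange(0.0, 10.0, 2.0),
                        frames=np.zeros((5, 4, 4)), spacing=0.1)
        with pytest.raises(ValueError):
            compute_phase(mv, tau=1.0)

    def test_shift_invariance_requires_matched_origin(self):
        mv = rotor_movie()
        pm = compute_phase(mv, tau=5.0, v_star=-40.0)
        shifted = FieldMovie(times=mv.times, frames=mv.frames + 10.0,
                             spacing=mv.spacing)
        pm2 = compute_phase(shifted, tau=5.0, v_star=-30.0)
        np.testing.assert_allclose(pm.frames, pm2.frames, atol=1e-5)

    def test_rotor_movie_winds_once_every_frame(self):
        mv = rotor_movie(omega=2 * np.pi / 20)
        pm = compute_phase(mv, tau=5.0)  # omega*tau = pi/2
        for fr in pm.frames:
            assert boundary_winding(fr) == 1


class TestDetector:
    def test_uniform_phase_empty(self):
        assert detect_phase_singularities(np.zeros((20, 20))) == []

    def test_single_rotor_found_at_centre(self):
        ph = rotor_phase(41, [(20.3, 19.6, +1)])
        dets = detect_phase_singularities(ph, spacing=1.0)
        assert len(dets) == 1
        x, y, q = dets[0]
        assert q == 1
        assert abs(x - 20.3) <= 1.0 and abs(y - 19.6) <= 1.0

    def test_charge_matches_boundary_winding_oracle(self):
        """Summed detector charges equal the brute-force boundary integral
        on 100+ random fields with implanted rotor pairs."""
        rng = np.random.default_rng(42)
        n = 36
        for trial in range(120):
            k = rng.integers(0, 4)
            ccs = [(rng.uniform(4, n - 5), rng.uniform(4, n - 5),
                    int(rng.choice([-1, 1]))) for _ in range(k)]
            # smooth single-valued background
            gx, gy = rng.normal(0, 0.06, 2)
            x = np.arange(n)[:, None]
            y = np.arange(n)[None, :]
            smooth = gx * x + gy * y + rng.normal(0, 0.5) * np.sin(
                2 * np.pi * (x + 2 * y) / n)
            ph = rotor_phase(n, ccs, smooth=smooth)
            dets = detect_phase_singularities(ph)
            assert sum(q for *_xy, q in dets) == boundary_winding(ph)

    def test_mask_excludes_outside_plaquettes(self):
        ph = rotor_phase(21, [(10.2, 10.2, +1)])
        mask = np.zeros((21, 21), dtype=bool)
        mask[:5, :5] = True  # rotor centre outside the mask
        assert detect_phase_singularities(ph, mask=mask) == []


class TestTracking:
    def test_single_rotor_single_unbroken_track(self):
        pm = compute_phase(rotor_movie(), tau=5.0)
        tracks = track_tips(pm)
        long = [t for t in tracks if len(t.times) == pm.n_frames]
        assert len(long) == 1

    def test_two_rotors_two_tracks_no_swap(self):
        n, frames = 60, 25
        cx = [(15, 15), (45, 45)]
        x = np.arange(n)[:, None]
        y = np.arange(n)[None, :]
        th = sum(np.arctan2(y - c[1], x - c[0]) for c in cx)
        t = np.arange(frames)[:, None, None]
        omega = 2 * np.pi / 20
        V = -40 + 30 * np.cos(th[None] - omega * t)
        mv = FieldMovie(times=np.arange(frames, dtype=float), frames=V,
                        spacing=0.05)
        pm = compute_phase(mv, tau=5.0)
        tracks = [t for t in track_tips(pm) if len(t.times) == pm.n_frames]
        assert len(tracks) == 2
        for tr in tracks:
            xy = tr.xy()
            assert np.ptp(xy, axis=0).max() < 0.3  # stays near its rotor

    def test_zero_gate_fragments_every_detection(self):
        pm = compute_phase(rotor_movie(frames=12), tau=5.0)
        tracks = track_tips(pm, gate=0.0)
        assert all(len(t.times) == 1 for t in tracks)


class TestMeanderAndCore:
    def make_traj(self, t, x, y, q=1):
        return TipTrajectory(times=list(t), positions=list(zip(x, y)), charge=q)

    def test_stationary_tip_zero_box(self):
        t = np.arange(0, 500.0)
        tr = self.make_traj(t, np.full_like(t, 1.0), np.full_like(t, 2.0))
        assert meander_extent(tr, discard=200.0) == (0.0, 0.0)

    def test_circular_orbit_box_is_diameter(self):
        t = np.arange(0, 1000.0)
        r = 0.3
        tr = self.make_traj(t, 1 + r * np.cos(t / 30), 1 + r * np.sin(t / 30))
        ext = meander_extent(tr, discard=200.0)
        assert ext[0] == pytest.approx(2 * r, rel=1e-3)
        assert ext[1] == pytest.approx(2 * r, rel=1e-3)

    def test_short_trajectory_rejected(self):
        tr = self.make_traj(np.arange(0, 100.0), np.zeros(100), np.zeros(100))
        with pytest.raises(ValueError):
            meander_extent(tr, discard=200.0)

    def test_circle_core_area(self):
        t = np.arange(0, 1200.0)
        r = 0.0564  # pi r^2 = 0.01 cm^2
        tr = self.make_traj(t, r * np.cos(t / 25), r * np.sin(t / 25))
        area, periodic = core_area(tr)
        assert periodic
        assert area == pytest.approx(np.pi * r ** 2, rel=0.02)

    def test_degenerate_point_zero(self):
        t = np.arange(0, 400.0)
        area, periodic = core_area(self.make_traj(t, np.zeros_like(t),
                                                  np.zeros_like(t)))
        assert area == 0.0 and periodic

    def test_nonperiodic_flagged(self):
        t = np.arange(0, 600.0)
        area, periodic = core_area(self.make_traj(t, t * 1e-3, t * 2e-3))
        assert not periodic
        assert area >= 0.0


class TestPsDensity:
    def test_quiescent_zero(self):
        mv = FieldMovie(times=np.arange(20.0),
                        frames=np.full((20, 50, 50), -83.0), spacing=0.05)
        pm = compute_phase(mv, tau=5.0)
        dens, counts, _ = ps_density(pm, window_cm=1.5)
        assert dens == 0.0 and counts.sum() == 0

    def test_single_centered_rotor_density(self):
        mv = rotor_movie(n=61, spacing=0.05)  # 3 cm surface, rotor centred
        pm = compute_phase(mv, tau=5.0)
        dens, counts, _ = ps_density(pm, window_cm=1.5)
        assert (counts == 1).all()
        assert dens == pytest.approx(1 / 2.25, rel=1e-6)

    def test_rotor_outside_window_not_counted(self):
        mv = rotor_movie(n=61, spacing=0.05, center=(5.0, 5.0))
        pm = compute_phase(mv, tau=5.0)
        dens, counts, _ = ps_density(pm, window_cm=1.5)
        assert dens == 0.0

    def test_window_exceeding_surface_rejected(self):
        mv = rotor_movie(n=21, spacing=0.05)  # 1 cm surface
        pm = compute_phase(mv, tau=5.0)
        with pytest.raises(ValueError):
            ps_density(pm, window_cm=1.5)
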