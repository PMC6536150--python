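"""Scroll-wave filament detection, linking, classification, divergence."""

import numpy as np
import pytest

from fibwave.filaments import (FilamentCountSeries, classify_filament,
                               count_series, detect_filaments, divergence,
                               surface_phase_singularities,
                               _plaquette_windings)
from fibwave.geometry import make_slab
from fibwave.phase import wrap_angle
from fibwave.solver import FieldMovie


@pytest.fixture(scope="module")
def slab():
    # 1 x 1 x 0.4 cm slab; z=0 endo, z=top epi
    return make_slab((1.0, 1.0, 0.4), 0.05)


def transmural_scroll_phase(shape, cx=9.7, cy=10.2):
    """Rotor phase extruded along z: a straight transmural filament."""
    nx, ny, nz = shape
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    ph = np.arctan2(y - cy, x - cx)
    return wrap_angle(np.repeat(ph[:, :, None], nz, axis=2))


def ring_phase(shape, R=5.0, z0=None, cx=None, cy=None):
    """Phase winding around a horizontal circular core: an O filament."""
    nx, ny, nz = shape
    cx = (nx - 1) / 2 if cx is None else cx
    cy = (ny - 1) / 2 if cy is None else cy
    z0 = (nz - 1) / 2 if z0 is None else z0
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    rho = np.hypot(x - cx, y - cy)
    return wrap_angle(np.arctan2(z - z0, rho - R))


class TestDetect:
    def test_quiescent_frame_empty(self, slab):
        fs = detect_filaments(np.zeros(slab.shape), slab)
        assert fs.count == 0

    def test_transmural_scroll_single_open_filament(self, slab):
        ph = transmural_scroll_phase(slab.shape)
        fs = detect_filaments(ph, slab)
        assert fs.count == 1
        f = fs.filaments[0]
        assert not f.closed
        assert set(f.endpoint_labels) == {"epi", "endo"}
        assert classify_filament(f, slab) == "linear-transmural"
        # spiral visible on both surfaces
        for side in ("low", "high"):
            dets = surface_phase_singularities(ph, slab, axis=2, side=side)
            assert len(dets) == 1

    def test_ring_rotor_single_closed_filament(self, slab):
        ph = ring_phase(slab.shape, R=5.0)
        fs = detect_filaments(ph, slab)
        assert fs.count == 1
        f = fs.filaments[0]
        assert f.closed
        assert classify_filament(f, slab) == "O"
        for side in ("low", "high"):
            assert surface_phase_singularities(ph, slab, axis=2,
                                               side=side) == []

    def test_face_charge_conservation(self, slab):
        """Outward winding summed over the six faces of every elementary
        cube vanishes - a filament entering a cube must leave it."""
        rng = np.random.default_rng(5)
        nx, ny, nz = slab.shape
        x = np.arange(nx)[:, None, None]
        y = np.arange(ny)[None, :, None]
        smooth = 0.2 * np.sin(2 * np.pi * x / nx) + 0.15 * y * 2 * np.pi / ny
        ph = wrap_angle(transmural_scroll_phase(slab.shape) + smooth
                        + rng.normal(0, 0.2, slab.shape))
        wx = _plaquette_windings(ph, 0)
        wy = _plaquette_windings(ph, 1)
        wz = _plaquette_windings(ph, 2)
        # all three difference arrays align on the (nx-1, ny-1, nz-1) cube grid
        net = (np.diff(wx, axis=0) + np.diff(wy, axis=1)
               + np.diff(wz, axis=2))
        assert np.abs(net).max() == 0

    def test_endpoints_on_boundary(self, slab):
        ph = transmural_scroll_phase(slab.shape)
        fs = detect_filaments(ph, slab)
        nz = slab.shape[2]
        for f in fs.filaments:
            if not f.closed:
                zs = [p.position[2] for p in (f.points[0], f.points[-1])]
                assert min(zs) < 1.0 and max(zs) > nz - 2.0

    def test_deterministic(self, slab):
        ph = ring_phase(slab.shape)
        a = detect_filaments(ph, slab)
        b = detect_filaments(ph, slab)
        assert a.count == b.count
        for fa, fb in zip(a.filaments, b.filaments):
            assert [p.face_id for p in fa.points] == [p.face_id for p in fb.points]


class TestClassify:
    def test_u_shape_both_ends_same_surface(self, slab):
        """A half-ring crossing the epicardial surface: both endpoints on
        the top face."""
        nz = slab.shape[2]
        ph = ring_phase(slab.shape, R=4.0, z0=nz - 1.0)  # core centred at top
        fs = detect_filaments(ph, slab)
        open_fs = [f for f in fs.filaments if not f.closed and len(f) > 2]
        assert open_fs
        assert any(classify_filament(f, slab) == "U" for f in open_fs)


class TestCountSeries:
    def test_stable_scroll_constant_count(self, slab):
        nx, ny, nz = slab.shape
        x = np.arange(nx)[:, None, None]
        y = np.arange(ny)[None, :, None]
        theta = np.arctan2(y - (ny - 1) / 2, x - (nx - 1) / 2)
        theta = np.repeat(theta, nz, axis=2)
        omega = 2 * np.pi / 20
        t = np.arange(30)[:, None, None, None]
        V = -40 + 30 * np.cos(theta[None] - omega * t)
        mv = FieldMovie(times=np.arange(30.0), frames=V, spacing=slab.spacing)
        cs = count_series(mv, slab, label="scroll")
        assert (cs.counts == 1).all()

    def test_quiescent_tail_detected(self, slab):
        nx, ny, nz = slab.shape
        V = np.full((30, nx, ny, nz), -83.0)
        mv = FieldMovie(times=np.arange(30.0), frames=V, spacing=slab.spacing)
        cs = count_series(mv, slab)
        assert (cs.counts == 0).all()

    def test_windowed_mean_and_label(self):
        cs = FilamentCountSeries(times=np.arange(10.0),
                                 counts=np.array([0, 0, 1, 2, 3, 3, 3, 2, 1, 0]),
                                 label="P2_I_nS")
        assert cs.windowed_mean(4, 6) == pytest.approx(3.0)
        assert cs.label == "P2_I_nS"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            FilamentCountSeries(times=np.arange(3.0),
                                counts=np.array([0, -1, 0]))


class TestDivergence:
    def mk(self, counts):
        return FilamentCountSeries(times=np.arange(len(counts), dtype=float),
                                   counts=np.asarray(counts))

    def test_identical_series_zero(self):
        a = self.mk([1, 2, 3, 2, 1] * 40)
        t, d, first = divergence(a, self.mk([1, 2, 3, 2, 1] * 40))
        assert (d == 0).all() and first is None

    def test_first_divergence_time(self):
        base = np.ones(2000)
        other = base.copy()
        other[1500:] = 3
        t, d, first = divergence(self.mk(base), self.mk(other), persist=50.0)
        assert first == pytest.approx(1500.0, abs=2.0)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = self.mk(rng.integers(0, 5, 500))
        b = self.mk(rng.integers(0, 5, 500))
        _, da, fa = divergence(a, b)
        _, db, fb = divergence(b, a)
        np.testing.assert_array_equal(da, db)
        assert fa == fb

    def test_disjoint_ranges_rejected(self):
        a = FilamentCountSeries(times=np.arange(0.0, 10.0), counts=np.ones(10))
        b = FilamentCountSeries(times=np.arange(20.0, 30.0), counts=np.ones(10))
        with pytest.raises(ValueError):
            divergence(a, b)
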