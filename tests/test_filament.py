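"""Filament extraction and tip-trace analytics against analytic oracles."""
import numpy as np
import pytest

from atriadrift.errors import AnalysisError
from atriadrift.filament import (Filament, TipTrace, average_tip_trace,
                                 classify_drift, core_diameter,
                                 extract_filament, rotation_period, tips)
from atriadrift.geometry import VoxelGeometry

DX = 0.33


def _slab(nx=21, ny=21, nz=10):
    mask = np.ones((nx, ny, nz), bool)
    epi = np.zeros_like(mask)
    epi[:, :, 0] = True
    return VoxelGeometry(mask, dx=DX, epi=epi)


def _linear_fields(geom, x0, y0, slope=1.0):
    nx, ny, nz = geom.shape
    x = np.arange(nx)[:, None, None] * DX
    y = np.arange(ny)[None, :, None] * DX
    V = -50.0 + slope * (x - x0) + np.zeros((1, 1, nz))
    O = 0.5 + slope * (y - y0) + np.zeros((1, 1, nz))
    return np.broadcast_to(V, geom.shape).copy(), \
        np.broadcast_to(O, geom.shape).copy()


class TestExtract:
    def test_analytic_line_recovery(self):
        """Two linear fields intersect on a vertical line; every extracted
        point must lie within one voxel of it."""
        g = _slab()
        x0, y0 = 3.14, 2.41
        V, O = _linear_fields(g, x0, y0)
        fil = extract_filament(V, O, g)
        assert fil.n_points >= g.shape[2] - 1
        pts = np.vstack(fil.polylines)
        err = np.hypot(pts[:, 0] - x0, pts[:, 1] - y0)
        assert err.max() < DX
        # transmural: spans essentially the whole wall
        assert np.ptp(pts[:, 2]) >= (g.shape[2] - 2) * DX

    def test_swapped_fields_same_line(self):
        """The intersection is symmetric in its two fields: exchanging them
        (rescaled to each other's iso level) yields the same line."""
        g = _slab()
        V, O = _linear_fields(g, 3.14, 2.41)
        f1 = extract_filament(V, O, g)
        Vs = (O - 0.5) - 50.0        # oi field rescaled to the -50 mV level
        Os = (V + 50.0) + 0.5        # V field rescaled to the 0.5 level
        f2 = extract_filament(Vs, Os, g)
        p1 = np.vstack(f1.polylines)
        p2 = np.vstack(f2.polylines)
        p1 = p1[np.argsort(p1[:, 2])]
        p2 = p2[np.argsort(p2[:, 2])]
        assert p1.shape == p2.shape
        assert np.allclose(p1, p2, atol=1e-9)

    def test_empty_when_no_crossing(self):
        g = _slab()
        V = np.full(g.shape, -20.0)
        O = np.full(g.shape, 0.7)
        assert extract_filament(V, O, g).n_points == 0

    def test_mirror_symmetry(self):
        """Mirroring both fields in x mirrors the filament."""
        g = _slab()
        V, O = _linear_fields(g, 3.14, 2.41)
        f1 = np.vstack(extract_filament(V, O, g).polylines)
        f2 = np.vstack(extract_filament(V[::-1], O[::-1], g).polylines)
        Lx = (g.shape[0] - 1) * DX
        assert np.allclose(sorted(f1[:, 0]), sorted(Lx - f2[:, 0]), atol=1e-9)


class TestTips:
    def test_transmural_filament_single_epi_tip(self):
        g = _slab()
        V, O = _linear_fields(g, 3.14, 2.41)
        fil = extract_filament(V, O, g)
        tp = tips(fil, g)
        assert tp.shape[0] == 1
        assert tp[0, 2] == pytest.approx(0.0, abs=DX)     # epi face z = 0
        assert tp[0, 0] == pytest.approx(3.14, abs=DX)
        assert tp[0, 1] == pytest.approx(2.41, abs=DX)

    def test_closed_loop_no_tips(self):
        g = _slab()
        ring = np.array([[1, 1, 1], [2, 1, 1], [2, 2, 1], [1, 2, 1],
                         [1, 1, 1]]) * DX
        fil = Filament(time=0.0, polylines=[ring.astype(float)])
        assert tips(fil, g).shape[0] == 0


def _circle_trace(freq_hz=9.43, radius=4.0, n=120, dt=10.0, drift=0.0,
                  centre=(10.0, 10.0)):
    t = np.arange(n) * dt
    w = 2 * np.pi * freq_hz / 1000.0
    x = centre[0] + radius * np.cos(w * t) + drift * t / 1000.0
    y = centre[1] + radius * np.sin(w * t)
    z = np.zeros(n)
    return TipTrace(t=t, xyz=np.column_stack([x, y, z]))


class TestRotationPeriod:
    def test_synthetic_circle(self):
        tr = _circle_trace(freq_hz=9.43)
        assert rotation_period(tr) == pytest.approx(106.0, abs=2.0)

    def test_stationary_raises(self):
        tr = TipTrace(t=np.arange(50) * 10.0,
                      xyz=np.tile([5.0, 5.0, 0.0], (50, 1)))
        with pytest.raises(AnalysisError):
            rotation_period(tr)

    def test_too_little_data_raises(self):
        tr = _circle_trace(n=6)
        with pytest.raises(AnalysisError):
            rotation_period(tr)


class TestAveraging:
    def test_circle_collapses_to_centre(self):
        tr = _circle_trace()
        tr = average_tip_trace(tr, 106.0)
        d = np.linalg.norm(tr.avg_xyz - [10.0, 10.0, 0.0], axis=1)
        assert d.max() < 0.5

    def test_translating_circle_recovers_drift(self):
        tr = _circle_trace(drift=2.0, n=400)           # 2 mm/s in x
        tr = average_tip_trace(tr, 106.0)
        dx_dt = np.polyfit(tr.avg_t, tr.avg_xyz[:, 0], 1)[0] * 1000.0
        assert dx_dt == pytest.approx(2.0, rel=0.05)
        assert np.ptp(tr.avg_xyz[:, 1]) < 0.5

    def test_single_window(self):
        tr = _circle_trace(n=10)
        tr = average_tip_trace(tr, 106.0)
        assert tr.avg_xyz.shape[0] == 1


class TestClassify:
    def test_fixed_point_stationary(self):
        tr = _circle_trace(n=400)
        tr = average_tip_trace(tr, 106.0)
        tr = classify_drift(tr)
        assert tr.classification == "stationary"

    def test_linear_drift_over_40s(self):
        """0.5 mm/s for 40 s = 20 mm > the 10 mm criterion."""
        tr = _circle_trace(drift=0.5, n=4000)
        tr = average_tip_trace(tr, 106.0)
        tr = classify_drift(tr)
        assert tr.classification == "drifting"
        assert tr.displacement == pytest.approx(20.0, rel=0.05)

    def test_scattered_motion_excluded(self):
        rng = np.random.default_rng(7)
        n = 2000
        t = np.arange(n) * 10.0
        steps = rng.normal(scale=1.2, size=(n, 3))
        steps[:, 2] = 0.0
        xyz = np.cumsum(steps, axis=0)
        xyz -= xyz[0]
        xyz[-1] = xyz[0] + [14.0, 0.0, 0.0]   # large net jump, huge path
        tr = TipTrace(t=t, xyz=xyz)
        tr = average_tip_trace(tr, 106.0)
        tr = classify_drift(tr)
        assert tr.classification in ("excluded", "stationary")


class TestCoreDiameter:
    def test_synthetic_circle_diameter(self):
        tr = _circle_trace(radius=4.0, n=300)
        assert core_diameter(tr) == pytest.approx(8.0, rel=0.02)

    def test_single_point_zero(self):
        tr = TipTrace(t=np.array([0.0]), xyz=np.array([[1.0, 2.0, 0.0]]))
        assert core_diameter(tr) == 0.0

    def test_no_data_raises(self):
        tr = TipTrace(t=np.empty(0), xyz=np.empty((0, 3)))
        with pytest.raises(AnalysisError):
            core_diameter(tr)
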