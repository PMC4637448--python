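"""Single-cell CRN model: I_KACh formulas, integration, AP metrics."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriadrift import constants as c
from atriadrift.cell_model import (CellState, RemodelParams, apd90, currents,
                                   ikach_current, ikach_open, ikach_terms,
                                   ikach_voltage, pace_to_steady,
                                   resting_state, step_cell, total_current)
from atriadrift.errors import AnalysisError, StimulusError


class TestIKAch:
    @pytest.mark.parametrize("ach,expected,tol", [
        (0.0, 0.0, 0.0),                 # limit convention at zero ACh
        (1e12, 10.0, 1e-3),              # saturation
        (0.0035, 0.07331, 5e-4),         # scalar evaluation oracle
    ])
    def test_open_examples(self, ach, expected, tol):
        assert ikach_open(ach) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("v,expected,tol", [
        (-59.53, 0.277, 1e-9),           # sigmoid midpoint: 0.052 + 0.45/2
        (1e4, 0.052, 1e-6),              # depolarised limit
        (-80.0, 0.39707, 5e-4),          # scalar evaluation oracle
    ])
    def test_voltage_examples(self, v, expected, tol):
        assert ikach_voltage(v) == pytest.approx(expected, abs=tol)

    def test_open_rejects_negative(self):
        with pytest.raises(ValueError):
            ikach_open(-0.1)

    @given(st.floats(1e-6, 10.0), st.floats(1e-6, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_open_monotone_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert ikach_open(lo) <= ikach_open(hi)

    @given(st.floats(-100.0, 60.0), st.floats(-100.0, 60.0))
    @settings(max_examples=50, deadline=None)
    def test_voltage_monotone_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert ikach_voltage(lo) >= ikach_voltage(hi)
        assert 0.052 < ikach_voltage(a) < 0.502

    def test_current_zero_at_reversal(self):
        p = RemodelParams()
        s = resting_state()
        ek = c.RTF * math.log(c.K_O / s.K_i)
        s.V = ek
        assert ikach_current(s, p) == pytest.approx(0.0, abs=1e-12)

    def test_current_zero_without_ach(self):
        s = resting_state()
        assert ikach_current(s, RemodelParams(ach=0.0)) == 0.0

    def test_current_composes_scalar_oracles(self):
        p = RemodelParams()
        s = resting_state()
        s.V = -80.0
        terms = ikach_terms(s, p)
        expect = p.Cm * ikach_open(0.0035) * ikach_voltage(-80.0) * (-80.0 - terms.E_k)
        assert terms.I_KAch == pytest.approx(expect, rel=1e-12)
        assert np.sign(terms.I_KAch) == np.sign(-80.0 - terms.E_k)


class TestTotalCurrent:
    def test_quiescence_control(self):
        """At the published resting state the control model carries ~no net
        current and stays quiescent for a second."""
        p = RemodelParams.control()
        s0 = resting_state()
        assert abs(total_current(s0, p)) / p.Cm < 0.01   # |dV/dt| mV/ms
        s1 = step_cell(s0, dt=0.01, params=p, n_steps=100_000)
        assert abs(s1.V - s0.V) < 0.1

    def test_plateau_cal_scaling(self):
        """At V = 0 the remodelled L-type current is exactly 0.35x control."""
        s = resting_state()
        s.V = 0.0
        i_ctrl = currents(s, RemodelParams.control())["I_CaL"]
        i_remod = currents(s, RemodelParams())["I_CaL"]
        assert i_remod == pytest.approx(0.35 * i_ctrl, rel=1e-12)

    def test_remodelled_kach_vanishes_at_ek(self):
        p = RemodelParams()
        s = resting_state()
        s.V = c.RTF * math.log(c.K_O / s.K_i)
        assert currents(s, p)["I_KACh"] == pytest.approx(0.0, abs=1e-12)


class TestStepCell:
    @given(st.lists(st.floats(0.0, 1.0), min_size=15, max_size=15),
           st.floats(-90.0, 30.0))
    @settings(max_examples=25, deadline=None)
    def test_gates_stay_bounded(self, gates, v):
        """Rush-Larsen is a convex move toward the steady state: gates that
        start inside [0, 1] remain inside after stepping (checked through the
        raw kernel so extreme non-physiological V excursions do not mask the
        gate property)."""
        from atriadrift.cell_model import _advance

        names = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
                 "d", "f", "fca", "u", "v", "w")
        s = resting_state()
        s.V = v
        for n, g in zip(names, gates):
            setattr(s, n, g)
        S = s.to_array()
        _advance(S, RemodelParams(), 0.01, 20, 0.0, np.zeros(1),
                 np.zeros((6, 1)), np.full(1, -np.inf))
        for row in range(1, 16):
            assert 0.0 <= S[row, 0] <= 1.0

    def test_rush_larsen_decay_toward_zero(self):
        """A gate relaxing to steady state ~0 decays without undershoot."""
        s = resting_state()
        s.d = 0.9        # d_inf(-81 mV) ~ 0; pure exponential decay
        prev = s.d
        for _ in range(50):
            s = step_cell(s, dt=0.01, params=RemodelParams.control())
            assert 0.0 <= s.d <= prev
            prev = s.d

    def test_step_halving_apd_convergence(self, study_params):
        a1 = pace_to_steady(study_params, bcl=300.0, n_beats=6, dt=0.01).apd90
        a2 = pace_to_steady(study_params, bcl=300.0, n_beats=6, dt=0.005).apd90
        assert abs(a1 - a2) < 1.0

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            step_cell(resting_state(), dt=0.0)


class TestPacing:
    def test_control_resting_potential(self, control_beat):
        assert control_beat.terminal.V == pytest.approx(-81.2, abs=1.0)

    def test_steadiness_of_final_beats(self, remodelled_beat):
        h = remodelled_beat.apd90_history
        assert abs(h[-1] - h[-2]) < 1.0

    def test_no_ap_raises(self, study_params):
        with pytest.raises(StimulusError):
            pace_to_steady(study_params, bcl=300.0, n_beats=2, stim_pA=-1.0)

    def test_single_beat_is_one_ap(self, study_params):
        beat = pace_to_steady(study_params, bcl=300.0, n_beats=1)
        assert np.max(beat.V) > 0
        assert beat.apd90 > 10


class TestApd90:
    def test_triangle_analytic(self):
        """Symmetric triangular pulse -80 -> +20 -> -80 over 200 ms:
        90 % repolarisation at 190 ms from the upstroke."""
        t = np.arange(0.0, 200.5, 0.5)
        v = np.where(t <= 100.0, -80.0 + t, 20.0 - (t - 100.0))
        assert apd90(v, 0.5) == pytest.approx(190.0, abs=0.51)

    def test_flat_trace_raises(self):
        with pytest.raises(AnalysisError):
            apd90(np.full(1000, -80.0), 0.5)
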