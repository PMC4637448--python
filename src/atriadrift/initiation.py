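"""Scroll-wave initiation by the phase-distribution method.

A cell is paced to a steady oscillation; those states pace a 1D strand; the
full state cycle recorded mid-strand during one steady propagating pulse forms
a phase-indexed library.  Each voxel of the target geometry is then assigned
the library state at a phase given by an Archimedean-spiral phase map

    phi(r, theta) = frac(s * theta / 2pi + r / lambda),

with s = +1 (anticlockwise) or -1 (clockwise) and pitch lambda, evaluated in
the plane tangent to the wall at the prescribed centre and held constant
through the wall thickness (transmural extension), which seeds a single
transmural filament at the centre.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as c
from .cell_model import RemodelParams, apd90, pace_to_steady
from .errors import ProtocolError
from .geometry import VoxelGeometry, build_strand1d
from .tissue_solver import FieldState, SolverConfig, build_weights, run, uniform_state

__all__ = ["CycleLibrary", "SpiralSpec", "record_cycle", "archimedean_phase",
           "apply_phase_distribution"]


@dataclass
class CycleLibrary:
    """Time-ordered full cell states over one steady propagating pulse.

    ``states`` is (21, L) sampled every ``dt_lib`` ms over one pacing period
    ``period``; index 0 is the upstroke sample (phase gauge phi = 0).
    """

    states: np.ndarray
    dt_lib: float
    period: float
    cv: float = np.nan            # mm/ms measured on the recording strand
    closure: float = np.nan       # mV, |V(cycle start) - V(one period later)|

    def __post_init__(self):
        if self.states.shape[0] != c.N_STATE:
            raise ValueError("library states must have 21 rows")
        if self.states.shape[1] < 100:
            raise ValueError("library must contain >= 100 samples")

    @property
    def length(self) -> int:
        return self.states.shape[1]

    @property
    def V(self) -> np.ndarray:
        return self.states[0]

    def closure_error(self) -> float:
        """Cyclic-closure figure of merit (mV): the voltage mismatch between
        the recorded cycle's start and the state one full period later."""
        return float(self.closure)


@dataclass
class SpiralSpec:
    """Where and how to seed the spiral.

    ``centre`` is a 3D physical point (mm); the phase plane is normal to
    ``normal`` (wall-tangent plane); ``wavelength`` is the Archimedean pitch
    (mm), defaulting to CV * period of the library when left as None.
    """

    centre: tuple
    chirality: str = "ccw"            # "cw" | "ccw"
    wavelength: float | None = None
    normal: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.chirality not in ("cw", "ccw"):
            raise ValueError("chirality must be 'cw' or 'ccw'")
        if self.wavelength is not None and self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def sign(self) -> float:
        return 1.0 if self.chirality == "ccw" else -1.0

    def tangent_basis(self) -> tuple[np.ndarray, np.ndarray]:
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        a = np.array([1.0, 0.0, 0.0])
        if abs(n @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = a - (a @ n) * n
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2


def record_cycle(params: RemodelParams | None = None, bcl: float = 200.0,
                 n_beats: int = 8, strand_length: float = 33.0,
                 dx: float = 0.33, dt: float = 0.01, D: float = 0.07,
                 dt_lib: float = 0.5, stim_pA: float = -2000.0,
                 stim_ms: float = 2.0) -> CycleLibrary:
    """Pace a strand and record the full state cycle at its midpoint.

    The strand starts from the single-cell rapid-pacing steady state and is
    stimulated at one end every ``bcl`` ms; the last period is recorded at the
    mid-strand node every ``dt_lib`` ms.  Steadiness requires successive
    mid-strand APs to differ by < 1 ms in APD90.
    """
    if params is None:
        params = RemodelParams()
    paced = pace_to_steady(params, bcl=bcl, n_beats=10, dt=dt,
                           stim_pA=stim_pA, stim_ms=stim_ms)
    geom = build_strand1d(strand_length, dx=dx)
    W = build_weights(geom)
    init = uniform_state(geom, paced.terminal, weights=W)
    mid = W.n // 2
    cfg = SolverConfig(
        D=D, dt=dt, duration=n_beats * bcl, record_interval=n_beats * bcl,
        probe_dt=dt_lib, probes=((mid, 0, 0),), params=params,
        stim_pA=stim_pA, stim_start=0.0, stim_duration=np.inf,
        stim_voxels=tuple((i, 0, 0) for i in range(3)),
    )
    # periodic stimulation: run beat by beat so the stimulus window repeats
    state = init
    samples_per_beat = int(round(bcl / dt_lib))
    mid_traces = []
    states_cycle = None
    for beat in range(n_beats):
        final = beat == n_beats - 1
        beat_cfg = SolverConfig(
            D=D, dt=dt, duration=bcl, record_interval=bcl,
            probe_dt=dt_lib, probes=((mid, 0, 0),), params=params,
            stim_pA=stim_pA, stim_start=state.t, stim_duration=stim_ms,
            stim_voxels=tuple((i, 0, 0) for i in range(3)),
        )
        if final:
            states_cycle = np.empty((c.N_STATE, samples_per_beat))
            traces = []
            t_rec = state.t
            # manual chunk loop to grab the full mid-state each sample
            from .tissue_solver import step_tissue
            istim = np.zeros(W.n)
            aux = np.zeros((6, W.n))
            last_act = np.full(W.n, -np.inf)
            n_sub = int(round(dt_lib / dt))
            for k in range(samples_per_beat):
                amp = (stim_pA / params.Cm
                       if (k * dt_lib) < stim_ms else 0.0)
                istim[:3] = amp
                states_cycle[:, k] = state.S[:, mid]
                step_tissue(state, W, beat_cfg, n_sub, istim, aux, last_act)
                traces.append(state.S[0, mid])
            mid_traces.append(np.asarray(traces))
        else:
            res = run(geom, state, beat_cfg)
            state = res.final
            mid_traces.append(res.probe_V[0])

    # steadiness check on the last two mid-strand APs
    try:
        a1 = apd90(mid_traces[-2], dt_lib)
        a2 = apd90(mid_traces[-1], dt_lib)
    except Exception as exc:
        raise ProtocolError(f"mid-strand propagation not steady: {exc}") from exc
    if abs(a1 - a2) >= 1.0:
        raise ProtocolError(
            f"mid-strand APD90 not steady ({a1:.2f} vs {a2:.2f} ms)"
        )

    # measure CV on the final beat from upstroke arrival 25 % -> 75 %
    i25, i75 = int(0.25 * (W.n - 1)), int(0.75 * (W.n - 1))
    t25, t75 = last_act[i25], last_act[i75]
    cv = (i75 - i25) * dx / (t75 - t25) if t75 > t25 else np.nan

    # closure: cycle start vs the state exactly one period later
    closure = float(abs(states_cycle[0, 0] - state.S[0, mid]))

    # rotate so index 0 is the upstroke (max dV/dt) sample
    v = states_cycle[0]
    dv = np.diff(v)
    i_up = int(np.argmax(dv)) + 1
    states_cycle = np.roll(states_cycle, -i_up, axis=1)
    return CycleLibrary(states=states_cycle, dt_lib=dt_lib, period=bcl, cv=cv,
                        closure=closure)


def archimedean_phase(x, y, spec: SpiralSpec, wavelength: float) -> np.ndarray:
    """Phase in [0, 1) at in-plane offsets (x, y) from the spiral centre.

    Level sets are Archimedean spirals of pitch ``wavelength``; a full turn
    around the centre changes the phase by exactly +/-1 (winding number one).
    r = 0 maps to phase 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.arctan2(y, x)
    r = np.hypot(x, y)
    phi = np.mod(spec.sign * theta / (2.0 * np.pi) + r / wavelength, 1.0)
    return np.where(r == 0, 0.0, phi)


def apply_phase_distribution(geom: VoxelGeometry, lib: CycleLibrary,
                             spec: SpiralSpec,
                             weights=None) -> FieldState:
    """Seed a scroll wave: assign each voxel the library state at its phase.

    The phase is computed in the tangent plane at ``spec.centre`` and is
    constant along the plane normal (transmural extension), so the seeded
    filament is a single transmural segment through the centre.
    """
    fs = FieldState(geom, weights=weights)
    lam = spec.wavelength
    if lam is None:
        cv = lib.cv if np.isfinite(lib.cv) else 0.4
        lam = cv * lib.period
    e1, e2 = spec.tangent_basis()
    pos = fs.W.voxels * geom.dx + np.asarray(geom.origin)
    rel = pos - np.asarray(spec.centre, dtype=float)
    phi = archimedean_phase(rel @ e1, rel @ e2, spec, lam)
    idx = np.mod(np.round(phi * lib.length).astype(int), lib.length)
    fs.S[:] = lib.states[:, idx]
    return fs
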