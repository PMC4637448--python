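"""Monodomain reaction–diffusion solver on a voxel geometry.

The monodomain equation  Cm dV/dt = -I_ion + D * lap(V)  with no-flux
boundaries is discretised on the voxel grid with a 7-point Laplacian stencil
by the method of weights: a neighbour contributes 1/dx^2 if it is tissue and 0
otherwise, and the centre weight is minus the sum of the neighbour weights, so
every stencil row sums to zero and the scheme conserves the diffusion flux
exactly.  Reaction and diffusion are advanced together in a single explicit
pass per time step (forward Euler for V and concentrations, Rush–Larsen for
gates); only V diffuses.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from ._kernel import step_chunk
from .cell_model import CellState, RemodelParams, get_table
from .errors import IntegrationError
from .geometry import VoxelGeometry

__all__ = ["SolverConfig", "FieldState", "LaplacianWeights", "SimResult",
           "build_weights", "laplacian", "step_tissue", "run",
           "uniform_state"]

log = logging.getLogger("atriadrift")

_OFFSETS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.int64)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration of a tissue run (units: mm, ms, mm^2/ms)."""

    D: float = 0.07
    dt: float = 0.01
    duration: float = 1000.0
    record_interval: float = 10.0
    probe_dt: float = 1.0
    probes: tuple = ()              # voxel (i, j, k) coordinates
    params: RemodelParams = field(default_factory=RemodelParams)
    stim_pA: float = 0.0            # stimulus current (pA, negative = depol.)
    stim_start: float = 0.0
    stim_duration: float = 0.0
    stim_voxels: tuple = ()         # voxel (i, j, k) coordinates
    record_activation: bool = False

    def check_stability(self, dx: float) -> None:
        bound = dx * dx / (6.0 * self.D) if self.D > 0 else np.inf
        if self.dt > bound:
            raise ValueError(
                f"dt={self.dt} violates the explicit stability bound "
                f"dx^2/(6 D)={bound:.4g} ms"
            )


class LaplacianWeights:
    """7-point no-flux stencil weights for a voxel geometry.

    Stored compactly as the tissue-neighbour index table; the weight of each
    present neighbour is 1/dx^2 and the centre weight is -(number of tissue
    neighbours)/dx^2 (row sums are exactly zero).
    """

    def __init__(self, geom: VoxelGeometry):
        self.geom = geom
        self.dx = geom.dx
        idx = np.argwhere(geom.mask)
        self.voxels = idx                     # (n, 3) tissue voxel indices
        self.n = idx.shape[0]
        lut = -np.ones(geom.shape, dtype=np.int32)
        lut[idx[:, 0], idx[:, 1], idx[:, 2]] = np.arange(self.n, dtype=np.int32)
        self.lut = lut
        nbr = np.full((self.n, 6), -1, dtype=np.int32)
        shp = np.array(geom.shape)
        for k, off in enumerate(_OFFSETS):
            p = idx + off
            ok = np.all((p >= 0) & (p < shp), axis=1)
            nbr[ok, k] = lut[p[ok, 0], p[ok, 1], p[ok, 2]]
        self.nbr = nbr

    def centre_weight(self, i: int) -> float:
        return -np.count_nonzero(self.nbr[i] >= 0) / self.dx ** 2

    def neighbour_weight(self) -> float:
        return 1.0 / self.dx ** 2


def build_weights(geom: VoxelGeometry) -> LaplacianWeights:
    """Construct the no-flux Laplacian weights for ``geom``."""
    return LaplacianWeights(geom)


def laplacian(V_field: np.ndarray, W: LaplacianWeights) -> np.ndarray:
    """Apply the weighted stencil to a 3D field defined on the mask.

    Returns a 3D field (mV/mm^2); non-tissue entries are 0.
    """
    v = np.asarray(V_field, dtype=float)
    vc = v[W.voxels[:, 0], W.voxels[:, 1], W.voxels[:, 2]]
    acc = np.zeros(W.n)
    for k in range(6):
        j = W.nbr[:, k]
        ok = j >= 0
        acc[ok] += vc[j[ok]] - vc[ok]
    out = np.zeros(v.shape)
    out[W.voxels[:, 0], W.voxels[:, 1], W.voxels[:, 2]] = acc / W.dx ** 2
    return out


class FieldState:
    """One CellState per tissue voxel (structure-of-arrays) plus the clock."""

    def __init__(self, geom: VoxelGeometry, S: np.ndarray | None = None,
                 t: float = 0.0, weights: LaplacianWeights | None = None):
        self.geom = geom
        self.W = weights if weights is not None else build_weights(geom)
        n = self.W.n
        if S is None:
            S = np.tile(CellState().to_array(), (1, n))
        if S.shape != (c.N_STATE, n):
            raise ValueError(f"state array must be (21, {n})")
        self.S = np.ascontiguousarray(S, dtype=float)
        self.t = float(t)

    def copy(self) -> "FieldState":
        return FieldState(self.geom, self.S.copy(), self.t, self.W)

    def field(self, name: str) -> np.ndarray:
        """Scatter one state variable to a 3D array (NaN outside tissue)."""
        out = np.full(self.geom.shape, np.nan)
        vx = self.W.voxels
        out[vx[:, 0], vx[:, 1], vx[:, 2]] = self.S[c.IDX[name]]
        return out

    def set_voxel_states(self, state_cols: np.ndarray,
                         which: np.ndarray | None = None) -> None:
        if which is None:
            self.S[:] = state_cols
        else:
            self.S[:, which] = state_cols


def uniform_state(geom: VoxelGeometry, cell: CellState | None = None,
                  weights: LaplacianWeights | None = None) -> FieldState:
    """Spatially uniform field state (defaults to the CRN resting state)."""
    fs = FieldState(geom, weights=weights)
    if cell is not None:
        fs.S[:] = cell.to_array()
    return fs


@dataclass
class SimResult:
    """Recorded output of a tissue run."""

    geom: VoxelGeometry
    cfg: SolverConfig
    snap_times: np.ndarray          # ms
    snaps_V: list                   # each (n_tissue,) float32
    snaps_oi: list
    probe_t: np.ndarray
    probe_V: np.ndarray             # (n_probes, nt)
    final: FieldState
    last_act: np.ndarray            # most recent -50 mV upstroke time per voxel
    act_maps: list = field(default_factory=list)  # (t0, per-voxel first act in window)

    def snapshot_field(self, k: int, which: str = "V") -> np.ndarray:
        data = (self.snaps_V if which == "V" else self.snaps_oi)[k]
        out = np.full(self.geom.shape, np.nan)
        vx = self.final.W.voxels
        out[vx[:, 0], vx[:, 1], vx[:, 2]] = data
        return out


def _voxel_indices(W: LaplacianWeights, coords) -> np.ndarray:
    out = []
    for (i, j, k) in coords:
        idx = W.lut[int(i), int(j), int(k)]
        if idx < 0:
            raise ValueError(f"probe/stimulus voxel {(i, j, k)} is not tissue")
        out.append(idx)
    return np.asarray(out, dtype=np.int64)


def step_tissue(state: FieldState, W: LaplacianWeights, cfg: SolverConfig,
                n_steps: int = 1, istim: np.ndarray | None = None,
                aux: np.ndarray | None = None,
                last_act: np.ndarray | None = None) -> FieldState:
    """Advance the field state in place by ``n_steps`` steps of cfg.dt."""
    cfg.check_stability(W.dx)
    n = W.n
    if istim is None:
        istim = np.zeros(n)
    if aux is None:
        aux = np.zeros((6, n))
    if last_act is None:
        last_act = np.full(n, -np.inf)
    p = cfg.params
    a_diff = cfg.D * cfg.dt / W.dx ** 2
    code = step_chunk(state.S, W.nbr, get_table(cfg.dt), cfg.dt, n_steps,
                      state.t, a_diff, p.g_cal, p.g_kr, p.g_ks, p.o_ach,
                      istim, aux, last_act)
    if code != 0:
        i, j, k = W.voxels[code - 1]
        raise IntegrationError(
            f"NaN at voxel ({i}, {j}, {k}) near t={state.t:.2f} ms"
        )
    state.t += n_steps * cfg.dt
    return state


def run(geom: VoxelGeometry, initial: FieldState, cfg: SolverConfig) -> SimResult:
    """Integrate the monodomain model and record snapshots and probe traces.

    Snapshots of V and the o_i gate are stored every ``cfg.record_interval``
    ms; probe V traces are sampled every ``cfg.probe_dt`` ms.  The run is
    fully deterministic.
    """
    cfg.check_stability(geom.dx)
    W = initial.W
    state = initial
    n = W.n
    n_sub = int(round(cfg.probe_dt / cfg.dt))
    if abs(n_sub * cfg.dt - cfg.probe_dt) > 1e-9:
        raise ValueError("probe_dt must be a multiple of dt")
    n_chunks = int(round(cfg.duration / cfg.probe_dt))
    rec_every = max(1, int(round(cfg.record_interval / cfg.probe_dt)))

    probe_idx = _voxel_indices(W, cfg.probes) if cfg.probes else np.empty(0, np.int64)
    istim = np.zeros(n)
    stim_idx = _voxel_indices(W, cfg.stim_voxels) if cfg.stim_voxels else None
    aux = np.zeros((6, n))
    last_act = np.full(n, -np.inf)

    snap_times = [state.t]
    snaps_V = [state.S[0].astype(np.float32)]
    snaps_oi = [state.S[c.IDX["oi"]].astype(np.float32)]
    probe_t = [state.t]
    probe_V = [state.S[0, probe_idx].copy()]
    act_maps = []
    cyc_act = np.full(n, np.nan)
    cyc_t0 = state.t
    p = cfg.params

    for chunk in range(n_chunks):
        t = state.t
        if stim_idx is not None:
            amp = (cfg.stim_pA / p.Cm
                   if cfg.stim_start <= t < cfg.stim_start + cfg.stim_duration
                   else 0.0)
            istim[stim_idx] = amp
        step_tissue(state, W, cfg, n_sub, istim, aux, last_act)
        probe_t.append(state.t)
        probe_V.append(state.S[0, probe_idx].copy())
        if (chunk + 1) % rec_every == 0:
            snap_times.append(state.t)
            snaps_V.append(state.S[0].astype(np.float32))
            snaps_oi.append(state.S[c.IDX["oi"]].astype(np.float32))
        if cfg.record_activation:
            fresh = (last_act > t) & np.isnan(cyc_act)
            cyc_act[fresh] = last_act[fresh]
            if state.t - cyc_t0 >= cfg.record_interval * 10 - 1e-9:
                act_maps.append((cyc_t0, cyc_act.copy()))
                cyc_act[:] = np.nan
                cyc_t0 = state.t
        if int(state.t) % 100 == 0 and abs(state.t - round(state.t)) < 1e-6:
            log.debug("t=%.0f ms  Vmax=%.1f mV", state.t, state.S[0].max())

    if cfg.record_activation and np.any(np.isfinite(cyc_act)):
        act_maps.append((cyc_t0, cyc_act.copy()))

    return SimResult(
        geom=geom, cfg=cfg,
        snap_times=np.asarray(snap_times),
        snaps_V=snaps_V, snaps_oi=snaps_oi,
        probe_t=np.asarray(probe_t),
        probe_V=np.asarray(probe_V).T if probe_idx.size else np.empty((0, 0)),
        final=state, last_act=last_act, act_maps=act_maps,
    )
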