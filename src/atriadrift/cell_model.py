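"""CRN human atrial myocyte model with AF remodelling and I_KACh.

The baseline is the 21-variable Courtemanche–Ramirez–Nattel (1998) model.  The
atrial-fibrillation variant used throughout this package applies three
electrophysiological alterations that together yield a short, stationary
rotor-supporting action potential: the L-type Ca2+ conductance is reduced to
35 % of control, the rapid and slow delayed-rectifier K+ conductances are
increased ninefold, and an acetylcholine-activated K+ current

    I_KACh = Cm * O_ACh([ACh]) * C_ACh(V) * (V - E_K)

is added, with [ACh] = 0.0035 umol/L by default.

Time stepping uses the Rush–Larsen exponential update for all gating variables
and forward Euler for the membrane potential and concentrations, with a fixed
default step of 0.01 ms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from . import _rates
from ._kernel import step_chunk
from .errors import AnalysisError, IntegrationError, StimulusError

__all__ = [
    "CellState", "RemodelParams", "IKAchTerms",
    "ikach_open", "ikach_voltage", "ikach_current", "ikach_terms",
    "currents", "total_current", "step_cell", "pace_to_steady", "apd90",
    "get_table", "resting_state",
]

_TABLE_CACHE: dict[float, np.ndarray] = {}


def get_table(dt: float) -> np.ndarray:
    """Rate lookup table for time step ``dt`` (cached)."""
    key = round(float(dt), 9)
    tab = _TABLE_CACHE.get(key)
    if tab is None:
        tab = _rates.build_table(key)
        _TABLE_CACHE[key] = tab
    return tab


@dataclass
class CellState:
    """Full ionic state of one CRN cell.

    V in mV; the 15 gates are dimensionless in [0, 1]; concentrations in mM.
    """

    V: float = c.REST_STATE["V"]
    m: float = c.REST_STATE["m"]
    h: float = c.REST_STATE["h"]
    j: float = c.REST_STATE["j"]
    oa: float = c.REST_STATE["oa"]
    oi: float = c.REST_STATE["oi"]
    ua: float = c.REST_STATE["ua"]
    ui: float = c.REST_STATE["ui"]
    xr: float = c.REST_STATE["xr"]
    xs: float = c.REST_STATE["xs"]
    d: float = c.REST_STATE["d"]
    f: float = c.REST_STATE["f"]
    fca: float = c.REST_STATE["fca"]
    u: float = c.REST_STATE["u"]
    v: float = c.REST_STATE["v"]
    w: float = c.REST_STATE["w"]
    Na_i: float = c.REST_STATE["Na_i"]
    K_i: float = c.REST_STATE["K_i"]
    Ca_i: float = c.REST_STATE["Ca_i"]
    Ca_up: float = c.REST_STATE["Ca_up"]
    Ca_rel: float = c.REST_STATE["Ca_rel"]

    def to_array(self) -> np.ndarray:
        """Column vector (21, 1) in the kernel's state ordering."""
        return np.array([[getattr(self, n)] for n in c.STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CellState":
        arr = np.asarray(arr, dtype=float).reshape(c.N_STATE)
        return cls(**{n: float(arr[i]) for i, n in enumerate(c.STATE_NAMES)})

    def validate(self) -> None:
        gates = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
                 "d", "f", "fca", "u", "v", "w")
        for g in gates:
            x = getattr(self, g)
            if not (0.0 <= x <= 1.0):
                raise IntegrationError(f"gate {g}={x} outside [0, 1]")
        for k in ("Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel"):
            if not getattr(self, k) > 0:
                raise IntegrationError(f"concentration {k} not positive")
        if not (-100.0 <= self.V <= 60.0):
            raise IntegrationError(f"V={self.V} mV outside [-100, 60]")


def resting_state() -> CellState:
    """Published control-CRN quiescent steady state."""
    return CellState()


@dataclass(frozen=True)
class RemodelParams:
    """Conductance scalings and [ACh] defining the AF-remodelled model.

    Defaults are the remodelled (rotor-supporting) condition; use
    :meth:`control` for the unmodified CRN model.
    """

    scale_gCaL: float = 0.35
    scale_gKr: float = 9.0
    scale_gKs: float = 9.0
    ach: float = 0.0035          # umol/L
    Cm: float = c.CM             # pF
    kach_exp: float = c.KACH_EXP_DEFAULT

    def __post_init__(self):
        if self.scale_gCaL <= 0 or self.scale_gKr <= 0 or self.scale_gKs <= 0:
            raise ValueError("conductance scale factors must be positive")
        if self.ach < 0:
            raise ValueError("acetylcholine concentration must be >= 0")

    @classmethod
    def control(cls) -> "RemodelParams":
        return cls(scale_gCaL=1.0, scale_gKr=1.0, scale_gKs=1.0, ach=0.0)

    @property
    def is_control(self) -> bool:
        return (self.scale_gCaL == 1.0 and self.scale_gKr == 1.0
                and self.scale_gKs == 1.0 and self.ach == 0.0)

    @property
    def g_cal(self) -> float:
        return c.G_CAL * self.scale_gCaL

    @property
    def g_kr(self) -> float:
        return c.G_KR * self.scale_gKr

    @property
    def g_ks(self) -> float:
        return c.G_KS * self.scale_gKs

    @property
    def o_ach(self) -> float:
        return ikach_open(self.ach, self.kach_exp)


@dataclass(frozen=True)
class IKAchTerms:
    O_Ach: float     # acetylcholine-dependent activation, [0, 10]
    C_Ach: float     # voltage-dependent term, (0.052, 0.502)
    E_k: float       # mV
    I_KAch: float    # pA


def ikach_open(ach: float, exponent: float = c.KACH_EXP_DEFAULT) -> float:
    """ACh-dependent activation O_ACh = 10 / (1 + 9.13 / [ACh]^p).

    Returns 0 at [ACh] = 0 (limit convention); monotone increasing,
    saturating at 10.
    """
    if ach < 0:
        raise ValueError("acetylcholine concentration must be >= 0")
    if ach == 0:
        return 0.0
    return c.KACH_SCALE / (1.0 + c.KACH_HALF / ach ** exponent)


def ikach_voltage(V: float) -> float:
    """Voltage-dependent term C_ACh = 0.052 + 0.45 / (1 + exp((V+59.53)/17.18))."""
    return c.CACH_BASE + c.CACH_AMP / (
        1.0 + math.exp((V - c.CACH_VHALF) / c.CACH_SLOPE)
    )


def ikach_terms(state: CellState, params: RemodelParams) -> IKAchTerms:
    ek = c.RTF * math.log(c.K_O / state.K_i)
    o = ikach_open(params.ach, params.kach_exp)
    ca = ikach_voltage(state.V)
    return IKAchTerms(o, ca, ek, params.Cm * o * ca * (state.V - ek))


def ikach_current(state: CellState, params: RemodelParams) -> float:
    """I_KACh in pA: Cm * O_ACh * C_ACh * (V - E_K)."""
    return ikach_terms(state, params).I_KAch


def currents(state: CellState, params: RemodelParams) -> dict[str, float]:
    """All membrane currents (pA) evaluated directly (no lookup table).

    This is the reference evaluation path; the integration kernel reproduces
    it through table interpolation.
    """
    s = state
    ena = c.RTF * math.log(c.NA_O / s.Na_i)
    ek = c.RTF * math.log(c.K_O / s.K_i)
    eca = 0.5 * c.RTF * math.log(c.CA_O / s.Ca_i)
    co = _rates.current_coeffs(s.V)
    cm = params.Cm
    out = {
        "I_Na": cm * c.G_NA * s.m ** 3 * s.h * s.j * (s.V - ena),
        "I_K1": cm * float(co["ck1"]) * (s.V - ek),
        "I_to": cm * c.G_TO * s.oa ** 3 * s.oi * (s.V - ek),
        "I_Kur": cm * float(co["gkur"]) * s.ua ** 3 * s.ui * (s.V - ek),
        "I_Kr": cm * params.g_kr * float(co["ckr"]) * s.xr * (s.V - ek),
        "I_Ks": cm * params.g_ks * s.xs ** 2 * (s.V - ek),
        "I_CaL": cm * params.g_cal * s.d * s.f * s.fca * (s.V - 65.0),
        "I_pCa": cm * c.I_PCA_MAX * s.Ca_i / (0.0005 + s.Ca_i),
        "I_NaK": cm * c.I_NAK_MAX * float(co["fnak"])
        / (1.0 + (c.KM_NA_I / s.Na_i) ** 1.5) * c.K_O / (c.K_O + c.KM_K_O),
        "I_NaCa": cm * c.I_NACA_MAX
        * (float(co["e1"]) * s.Na_i ** 3 * c.CA_O
           - float(co["e2"]) * c.NA_O ** 3 * s.Ca_i)
        / ((c.KM_NA ** 3 + c.NA_O ** 3) * (c.KM_CA + c.CA_O)
           * (1.0 + c.K_SAT * float(co["e2"]))),
        "I_bNa": cm * c.G_B_NA * (s.V - ena),
        "I_bCa": cm * c.G_B_CA * (s.V - eca),
        "I_KACh": ikach_current(state, params),
    }
    for name, val in out.items():
        if not math.isfinite(val):
            raise IntegrationError(f"current {name} is not finite")
    return out


def total_current(state: CellState, params: RemodelParams) -> float:
    """Sum of all membrane currents (pA); positive = outward."""
    return sum(currents(state, params).values())


def _advance(S: np.ndarray, params: RemodelParams, dt: float, nsub: int,
             t0: float, istim: np.ndarray, aux: np.ndarray,
             last_act: np.ndarray) -> None:
    nbr = np.full((S.shape[1], 6), -1, dtype=np.int32)
    code = step_chunk(S, nbr, get_table(dt), dt, nsub, t0, 0.0,
                      params.g_cal, params.g_kr, params.g_ks, params.o_ach,
                      istim, aux, last_act)
    if code != 0:
        raise IntegrationError(f"NaN at cell index {code - 1}")


def step_cell(state: CellState, dt: float = 0.01, I_stim: float = 0.0,
              params: RemodelParams | None = None, n_steps: int = 1) -> CellState:
    """Advance a single cell by ``n_steps`` steps of ``dt`` ms.

    ``I_stim`` is in pA (negative = depolarising), constant over the interval.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params is None:
        params = RemodelParams.control()
    S = state.to_array()
    istim = np.array([I_stim / params.Cm])
    aux = np.zeros((6, 1))
    last_act = np.full(1, -np.inf)
    _advance(S, params, dt, n_steps, 0.0, istim, aux, last_act)
    out = CellState.from_array(S[:, 0])
    out.validate()
    return out


@dataclass
class PacedBeat:
    """Final-beat recording returned by :func:`pace_to_steady`."""

    t: np.ndarray            # ms, relative to final-beat stimulus
    V: np.ndarray            # mV
    states: np.ndarray       # (21, n_samples) full state at each sample
    terminal: CellState
    apd90: float             # ms
    apd90_history: list[float] = field(default_factory=list)


def pace_to_steady(params: RemodelParams, bcl: float | None = None,
                   n_beats: int = 20, dt: float = 0.01,
                   stim_pA: float = -2000.0, stim_ms: float = 2.0,
                   dt_sample: float = 0.5,
                   initial: CellState | None = None) -> PacedBeat:
    """Pace a single cell to a steady action potential.

    Default basic cycle length: 1000 ms for the control model, 300 ms for any
    remodelled parameter set.  Steadiness = |APD90 change| < 1 ms between the
    last two beats (reported, not enforced, when ``n_beats`` is small).
    """
    if bcl is None:
        bcl = 1000.0 if params.is_control else 300.0
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    state = initial if initial is not None else resting_state()
    S = state.to_array()
    aux = np.zeros((6, 1))
    last_act = np.full(1, -np.inf)
    n_sub = int(round(dt_sample / dt))
    samples_per_beat = int(round(bcl / dt_sample))
    stim_samples = int(round(stim_ms / dt_sample))
    apds: list[float] = []
    trace = np.empty(samples_per_beat + 1)
    states = np.empty((c.N_STATE, samples_per_beat + 1))
    for beat in range(n_beats):
        final = beat == n_beats - 1
        trace[0] = S[0, 0]
        if final:
            states[:, 0] = S[:, 0]
        for k in range(samples_per_beat):
            amp = stim_pA / params.Cm if k < stim_samples else 0.0
            _advance(S, params, dt, n_sub, beat * bcl + k * dt_sample,
                     np.array([amp]), aux, last_act)
            trace[k + 1] = S[0, 0]
            if final:
                states[:, k + 1] = S[:, 0]
        try:
            apds.append(apd90(trace, dt_sample))
        except AnalysisError:
            apds.append(float("nan"))
    final_apd = apds[-1]
    if np.max(trace) < 0.0:
        raise StimulusError("no action potential elicited (peak V < 0 mV)")
    out = PacedBeat(
        t=np.arange(samples_per_beat + 1) * dt_sample,
        V=trace.copy(),
        states=states.copy(),
        terminal=CellState.from_array(S[:, 0]),
        apd90=final_apd,
        apd90_history=apds,
    )
    return out


def apd90(V_trace: np.ndarray, dt_sample: float) -> float:
    """Action-potential duration at 90 % repolarisation.

    Measured from the point of maximum dV/dt to the 90 %-repolarisation
    crossing of the peak-to-baseline amplitude (baseline = diastolic minimum
    before the upstroke), with linear interpolation at the crossing.  The
    trace must contain one AP.
    """
    V = np.asarray(V_trace, dtype=float)
    if V.size < 3:
        raise AnalysisError("trace too short")
    dv = np.diff(V)
    i_up = int(np.argmax(dv))
    if dv[i_up] <= 1e-3:
        raise AnalysisError("no upstroke found in trace")
    baseline = float(np.min(V[: i_up + 1]))
    i_peak = i_up + int(np.argmax(V[i_up:]))
    peak = V[i_peak]
    if peak - baseline < 1.0:
        raise AnalysisError("no upstroke found in trace")
    v90 = peak - 0.9 * (peak - baseline)
    below = np.nonzero(V[i_peak:] <= v90)[0]
    if below.size == 0:
        raise AnalysisError("trace does not repolarise to 90 %")
    k = i_peak + below[0]
    # linear interpolation between samples k-1 and k
    frac = (V[k - 1] - v90) / (V[k - 1] - V[k]) if V[k - 1] != V[k] else 0.0
    t_cross = (k - 1 + frac) * dt_sample
    return t_cross - i_up * dt_sample
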