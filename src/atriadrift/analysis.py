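"""AP-trace analytics, conduction-velocity measurement, and breakthrough
detection.

The dominant pacing rate of a recorded AP profile comes from a single-taper
periodogram (mean removed, zero-padded to the next power of two, no
smoothing); the rhythm is classified monomorphic/polymorphic from the number
of strong non-harmonic spectral peaks; recurrence maps plot consecutive cycle
lengths measured between successive upward -50 mV crossings.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import AnalysisError
from .geometry import VoxelGeometry, LABELS

__all__ = ["PSDResult", "RecurrenceMap", "psd", "cycle_lengths",
           "classify_morphology", "measure_cv", "detect_breakthrough",
           "BreakthroughEvent"]

F_MIN = 0.5          # Hz, exclude DC/very-low-frequency leakage
UPSTROKE_THRESHOLD = -50.0   # mV


@dataclass
class PSDResult:
    freqs: np.ndarray            # Hz
    power: np.ndarray
    dominant: float              # Hz, global maximum above F_MIN
    peaks: list = field(default_factory=list)  # (freq_Hz, relative_power)


@dataclass
class RecurrenceMap:
    cycle_lengths: np.ndarray    # ms, ordered
    @property
    def points(self) -> np.ndarray:
        """(CL_n, CL_{n+1}) scatter points."""
        cl = self.cycle_lengths
        return np.column_stack([cl[:-1], cl[1:]])

    @property
    def mean_cl(self) -> float:
        return float(np.mean(self.cycle_lengths))


def psd(trace: np.ndarray, dt_sample: float, rel_peak: float = 0.05) -> PSDResult:
    """Periodogram of a detrended AP trace; dominant frequency above 0.5 Hz.

    ``dt_sample`` in ms.  Traces shorter than 2 s trigger a resolution
    warning (frequency bin wider than ~0.5 Hz).
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 8:
        raise AnalysisError("trace too short for a spectrum")
    T = x.size * dt_sample
    if T < 2000.0:
        warnings.warn(
            f"trace of {T:.0f} ms gives frequency resolution "
            f"{1e3 / T:.2f} Hz; dominant-frequency estimates may be coarse",
            stacklevel=2,
        )
    fs = 1000.0 / dt_sample      # Hz
    nfft = int(2 ** np.ceil(np.log2(x.size)))
    freqs, power = sps.periodogram(x - np.mean(x), fs=fs, nfft=nfft,
                                   detrend=False, window="boxcar")
    valid = freqs > F_MIN
    if not np.any(valid) or np.max(power[valid]) <= 0:
        raise AnalysisError("no spectral content above 0.5 Hz")
    k_dom = np.argmax(np.where(valid, power, 0.0))
    dominant = float(freqs[k_dom])
    p_dom = power[k_dom]
    # secondary peaks: local maxima separated by >= 0.5 Hz, above rel_peak
    min_dist = max(1, int(round(0.5 / (freqs[1] - freqs[0]))))
    idx, _ = sps.find_peaks(power, height=rel_peak * p_dom, distance=min_dist)
    peaks = [(float(freqs[i]), float(power[i] / p_dom))
             for i in idx if freqs[i] > F_MIN]
    return PSDResult(freqs=freqs, power=power, dominant=dominant, peaks=peaks)


def classify_morphology(res: PSDResult, rel_power: float = 0.2,
                        harmonic_tol: float = 0.08) -> str:
    """'polymorphic' iff two or more mutually non-harmonic peaks carry more
    than ``rel_power`` of the dominant peak's power (the dominant included).

    A peak is harmonic when its frequency is an integer multiple of the
    dominant within ``harmonic_tol`` (relative).
    """
    f0 = res.dominant
    strong = [(f, p) for f, p in res.peaks if p >= rel_power]
    non_harm = 1  # the dominant peak itself
    for f, _ in strong:
        if abs(f - f0) < 1e-9:
            continue
        ratio = f / f0
        if abs(ratio - round(ratio)) > harmonic_tol or round(ratio) == 0:
            non_harm += 1
    return "polymorphic" if non_harm >= 2 else "monomorphic"


def cycle_lengths(trace: np.ndarray, dt_sample: float,
                  threshold: float = UPSTROKE_THRESHOLD) -> RecurrenceMap:
    """Cycle lengths between successive upward threshold crossings.

    Crossing times are linearly interpolated; at least 3 upstrokes required.
    """
    x = np.asarray(trace, dtype=float)
    below = x[:-1] < threshold
    above = x[1:] >= threshold
    k = np.nonzero(below & above)[0]
    if k.size < 3:
        raise AnalysisError("fewer than 3 upstrokes in trace")
    frac = (threshold - x[k]) / (x[k + 1] - x[k])
    t_cross = (k + frac) * dt_sample
    cl = np.diff(t_cross)
    if np.any(cl <= 0):
        raise AnalysisError("non-positive cycle length")
    return RecurrenceMap(cycle_lengths=cl)


def measure_cv(result, frac_lo: float = 0.25, frac_hi: float = 0.75) -> float:
    """Solitary-wave conduction velocity (mm/ms) on a strand SimResult.

    Uses the -50 mV upstroke activation times recorded by the solver at the
    ``frac_lo`` and ``frac_hi`` positions along the strand.
    """
    W = result.final.W
    n = W.n
    i_lo, i_hi = int(round(frac_lo * (n - 1))), int(round(frac_hi * (n - 1)))
    if i_lo == i_hi:
        raise AnalysisError("zero-length measurement interval")
    t_lo, t_hi = result.last_act[i_lo], result.last_act[i_hi]
    if not (np.isfinite(t_lo) and np.isfinite(t_hi)) or t_hi <= t_lo:
        raise AnalysisError("wave failed to traverse the strand")
    return float((i_hi - i_lo) * W.dx / (t_hi - t_lo))


@dataclass
class BreakthroughEvent:
    time: float                  # ms, activation time at the event focus
    position: np.ndarray         # mm
    junction_distance: float     # mm (inf when no junction labels present)


def detect_breakthrough(act_times: np.ndarray, geom: VoxelGeometry,
                        ring_radius: float = 2.0, lead_ms: float = 2.0,
                        early_ms: float = 10.0) -> list:
    """Detect focal (breakthrough) activations on the epicardial surface.

    An event is a local minimum of epicardial activation time whose 2 mm ring
    activates at least ``lead_ms`` later, and which is not connected — within
    the earliest ``early_ms`` of the cycle — to a front entering from the map
    border.  ``act_times`` is a 3D array of activation times (ms; NaN where
    not activated this cycle).
    """
    act = np.asarray(act_times, dtype=float)
    epi_idx = np.argwhere(geom.epi)
    if epi_idx.size == 0:
        return []
    t_epi = act[epi_idx[:, 0], epi_idx[:, 1], epi_idx[:, 2]]
    ok = np.isfinite(t_epi)
    epi_idx, t_epi = epi_idx[ok], t_epi[ok]
    if t_epi.size == 0:
        return []
    pos = epi_idx * geom.dx + np.asarray(geom.origin)
    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    # border voxels of the epicardial map: at the array edge in-plane, plus
    # the rim (k = 0) for curved (multi-layer) epicardial surfaces
    nx, ny, nz = geom.shape
    border = (epi_idx[:, 0] == 0) | (epi_idx[:, 0] == nx - 1) \
        | (epi_idx[:, 1] == 0) | (epi_idx[:, 1] == ny - 1)
    if np.unique(epi_idx[:, 2]).size > 3:
        border |= epi_idx[:, 2] == 0

    # junction positions for annotation
    j_idx = np.argwhere(geom.labels == LABELS["junction"])
    j_pos = j_idx * geom.dx + np.asarray(geom.origin) if j_idx.size else None

    events = []
    t0 = np.nanmin(t_epi)
    ring_lo, ring_hi = 0.6 * ring_radius, 1.25 * ring_radius
    for i in range(t_epi.size):
        ti = t_epi[i]
        nb = tree.query_ball_point(pos[i], ring_hi)
        nb = [k for k in nb if k != i]
        if not nb:
            continue
        d = np.linalg.norm(pos[nb] - pos[i], axis=1)
        tn = t_epi[nb]
        inner = d < ring_lo
        ring = ~inner
        if np.any(tn[inner] < ti):            # not a local minimum
            continue
        if not np.any(ring) or np.min(tn[ring]) < ti + lead_ms:
            continue
        # reject if connected to a border-entering front in the early window
        early = t_epi <= ti + early_ms
        if np.any(early & border):
            comp = _surface_component(pos, early, tree, i,
                                      link=1.8 * geom.dx)
            if np.any(border[comp]):
                continue
        jd = float(np.min(np.linalg.norm(j_pos - pos[i], axis=1))) \
            if j_pos is not None else np.inf
        events.append(BreakthroughEvent(time=float(ti), position=pos[i],
                                        junction_distance=jd))
    # merge events closer than the ring radius (same focus)
    events.sort(key=lambda e: e.time)
    merged = []
    for ev in events:
        if all(np.linalg.norm(ev.position - m.position) > ring_radius
               for m in merged):
            merged.append(ev)
    return merged


def _surface_component(pos, active, tree, seed, link):
    """Indices of the connected set of ``active`` points containing seed."""
    import collections

    n = pos.shape[0]
    seen = np.zeros(n, dtype=bool)
    if not active[seed]:
        return np.array([seed])
    q = collections.deque([seed])
    seen[seed] = True
    while q:
        k = q.popleft()
        for m in tree.query_ball_point(pos[k], link):
            if active[m] and not seen[m]:
                seen[m] = True
                q.append(m)
    return np.nonzero(seen)[0]
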