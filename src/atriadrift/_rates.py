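"""Voltage-dependent gating kinetics and current coefficients of the CRN model.

Everything here is vectorised numpy used to precompute a lookup table over
membrane potential for a fixed time step.  The hot integration kernel
(:mod:`atriadrift._kernel`) interpolates this table linearly, which removes all
transcendental evaluations of V-dependent terms from the inner loop.  Table
spacing is 0.1 mV; for the sigmoidal/exponential rate laws of the model (scales
of 5–28 mV) the interpolation error is O(1e-6) relative and far below the
integration error of the explicit scheme.
"""
from __future__ import annotations

import numpy as np

from . import constants as c

# table layout: columns 0..11 gate steady states, 12..23 Rush-Larsen factors
# exp(-dt/tau) in the same gate order, 24.. current coefficients.
GATE_ORDER = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "w")
COL_INF = 0
COL_RLF = 12
COL_CK1 = 24       # g_K1 / (1 + exp(0.07 (V+80)))
COL_GKUR = 25      # g_Kur(V)
COL_CKR = 26       # 1 / (1 + exp((V+15)/22.4))
COL_CACH = 27      # C_Ach(V)
COL_FNAK = 28      # f_NaK(V)
COL_E1 = 29        # exp(gamma V F / RT)
COL_E2 = 30        # exp((gamma-1) V F / RT)
N_COLS = 31

V_MIN = -120.0
V_MAX = 80.0
DV_TABLE = 0.1


def _safe_ratio(num, den, limit):
    """num/den with a removable singularity replaced by its limit."""
    out = np.where(np.abs(den) < 1e-9, limit, num / np.where(den == 0, 1.0, den))
    return out


def gate_inf_tau(v):
    """Steady states and time constants of the 12 V-dependent gates.

    Returns two dicts keyed by gate name; arrays broadcast against ``v``.
    """
    v = np.asarray(v, dtype=float)
    inf, tau = {}, {}

    # fast sodium activation m
    a_m = _safe_ratio(0.32 * (v + 47.13), 1.0 - np.exp(-0.1 * (v + 47.13)), 3.2)
    b_m = 0.08 * np.exp(-v / 11.0)
    inf["m"] = a_m / (a_m + b_m)
    tau["m"] = 1.0 / (a_m + b_m)

    # fast sodium inactivation h, j (piecewise at -40 mV)
    lo = v < -40.0
    a_h = np.where(lo, 0.135 * np.exp(-(v + 80.0) / 6.8), 0.0)
    b_h = np.where(
        lo,
        3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
        1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
    )
    inf["h"] = a_h / (a_h + b_h)
    tau["h"] = 1.0 / (a_h + b_h)

    a_j = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
        * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
        0.0,
    )
    b_j = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
        0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
    )
    inf["j"] = a_j / (a_j + b_j)
    tau["j"] = 1.0 / (a_j + b_j)

    # transient outward activation oa / inactivation oi
    a_oa = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    inf["oa"] = 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54))
    tau["oa"] = 1.0 / ((a_oa + b_oa) * c.K_Q10)

    a_oi = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
    inf["oi"] = 1.0 / (1.0 + np.exp((v + 43.1) / 5.3))
    tau["oi"] = 1.0 / ((a_oi + b_oi) * c.K_Q10)

    # ultrarapid delayed rectifier ua / ui
    a_ua = a_oa
    b_ua = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    inf["ua"] = 1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6))
    tau["ua"] = 1.0 / ((a_ua + b_ua) * c.K_Q10)

    a_ui = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
    b_ui = np.exp((v - 158.0) / 16.0)
    inf["ui"] = 1.0 / (1.0 + np.exp((v - 99.45) / 27.48))
    tau["ui"] = 1.0 / ((a_ui + b_ui) * c.K_Q10)

    # rapid delayed rectifier xr
    a_xr = _safe_ratio(
        0.0003 * (v + 14.1), 1.0 - np.exp(-(v + 14.1) / 5.0), 0.0015
    )
    b_xr = _safe_ratio(
        7.3898e-5 * (v - 3.3328),
        np.exp((v - 3.3328) / 5.1237) - 1.0,
        7.3898e-5 * 5.1237,
    )
    inf["xr"] = 1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5))
    tau["xr"] = 1.0 / (a_xr + b_xr)

    # slow delayed rectifier xs
    a_xs = _safe_ratio(
        4e-5 * (v - 19.9), 1.0 - np.exp(-(v - 19.9) / 17.0), 4e-5 * 17.0
    )
    b_xs = _safe_ratio(
        3.5e-5 * (v - 19.9), np.exp((v - 19.9) / 9.0) - 1.0, 3.5e-5 * 9.0
    )
    inf["xs"] = 1.0 / np.sqrt(1.0 + np.exp(-(v - 19.9) / 12.7))
    tau["xs"] = 0.5 / (a_xs + b_xs)

    # L-type calcium activation d / voltage inactivation f
    e_d = np.exp(-(v + 10.0) / 6.24)
    tau["d"] = _safe_ratio(
        1.0 - e_d, 0.035 * (v + 10.0) * (1.0 + e_d), 1.0 / (0.035 * 6.24 * 2.0)
    )
    inf["d"] = 1.0 / (1.0 + np.exp(-(v + 10.0) / 8.0))
    tau["f"] = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02)
    inf["f"] = 1.0 / (1.0 + np.exp((v + 28.0) / 6.9))

    # SR release voltage gate w
    e_w = np.exp(-(v - 7.9) / 5.0)
    tau["w"] = _safe_ratio(
        6.0 * (1.0 - e_w), (1.0 + 0.3 * e_w) * (v - 7.9), 6.0 / (1.3 * 5.0)
    )
    inf["w"] = 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0))

    return inf, tau


def current_coeffs(v):
    """V-dependent coefficients of the membrane currents (per-pF scale)."""
    v = np.asarray(v, dtype=float)
    sigma = (np.exp(c.NA_O / 67.3) - 1.0) / 7.0
    vfrt = v / c.RTF
    out = {
        "ck1": c.G_K1 / (1.0 + np.exp(0.07 * (v + 80.0))),
        "gkur": 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0)),
        "ckr": 1.0 / (1.0 + np.exp((v + 15.0) / 22.4)),
        "cach": c.CACH_BASE
        + c.CACH_AMP / (1.0 + np.exp((v - c.CACH_VHALF) / c.CACH_SLOPE)),
        "fnak": 1.0
        / (
            1.0
            + 0.1245 * np.exp(-0.1 * vfrt)
            + 0.0365 * sigma * np.exp(-vfrt)
        ),
        "e1": np.exp(c.GAMMA * vfrt),
        "e2": np.exp((c.GAMMA - 1.0) * vfrt),
    }
    return out


def build_table(dt):
    """Precompute the (n_v, 31) lookup table for time step ``dt`` (ms)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = np.arange(V_MIN, V_MAX + DV_TABLE / 2, DV_TABLE)
    tab = np.empty((v.size, N_COLS))
    inf, tau = gate_inf_tau(v)
    for k, g in enumerate(GATE_ORDER):
        tab[:, COL_INF + k] = inf[g]
        tab[:, COL_RLF + k] = np.exp(-dt / tau[g])
    cur = current_coeffs(v)
    tab[:, COL_CK1] = cur["ck1"]
    tab[:, COL_GKUR] = cur["gkur"]
    tab[:, COL_CKR] = cur["ckr"]
    tab[:, COL_CACH] = cur["cach"]
    tab[:, COL_FNAK] = cur["fnak"]
    tab[:, COL_E1] = cur["e1"]
    tab[:, COL_E2] = cur["e2"]
    return np.ascontiguousarray(tab)
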