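"""Numba integration kernel shared by the single-cell and tissue solvers.

One kernel call advances every tissue node by ``nsub`` explicit steps of size
``dt``: Rush–Larsen exponential updates for the gating variables, forward Euler
for membrane potential and concentrations, and a 7-point no-flux Laplacian
(method of weights) applied to V only.  All V-dependent transcendental terms
come from the precomputed table (see :mod:`atriadrift._rates`); reversal
potentials and the slowly varying Na+ pump terms are refreshed every 10
substeps, which is far faster than any concentration time scale.

State array layout: shape (21, n), rows ordered per ``constants.STATE_NAMES``.
Neighbour array: shape (n, 6), -1 marks a missing (no-flux) neighbour.
"""
from __future__ import annotations

import numba
import numpy as np

from . import constants as c
from ._rates import COL_CACH, COL_CK1, COL_CKR, COL_E1, COL_E2, COL_FNAK, \
    COL_GKUR, COL_INF, COL_RLF, DV_TABLE, V_MIN

_NACA_DEN = (c.KM_NA ** 3 + c.NA_O ** 3) * (c.KM_CA + c.CA_O)
_ACT_THRESHOLD = -50.0  # mV, upstroke detection for activation times


@numba.njit(cache=True, fastmath=True)
def step_chunk(S, nbr, table, dt, nsub, t0, a_diff, g_cal, g_kr, g_ks,
               o_ach, istim, aux, last_act):
    """Advance all nodes by nsub steps of dt; returns 0, or 1+node on NaN.

    a_diff = D*dt/dx^2 (dimensionless); istim in pA/pF (negative =
    depolarising); aux is a scratch (6, n) float64 array; last_act records the
    most recent -50 mV upstroke crossing time per node.
    """
    n = S.shape[1]
    inv_dv = 1.0 / DV_TABLE
    nrow = table.shape[0]
    k_u = 1.0 - np.exp(-dt / c.TAU_U)
    k_fca = 1.0 - np.exp(-dt / c.TAU_F_CA)
    conc_fac = 1.0 / (c.FARADAY * c.V_I)
    lap = aux[0]
    ena = aux[1]
    ek = aux[2]
    eca = aux[3]
    fnak_na = aux[4]
    nai3 = aux[5]

    for it in range(nsub):
        if it % 10 == 0:
            for i in range(n):
                nai = S[16, i]
                ki = S[17, i]
                cai = S[18, i]
                ena[i] = c.RTF * np.log(c.NA_O / nai)
                ek[i] = c.RTF * np.log(c.K_O / ki)
                eca[i] = 0.5 * c.RTF * np.log(c.CA_O / cai)
                fnak_na[i] = 1.0 / (1.0 + (c.KM_NA_I / nai) ** 1.5)
                nai3[i] = nai * nai * nai

        if a_diff != 0.0:
            for i in range(n):
                v0 = S[0, i]
                acc = 0.0
                for k in range(6):
                    j = nbr[i, k]
                    if j >= 0:
                        acc += S[0, j] - v0
                lap[i] = acc
        else:
            for i in range(n):
                lap[i] = 0.0

        t_now = t0 + (it + 1) * dt
        for i in range(n):
            v0 = S[0, i]
            x = (v0 - V_MIN) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > nrow - 1.001:
                x = nrow - 1.001
            i0 = int(x)
            fr = x - i0
            r0 = table[i0]
            r1 = table[i0 + 1]

            m = S[1, i]
            h = S[2, i]
            jj = S[3, i]
            oa = S[4, i]
            oi = S[5, i]
            ua = S[6, i]
            ui = S[7, i]
            xr = S[8, i]
            xs = S[9, i]
            d = S[10, i]
            f = S[11, i]
            fca = S[12, i]
            u = S[13, i]
            vv = S[14, i]
            w = S[15, i]
            nai = S[16, i]
            ki = S[17, i]
            cai = S[18, i]
            caup = S[19, i]
            carel = S[20, i]

            # membrane currents (pA) at the current state
            ina = c.CM * c.G_NA * m * m * m * h * jj * (v0 - ena[i])
            ck1 = r0[COL_CK1] + fr * (r1[COL_CK1] - r0[COL_CK1])
            ik1 = c.CM * ck1 * (v0 - ek[i])
            ito = c.CM * c.G_TO * oa * oa * oa * oi * (v0 - ek[i])
            gkur = r0[COL_GKUR] + fr * (r1[COL_GKUR] - r0[COL_GKUR])
            ikur = c.CM * gkur * ua * ua * ua * ui * (v0 - ek[i])
            ckr = r0[COL_CKR] + fr * (r1[COL_CKR] - r0[COL_CKR])
            ikr = c.CM * g_kr * ckr * xr * (v0 - ek[i])
            iks = c.CM * g_ks * xs * xs * (v0 - ek[i])
            ical = c.CM * g_cal * d * f * fca * (v0 - 65.0)
            ipca = c.CM * c.I_PCA_MAX * cai / (0.0005 + cai)
            fnak = r0[COL_FNAK] + fr * (r1[COL_FNAK] - r0[COL_FNAK])
            inak = (
                c.CM * c.I_NAK_MAX * fnak * fnak_na[i]
                * c.K_O / (c.K_O + c.KM_K_O)
            )
            e1 = r0[COL_E1] + fr * (r1[COL_E1] - r0[COL_E1])
            e2 = r0[COL_E2] + fr * (r1[COL_E2] - r0[COL_E2])
            inaca = (
                c.CM * c.I_NACA_MAX
                * (e1 * nai3[i] * c.CA_O - e2 * c.NA_O ** 3 * cai)
                / (_NACA_DEN * (1.0 + c.K_SAT * e2))
            )
            ibna = c.CM * c.G_B_NA * (v0 - ena[i])
            ibca = c.CM * c.G_B_CA * (v0 - eca[i])
            cach = r0[COL_CACH] + fr * (r1[COL_CACH] - r0[COL_CACH])
            ikach = c.CM * o_ach * cach * (v0 - ek[i])

            iion = (
                ina + ik1 + ito + ikur + ikr + iks + ical + ipca
                + inak + inaca + ibna + ibca + ikach
            )

            # SR release and the Fn-controlled gates u, v
            irel = c.K_REL * u * u * vv * w * (carel - cai)
            fn = 1e-12 * c.V_REL * irel - (5e-13 / c.FARADAY) * (
                0.5 * ical - 0.2 * inaca
            )
            arg = (fn - 3.4175e-13) / 1.367e-15
            if arg > 40.0:
                s1 = 1.0
            elif arg < -40.0:
                s1 = 0.0
            else:
                s1 = 1.0 / (1.0 + np.exp(-arg))
            arg2 = (fn - 6.835e-14) / 1.367e-15
            if arg2 > 40.0:
                s2 = 1.0
            elif arg2 < -40.0:
                s2 = 0.0
            else:
                s2 = 1.0 / (1.0 + np.exp(-arg2))
            u_inf = s1
            v_inf = 1.0 - s2
            tau_v = 1.91 + 2.09 * s1
            # exp(-dt/tau_v) via 2nd-order Taylor; dt/tau_v <= ~0.01 here
            q = dt / tau_v
            k_v = q - 0.5 * q * q

            # Rush-Larsen gate updates (table gates)
            S[1, i] = m + (r0[COL_INF + 0] + fr * (r1[COL_INF + 0] - r0[COL_INF + 0]) - m) * (
                1.0 - (r0[COL_RLF + 0] + fr * (r1[COL_RLF + 0] - r0[COL_RLF + 0])))
            S[2, i] = h + (r0[COL_INF + 1] + fr * (r1[COL_INF + 1] - r0[COL_INF + 1]) - h) * (
                1.0 - (r0[COL_RLF + 1] + fr * (r1[COL_RLF + 1] - r0[COL_RLF + 1])))
            S[3, i] = jj + (r0[COL_INF + 2] + fr * (r1[COL_INF + 2] - r0[COL_INF + 2]) - jj) * (
                1.0 - (r0[COL_RLF + 2] + fr * (r1[COL_RLF + 2] - r0[COL_RLF + 2])))
            S[4, i] = oa + (r0[COL_INF + 3] + fr * (r1[COL_INF + 3] - r0[COL_INF + 3]) - oa) * (
                1.0 - (r0[COL_RLF + 3] + fr * (r1[COL_RLF + 3] - r0[COL_RLF + 3])))
            S[5, i] = oi + (r0[COL_INF + 4] + fr * (r1[COL_INF + 4] - r0[COL_INF + 4]) - oi) * (
                1.0 - (r0[COL_RLF + 4] + fr * (r1[COL_RLF + 4] - r0[COL_RLF + 4])))
            S[6, i] = ua + (r0[COL_INF + 5] + fr * (r1[COL_INF + 5] - r0[COL_INF + 5]) - ua) * (
                1.0 - (r0[COL_RLF + 5] + fr * (r1[COL_RLF + 5] - r0[COL_RLF + 5])))
            S[7, i] = ui + (r0[COL_INF + 6] + fr * (r1[COL_INF + 6] - r0[COL_INF + 6]) - ui) * (
                1.0 - (r0[COL_RLF + 6] + fr * (r1[COL_RLF + 6] - r0[COL_RLF + 6])))
            S[8, i] = xr + (r0[COL_INF + 7] + fr * (r1[COL_INF + 7] - r0[COL_INF + 7]) - xr) * (
                1.0 - (r0[COL_RLF + 7] + fr * (r1[COL_RLF + 7] - r0[COL_RLF + 7])))
            S[9, i] = xs + (r0[COL_INF + 8] + fr * (r1[COL_INF + 8] - r0[COL_INF + 8]) - xs) * (
                1.0 - (r0[COL_RLF + 8] + fr * (r1[COL_RLF + 8] - r0[COL_RLF + 8])))
            S[10, i] = d + (r0[COL_INF + 9] + fr * (r1[COL_INF + 9] - r0[COL_INF + 9]) - d) * (
                1.0 - (r0[COL_RLF + 9] + fr * (r1[COL_RLF + 9] - r0[COL_RLF + 9])))
            S[11, i] = f + (r0[COL_INF + 10] + fr * (r1[COL_INF + 10] - r0[COL_INF + 10]) - f) * (
                1.0 - (r0[COL_RLF + 10] + fr * (r1[COL_RLF + 10] - r0[COL_RLF + 10])))
            S[15, i] = w + (r0[COL_INF + 11] + fr * (r1[COL_INF + 11] - r0[COL_INF + 11]) - w) * (
                1.0 - (r0[COL_RLF + 11] + fr * (r1[COL_RLF + 11] - r0[COL_RLF + 11])))

            # Ca-/Fn-dependent gates
            fca_inf = 1.0 / (1.0 + cai / 0.00035)
            S[12, i] = fca + (fca_inf - fca) * k_fca
            S[13, i] = u + (u_inf - u) * k_u
            S[14, i] = vv + (v_inf - vv) * k_v

            # intracellular concentrations (forward Euler)
            iup = c.I_UP_MAX / (1.0 + c.K_UP / cai)
            iupleak = c.I_UP_MAX * caup / c.CA_UP_MAX
            itr = (caup - carel) / c.TAU_TR
            S[16, i] = nai + dt * conc_fac * (-3.0 * inak - 3.0 * inaca - ibna - ina)
            S[17, i] = ki + dt * conc_fac * (
                2.0 * inak - ik1 - ito - ikur - ikr - iks - ikach
            )
            b1 = (2.0 * inaca - ipca - ical - ibca) / (2.0 * c.FARADAY * c.V_I) + (
                c.V_UP * (iupleak - iup) + irel * c.V_REL
            ) / c.V_I
            b2 = (
                1.0
                + c.TRPN_MAX * c.KM_TRPN / ((cai + c.KM_TRPN) * (cai + c.KM_TRPN))
                + c.CMDN_MAX * c.KM_CMDN / ((cai + c.KM_CMDN) * (cai + c.KM_CMDN))
            )
            S[18, i] = cai + dt * b1 / b2
            S[19, i] = caup + dt * (iup - iupleak - itr * c.V_REL / c.V_UP)
            S[20, i] = carel + dt * (itr - irel) / (
                1.0 + c.CSQN_MAX * c.KM_CSQN / ((carel + c.KM_CSQN) * (carel + c.KM_CSQN))
            )

            # membrane potential: reaction + stimulus + diffusion
            v_new = v0 + dt * (-iion / c.CM - istim[i]) + a_diff * lap[i]
            if v0 < _ACT_THRESHOLD and v_new >= _ACT_THRESHOLD:
                last_act[i] = t_now
            S[0, i] = v_new

    # NaN guard (checked once per chunk; cheap relative to the loop)
    for i in range(n):
        if not np.isfinite(S[0, i]):
            return 1 + i
    return 0
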