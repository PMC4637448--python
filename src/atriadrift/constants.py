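"""Physical constants and parameters of the Courtemanche–Ramirez–Nattel (CRN)
human atrial myocyte model, in the model's original units.

Units convention used throughout the package: membrane potential in mV, time in
ms, membrane currents in pA (conductances in nS/pF are multiplied by the cell
capacitance CM), concentrations in mM, volumes in um^3, lengths in mm.
"""

# thermodynamics
R_GAS = 8.3143          # J / (mol K)
TEMP = 310.0            # K
FARADAY = 96.4867       # C / mmol
RTF = R_GAS * TEMP / FARADAY  # mV, ~26.71

# cell geometry / capacitance
CM = 100.0              # pF
V_CELL = 20100.0        # um^3
V_I = 13668.0           # um^3, intracellular (myoplasm)
V_UP = 1109.52          # um^3, SR uptake compartment
V_REL = 96.48           # um^3, SR release compartment

# extracellular concentrations (mM)
K_O = 5.4
NA_O = 140.0
CA_O = 1.8

# maximum conductances (nS/pF)
G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375

# pumps / exchangers
I_NAK_MAX = 0.59933874  # pA/pF
KM_NA_I = 10.0          # mM
KM_K_O = 1.5            # mM
I_NACA_MAX = 1600.0     # pA/pF
KM_NA = 87.5            # mM
KM_CA = 1.38            # mM
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275       # pA/pF

# SR calcium handling
K_REL = 30.0            # 1/ms
I_UP_MAX = 0.005        # mM/ms
K_UP = 0.00092          # mM
CA_UP_MAX = 15.0        # mM
TAU_TR = 180.0          # ms
TAU_U = 8.0             # ms
TAU_F_CA = 2.0          # ms

# calcium buffers (mM)
CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

# Q10 factor applied to the transient-outward / ultrarapid gate kinetics
K_Q10 = 3.0

# I_KACh (acetylcholine-activated K+ current) constants.  The activation
# exponent is configurable; 0.477 is the Kneller-formulation default.
KACH_SCALE = 10.0
KACH_HALF = 9.13
KACH_EXP_DEFAULT = 0.477
CACH_BASE = 0.052
CACH_AMP = 0.45
CACH_VHALF = -59.53
CACH_SLOPE = 17.18

# published CRN resting steady state (control model, quiescent)
REST_STATE = {
    "V": -81.18,
    "m": 2.908e-3,
    "h": 9.649e-1,
    "j": 9.775e-1,
    "oa": 3.043e-2,
    "oi": 9.992e-1,
    "ua": 4.966e-3,
    "ui": 9.986e-1,
    "xr": 3.296e-5,
    "xs": 1.869e-2,
    "d": 1.367e-4,
    "f": 9.996e-1,
    "fca": 7.755e-1,
    "u": 0.0,
    "v": 1.0,
    "w": 9.992e-1,
    "Na_i": 1.117e1,
    "K_i": 1.39e2,
    "Ca_i": 1.013e-4,
    "Ca_up": 1.488,
    "Ca_rel": 1.488,
}

# ordered state-variable names; index into the (21, n) state array
STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel",
)
N_STATE = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
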