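"""Courtemanche-Ramirez-Nattel (CRN) human atrial myocyte electrophysiology.

Equations and parameters follow the original 1998 publication of the model
(Am J Physiol 275:H301).  Currents are in pA (the model's native unit system:
conductances in nS/pF scaled by the 100 pF cell capacitance), potentials in mV,
time in ms, concentrations in mM, compartment volumes in um^3.

Gate kinetics are written as singularity-safe, numpy-vectorised functions so a
single transcription serves both the adaptive reference right-hand side and the
lookup tables of the fast fixed-step kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np

__all__ = [
    "CellParameters",
    "BASE_PARAMETERS",
    "GATE_NAMES",
    "gate_inf_tau",
    "crn_currents",
    "initial_electro_state",
]

# physical constants and fixed CRN environment
R_GAS = 8.3143          # J/(mol K)
TEMP = 310.0            # K (37 C)
FARADAY = 96.4867       # C/mmol
RTF = R_GAS * TEMP / FARADAY

NA_O = 140.0            # mM
K_O = 5.4
CA_O = 1.8

V_CELL = 20100.0        # um^3
CA_UP_MAX = 15.0        # mM, NSR saturation
CSQN_MAX = 10.0         # mM, calsequestrin capacity (JSR)
KM_CSQN = 0.8
TRPN_MAX = 0.070        # mM; retained for the uncoupled (EP-only) model
KM_TRPN = 0.0005
K_Q10 = 3.0             # tau scaling for the Ito / IKur gates
TAU_TR = 180.0          # ms, NSR->JSR transfer
TAU_F_CA = 2.0          # ms
TAU_U = 8.0             # ms
K_M_NA_I = 10.0         # mM, NaK
K_M_K_O = 1.5
K_M_NA = 87.5           # NCX
K_M_CA = 1.38
K_SAT = 0.1
GAMMA_NCX = 0.35


@dataclass(frozen=True)
class CellParameters:
    """Maximal conductances/fluxes and geometry for one cell variant.

    Conductances in nS/pF; ``g_Kur_scale`` scales the model's voltage-dependent
    IKur conductance curve.  ``k_leak`` is the SR leak rate per mM of NSR load
    (base value I_up_max / Ca_up_max).  Volumes in um^3, capacitance in pF.
    """

    g_Na: float = 7.8
    g_to: float = 0.1652
    g_CaL: float = 0.12375
    g_Kr: float = 0.029411765
    g_Ks: float = 0.12941176
    g_K1: float = 0.09
    g_Kur_scale: float = 1.0
    g_bNa: float = 0.0006744375
    g_bCa: float = 0.001131
    i_NaK_max: float = 0.59933874
    i_pCa_max: float = 0.275
    i_NaCa_max: float = 1600.0
    i_up_max: float = 0.005          # mM/ms (SERCA)
    k_rel: float = 30.0              # ms^-1 (RyR)
    k_leak: float = 0.005 / 15.0     # ms^-1 (SR leak per mM Ca_up)
    Cm: float = 100.0                # pF
    V_myo: float = 0.68 * V_CELL     # 13668 um^3
    V_nsr: float = 0.0552 * V_CELL   # 1109.52 um^3
    V_jsr: float = 0.0048 * V_CELL   # 96.48 um^3
    cmdn_max: float = 0.050          # mM
    km_cmdn: float = 0.00238         # mM
    F_const: float = FARADAY

    def validate(self) -> "CellParameters":
        for name, value in asdict(self).items():
            if value <= 0.0:
                raise ValueError(f"CellParameters.{name} must be strictly positive, got {value}")
        return self

    def scaled(self, **factors) -> "CellParameters":
        """Return a copy with named fields multiplied by the given factors."""
        updates = {k: getattr(self, k) * v for k, v in factors.items()}
        return replace(self, **updates)


BASE_PARAMETERS = CellParameters()

# gate ordering shared by the reference RHS, the kernel lookup tables and the
# state-vector layout (indices 1..12 of the electro block)
GATE_NAMES = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "w")


def _safe_ratio(num, den, limit, width=1e-6):
    """num/den with the removable singularity at den ~ 0 replaced by its limit."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < width
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def gate_inf_tau(V):
    """Steady states and time constants of the 12 voltage-dependent gates.

    Returns ``(inf, tau)``, each an array of shape ``V.shape + (12,)`` ordered
    as GATE_NAMES.  All removable singularities are handled by their limits.
    """
    V = np.asarray(V, dtype=float)
    inf = np.empty(V.shape + (12,))
    tau = np.empty(V.shape + (12,))

    # m
    a_m = _safe_ratio(0.32 * (V + 47.13), 1.0 - np.exp(-0.1 * (V + 47.13)), 3.2)
    b_m = 0.08 * np.exp(-V / 11.0)
    inf[..., 0] = a_m / (a_m + b_m)
    tau[..., 0] = 1.0 / (a_m + b_m)

    # h, j (piecewise at -40 mV)
    below = V < -40.0
    a_h = np.where(below, 0.135 * np.exp(-(V + 80.0) / 6.8), 0.0)
    b_h = np.where(
        below,
        3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
        1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
    )
    inf[..., 1] = a_h / (a_h + b_h)
    tau[..., 1] = 1.0 / (a_h + b_h)

    a_j = np.where(
        below,
        (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78)
        / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0,
    )
    b_j = np.where(
        below,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )
    inf[..., 2] = a_j / (a_j + b_j)
    tau[..., 2] = 1.0 / (a_j + b_j)

    # oa, oi (Ito), with the Q10 tau scaling
    a_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    inf[..., 3] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    tau[..., 3] = 1.0 / ((a_oa + b_oa) * K_Q10)

    a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    inf[..., 4] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    tau[..., 4] = 1.0 / ((a_oi + b_oi) * K_Q10)

    # ua, ui (IKur)
    a_ua = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    inf[..., 5] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    tau[..., 5] = 1.0 / ((a_ua + b_ua) * K_Q10)

    a_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    b_ui = np.exp((V - 158.0) / 16.0)
    inf[..., 6] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
    tau[..., 6] = 1.0 / ((a_ui + b_ui) * K_Q10)

    # xr (IKr)
    a_xr = _safe_ratio(0.0003 * (V + 14.1), 1.0 - np.exp(-(V + 14.1) / 5.0), 0.0015)
    b_xr = _safe_ratio(
        7.3898e-5 * (V - 3.3328), np.exp((V - 3.3328) / 5.1237) - 1.0, 7.3898e-5 * 5.1237
    )
    inf[..., 7] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    tau[..., 7] = 1.0 / (a_xr + b_xr)

    # xs (IKs)
    a_xs = _safe_ratio(4e-5 * (V - 19.9), 1.0 - np.exp(-(V - 19.9) / 17.0), 4e-5 * 17.0)
    b_xs = _safe_ratio(3.5e-5 * (V - 19.9), np.exp((V - 19.9) / 9.0) - 1.0, 3.5e-5 * 9.0)
    inf[..., 8] = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
    tau[..., 8] = 0.5 / (a_xs + b_xs)

    # d, f (ICaL)
    ed = np.exp(-(V + 10.0) / 6.24)
    inf[..., 9] = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
    tau[..., 9] = _safe_ratio(
        1.0 - ed, 0.035 * (V + 10.0) * (1.0 + ed), 1.0 / (0.035 * 6.24 * 2.0)
    )
    inf[..., 10] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    tau[..., 10] = 9.0 / (0.0197 * np.exp(-(0.0337**2) * (V + 10.0) ** 2) + 0.02)

    # w (RyR voltage gate)
    ew = np.exp(-(V - 7.9) / 5.0)
    inf[..., 11] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    tau[..., 11] = _safe_ratio(
        6.0 * (1.0 - ew), (1.0 + 0.3 * ew) * (V - 7.9), 6.0 * 0.2 / 1.3
    )

    return inf, tau


def f_ca_inf(Cai):
    return 1.0 / (1.0 + Cai / 0.00035)


def nernst(z_conc_out, conc_in, z=1):
    return RTF / z * np.log(z_conc_out / conc_in)


def crn_currents(V, gates, Nai, Ki, Cai, Caup, Carel, p: CellParameters):
    """All CRN membrane currents (pA) and SR fluxes (mM/ms) at one state.

    ``gates`` is the 15-vector (m h j oa oi ua ui xr xs d f w fca u v) ordered
    as GATE_NAMES + (fca, u, v); returns a dict including the signed total
    ``I_ion`` entering Cm dV/dt = -(I_ion + I_stim).
    """
    m, h, j, oa, oi, ua, ui, xr, xs, d, f, w, fca, u, v = gates
    E_Na = nernst(NA_O, Nai)
    E_K = nernst(K_O, Ki)
    E_Ca = nernst(CA_O, Cai, z=2)
    Cm = p.Cm

    i_Na = Cm * p.g_Na * m**3 * h * j * (V - E_Na)
    i_K1 = Cm * p.g_K1 * (V - E_K) / (1.0 + np.exp(0.07 * (V + 80.0)))
    i_to = Cm * p.g_to * oa**3 * oi * (V - E_K)
    g_Kur = p.g_Kur_scale * (0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0)))
    i_Kur = Cm * g_Kur * ua**3 * ui * (V - E_K)
    i_Kr = Cm * p.g_Kr * xr * (V - E_K) / (1.0 + np.exp((V + 15.0) / 22.4))
    i_Ks = Cm * p.g_Ks * xs**2 * (V - E_K)
    i_CaL = Cm * p.g_CaL * d * f * fca * (V - 65.0)

    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    f_NaK = 1.0 / (
        1.0 + 0.1245 * np.exp(-0.1 * V / RTF) + 0.0365 * sigma * np.exp(-V / RTF)
    )
    i_NaK = (
        Cm
        * p.i_NaK_max
        * f_NaK
        * (1.0 / (1.0 + (K_M_NA_I / Nai) ** 1.5))
        * (K_O / (K_O + K_M_K_O))
    )
    i_NaCa = (
        Cm
        * p.i_NaCa_max
        * (
            np.exp(GAMMA_NCX * V / RTF) * Nai**3 * CA_O
            - np.exp((GAMMA_NCX - 1.0) * V / RTF) * NA_O**3 * Cai
        )
        / (
            (K_M_NA**3 + NA_O**3)
            * (K_M_CA + CA_O)
            * (1.0 + K_SAT * np.exp((GAMMA_NCX - 1.0) * V / RTF))
        )
    )
    i_bNa = Cm * p.g_bNa * (V - E_Na)
    i_bCa = Cm * p.g_bCa * (V - E_Ca)
    i_pCa = Cm * p.i_pCa_max * Cai / (0.0005 + Cai)

    # SR fluxes (mM/ms, per their respective compartment volumes)
    i_rel = p.k_rel * u**2 * v * w * (Carel - Cai)
    i_up = p.i_up_max / (1.0 + 0.00092 / Cai)
    i_up_leak = p.k_leak * Caup
    i_tr = (Caup - Carel) / TAU_TR

    i_ion = (
        i_Na + i_K1 + i_to + i_Kur + i_Kr + i_Ks + i_CaL
        + i_pCa + i_NaK + i_NaCa + i_bNa + i_bCa
    )
    return {
        "I_Na": i_Na, "I_K1": i_K1, "I_to": i_to, "I_Kur": i_Kur, "I_Kr": i_Kr,
        "I_Ks": i_Ks, "I_CaL": i_CaL, "I_NaK": i_NaK, "I_NaCa": i_NaCa,
        "I_bNa": i_bNa, "I_bCa": i_bCa, "I_pCa": i_pCa,
        "J_rel": i_rel, "J_up": i_up, "J_leak": i_up_leak, "J_tr": i_tr,
        "I_ion": i_ion,
    }


# Published CRN resting-state initial conditions (quiescent steady state).
INITIAL_V = -81.18
INITIAL_GATES = {
    "m": 2.908e-3, "h": 9.649e-1, "j": 9.775e-1,
    "oa": 3.043e-2, "oi": 9.992e-1,
    "ua": 4.966e-3, "ui": 9.986e-1,
    "xr": 8.696e-5, "xs": 1.869e-2,
    "d": 1.367e-4, "f": 9.996e-1, "w": 9.992e-1,
    "fca": 7.755e-1, "u": 0.0, "v": 1.0,
}
INITIAL_CONCENTRATIONS = {
    "Nai": 1.117e1, "Ki": 1.390e2, "Cai": 1.013e-4,
    "Caup": 1.488, "Carel": 1.488,
}


def initial_electro_state():
    """(V, gates[15], concentrations[5]) at the published rest state."""
    gates = np.array([INITIAL_GATES[g] for g in GATE_NAMES + ("fca", "u", "v")])
    conc = np.array([INITIAL_CONCENTRATIONS[c] for c in ("Nai", "Ki", "Cai", "Caup", "Carel")])
    return INITIAL_V, gates, conc
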