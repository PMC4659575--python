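"""Reference right-hand side of the coupled electromechanical cell.

This is the readable, adaptive-solver-friendly formulation used with
scipy.integrate.solve_ivp (stiff BDF/LSODA); the production path is the
fixed-step Rush-Larsen kernel in ``kernel.py``, which is cross-checked against
this one in the test suite.

The electromechanical coupling replaces the instantaneous troponin buffer of
the electrophysiology model's Ca2+ balance with the dynamic troponin binding
of the myofilament model:

  dCai/dt = b(Cai) * [ Cm(2 I_NaCa - I_CaL - I_bCa - I_pCa)/(2 V_myo F)
                       + (V_nsr (J_leak - J_up) + J_rel V_jsr)/V_myo
                       - dTropCa/dt * 1/1000 ]

with b the instantaneous calmodulin buffering factor
1/(1 + CMDN_max K_CMDN/(Cai + K_CMDN)^2), Cai in mM and dTropCa/dt in uM/ms.
"""

from __future__ import annotations

import numpy as np

from ..ionic.crn import (
    CellParameters,
    TAU_F_CA,
    TAU_U,
    CSQN_MAX,
    KM_CSQN,
    TRPN_MAX,
    KM_TRPN,
    crn_currents,
    gate_inf_tau,
    f_ca_inf,
)
from ..myofilament.rice import RiceParameters, myofilament_derivatives
from .state import (
    I_V,
    I_NAI,
    I_KI,
    I_CAI,
    I_CAUP,
    I_CAREL,
    I_MF,
    N_STATES,
)

__all__ = ["coupled_calcium_derivative", "coupled_rhs", "cell_rhs_factory"]


def _buffer_factor(Cai: float, p: CellParameters) -> float:
    return 1.0 / (1.0 + p.cmdn_max * p.km_cmdn / (Cai + p.km_cmdn) ** 2)


def coupled_calcium_derivative(
    currents: dict,
    dTropCa_dt: float,
    Cai: float,
    p: CellParameters,
) -> float:
    """d[Ca2+]_i/dt (mM/ms) of the coupled Ca balance.

    ``currents`` holds the membrane currents (pA) and SR fluxes (mM/ms) as
    returned by ``crn_currents``; ``dTropCa_dt`` is the troponin binding rate
    in uM/ms (converted to mM by the 1/1000 factor).
    """
    for key in ("I_CaL", "I_bCa", "I_pCa", "I_NaCa", "J_leak", "J_up", "J_rel"):
        if not np.isfinite(currents[key]):
            raise ValueError(f"non-finite current {key}")
    if not np.isfinite(dTropCa_dt):
        raise ValueError("non-finite troponin binding rate")
    # the printed balance carries a Cm factor because its currents are per
    # unit capacitance (pA/pF); crn_currents returns whole-cell pA, so the
    # factor is already included
    sarcolemmal = (
        2.0 * currents["I_NaCa"] - currents["I_CaL"] - currents["I_bCa"] - currents["I_pCa"]
    ) / (2.0 * p.V_myo * p.F_const)
    sr = (
        p.V_nsr * (currents["J_leak"] - currents["J_up"])
        + currents["J_rel"] * p.V_jsr
    ) / p.V_myo
    return _buffer_factor(Cai, p) * (sarcolemmal + sr - dTropCa_dt / 1000.0)


def coupled_rhs(
    t: float,
    y: np.ndarray,
    p: CellParameters,
    rice: RiceParameters,
    stim,
    mode: str = "cell",
    coupled: bool = True,
) -> np.ndarray:
    """Full time derivative of the 30-state coupled cell.

    ``stim(t)`` returns the applied depolarising stimulus amplitude (pA,
    positive = depolarising).  With ``coupled=False`` the electrophysiology
    model's original instantaneous-troponin Ca balance is used instead of the
    myofilament feedback (pure EP reference mode; the myofilament still *sees*
    Cai but does not act back on it).
    """
    dy = np.zeros(N_STATES)
    V = y[I_V]
    gates = y[1:16]
    Nai, Ki, Cai, Caup, Carel = y[I_NAI], y[I_KI], y[I_CAI], y[I_CAUP], y[I_CAREL]

    cur = crn_currents(V, gates, Nai, Ki, Cai, Caup, Carel, p)

    # membrane potential; stimulus applied as inward (depolarising) current
    i_stim = -float(stim(t)) if stim is not None else 0.0
    dy[I_V] = -(cur["I_ion"] + i_stim) / p.Cm

    # voltage gates
    inf, tau = gate_inf_tau(V)
    dy[1:13] = (inf - gates[:12]) / tau
    # fca, u, v
    fca, u, v = gates[12], gates[13], gates[14]
    dy[13] = (f_ca_inf(Cai) - fca) / TAU_F_CA
    Fn = 1e3 * (1e-15 * p.V_jsr * cur["J_rel"]
                - (1e-15 / (2.0 * p.F_const)) * (0.5 * cur["I_CaL"] - 0.2 * cur["I_NaCa"]))
    u_inf = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    dy[14] = (u_inf - u) / TAU_U
    dy[15] = (v_inf - v) / tau_v

    # ion concentrations
    FVi = p.F_const * p.V_myo
    dy[I_NAI] = (-3.0 * cur["I_NaK"] - 3.0 * cur["I_NaCa"] - cur["I_bNa"] - cur["I_Na"]) / FVi
    dy[I_KI] = (
        2.0 * cur["I_NaK"] - cur["I_K1"] - cur["I_to"] - cur["I_Kur"]
        - cur["I_Kr"] - cur["I_Ks"]
    ) / FVi
    dy[I_CAUP] = cur["J_up"] - cur["J_leak"] - cur["J_tr"] * p.V_jsr / p.V_nsr
    dy[I_CAREL] = (cur["J_tr"] - cur["J_rel"]) / (
        1.0 + CSQN_MAX * KM_CSQN / (Carel + KM_CSQN) ** 2
    )

    # myofilament (uM, s) and the Ca balance
    mf = y[I_MF]
    dmf, _force, dTropTot_per_s = myofilament_derivatives(mf, Cai * 1e3, rice, mode)
    dy[I_MF] = dmf / 1e3  # per second -> per ms

    if coupled:
        dy[I_CAI] = coupled_calcium_derivative(cur, dTropTot_per_s / 1e3, Cai, p)
    else:
        b1 = (
            (2.0 * cur["I_NaCa"] - cur["I_pCa"] - cur["I_CaL"] - cur["I_bCa"])
            / (2.0 * p.V_myo * p.F_const)
            + (p.V_nsr * (cur["J_leak"] - cur["J_up"]) + cur["J_rel"] * p.V_jsr) / p.V_myo
        )
        b2 = (
            1.0
            + TRPN_MAX * KM_TRPN / (Cai + KM_TRPN) ** 2
            + p.cmdn_max * p.km_cmdn / (Cai + p.km_cmdn) ** 2
        )
        dy[I_CAI] = b1 / b2

    return dy


def cell_rhs_factory(p, rice, stim=None, mode="cell", coupled=True):
    """Bind parameters into an f(t, y) suitable for scipy.integrate.solve_ivp."""
    def rhs(t, y):
        return coupled_rhs(t, y, p, rice, stim, mode=mode, coupled=coupled)
    return rhs
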