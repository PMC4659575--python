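"""Total-calcium bookkeeping for the coupled cell.

The only pathway for Ca2+ in or out of the cell is the sarcolemma
(I_CaL, I_bCa, I_pCa and the exchanger), so over any interval the change of
the total cell Ca2+ content — free cytosolic + calmodulin-bound +
troponin-bound + volume-weighted SR free and calsequestrin-bound — must equal
the time-integral of the sarcolemmal flux.  This module recomputes both sides
independently along a simulated beat.
"""

from __future__ import annotations

import numpy as np

from ..ionic.crn import CellParameters, crn_currents, CSQN_MAX, KM_CSQN
from ..myofilament.rice import RiceParameters, trop_total
from .state import I_MF
from .kernel import build_lut, pack_params, cell_step

__all__ = ["total_calcium", "calcium_bookkeeping"]


def total_calcium(y: np.ndarray, p: CellParameters, rice: RiceParameters) -> float:
    """Total cell Ca2+ content in mM * um^3 (amount units of the model)."""
    Cai, Caup, Carel = y[18], y[19], y[20]
    cmdn = p.cmdn_max * Cai / (Cai + p.km_cmdn)
    csqn = CSQN_MAX * Carel / (Carel + KM_CSQN)
    trop_mM = trop_total(y[I_MF], rice) / 1000.0
    return (
        p.V_myo * (Cai + cmdn + trop_mM)
        + p.V_nsr * Caup
        + p.V_jsr * (Carel + csqn)
    )


def calcium_bookkeeping(
    y0: np.ndarray,
    p: CellParameters,
    rice: RiceParameters,
    duration: float = 1000.0,
    dt: float = 0.01,
    stim_amp: float = 4000.0,
    stim_dur: float = 2.0,
    sample_every: int = 1,
) -> dict:
    """Integrate one stimulated beat and close the Ca budget.

    Returns the content change, the trapezoid integral of the sarcolemmal
    flux, their residual, and the peak-to-peak swing of the cytosolic content
    (the natural transient-amplitude scale for the closure error).
    """
    pv = pack_params(p, rice)
    lut, aux = build_lut(dt)
    y = np.array(y0, dtype=float)
    n_steps = int(round(duration / dt))

    def sarcolemmal_flux(state):
        cur = crn_currents(state[0], state[1:16], state[16], state[17],
                           state[18], state[19], state[20], p)
        return (2.0 * cur["I_NaCa"] - cur["I_CaL"] - cur["I_bCa"] - cur["I_pCa"]) / (
            2.0 * p.F_const
        )

    total_start = total_calcium(y, p, rice)
    fluxes = [sarcolemmal_flux(y)]
    cyto = []
    for k in range(n_steps):
        t = k * dt
        amp = stim_amp if t < stim_dur else 0.0
        cell_step(y, pv, lut, aux, dt, amp)
        if (k + 1) % sample_every == 0:
            fluxes.append(sarcolemmal_flux(y))
            Cai = y[18]
            cmdn = p.cmdn_max * Cai / (Cai + p.km_cmdn)
            cyto.append(p.V_myo * (Cai + cmdn + trop_total(y[I_MF], rice) / 1000.0))
    total_end = total_calcium(y, p, rice)

    h = dt * sample_every
    integral = float(np.trapezoid(fluxes, dx=h))
    delta = total_end - total_start
    cyto = np.asarray(cyto)
    return {
        "delta_content": delta,
        "flux_integral": integral,
        "residual": delta - integral,
        "cytosolic_swing": float(cyto.max() - cyto.min()),
        "final_state": y,
    }
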