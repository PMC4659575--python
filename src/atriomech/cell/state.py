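"""State-vector layout of the coupled electromechanical cell.

A single flat float64 vector carries the electrophysiology (membrane potential,
15 gates, 5 concentrations) followed by the myofilament state; the same layout
is used by the reference SciPy integrator, the fast fixed-step kernel and the
tissue solver.
"""

from __future__ import annotations

import numpy as np

from ..ionic.crn import GATE_NAMES, initial_electro_state
from ..myofilament.rice import (
    MF_STATE_NAMES,
    RiceParameters,
    initial_myofilament_state,
)

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "IDX",
    "initial_state",
    "check_state",
]

STATE_NAMES = (
    ("V",)
    + GATE_NAMES
    + ("fca", "u", "v")
    + ("Nai", "Ki", "Cai", "Caup", "Carel")
    + MF_STATE_NAMES
)
N_STATES = len(STATE_NAMES)  # 30
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

I_V = IDX["V"]
I_GATES = slice(1, 16)          # 12 voltage gates + fca, u, v
I_NAI, I_KI, I_CAI = IDX["Nai"], IDX["Ki"], IDX["Cai"]
I_CAUP, I_CAREL = IDX["Caup"], IDX["Carel"]
I_MF = slice(IDX["N"], IDX["intf"] + 1)
I_SL = IDX["SL"]


def initial_state(rice_params: RiceParameters | None = None) -> np.ndarray:
    """Published electrophysiology rest state + myofilament rest state."""
    V, gates, conc = initial_electro_state()
    mf = initial_myofilament_state(rice_params, Ca_uM=conc[2] * 1e3)
    y = np.empty(N_STATES)
    y[I_V] = V
    y[I_GATES] = gates
    y[I_NAI:I_CAREL + 1] = conc
    y[I_MF] = mf
    return y


def check_state(y: np.ndarray) -> None:
    """Raise on non-finite entries, gates outside [0,1] or non-positive
    concentrations (the model invariants)."""
    y = np.asarray(y)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite cell state")
    gates = y[I_GATES]
    if np.any(gates < -1e-9) or np.any(gates > 1.0 + 1e-9):
        bad = [STATE_NAMES[1 + i] for i in np.where((gates < -1e-9) | (gates > 1 + 1e-9))[0]]
        raise ValueError(f"gating variables out of [0,1]: {bad}")
    conc = y[I_NAI:I_CAREL + 1]
    if np.any(conc <= 0):
        raise ValueError("non-positive ionic concentration")
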