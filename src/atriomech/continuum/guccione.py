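"""Guccione transversely isotropic strain energy and its stress.

W(Ee) = C1 * exp(Q),  Q = C2*E11^2 + C3*(E22^2 + E33^2 + E23^2)
                          + 2*C4*(E12*E21 + E13*E31),

with E expressed in an orthonormal frame whose first axis is the fibre
direction.  Defaults are the passive human-myocardium fit C1 = 0.831 kPa,
C2 = 14.31, C3 = 4.49, C4 = 10 (C2..C4 dimensionless).

The second Piola-Kirchhoff stress is S = dW/dEe - p * Ce^-1 with the
hydrostatic pressure p acting as the incompressibility Lagrange multiplier.
dW/dEe is taken in the symmetric-tensor sense: W is regarded as a function of
the symmetrised argument, S_ij = dW/dE_ij of that symmetrised function, which
is what a finite-difference derivative of ``energy`` reproduces entry-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import fibre_frame

__all__ = ["GuccioneParameters", "guccione_energy", "second_pk_stress"]


@dataclass(frozen=True)
class GuccioneParameters:
    C1: float = 0.831  # kPa
    C2: float = 14.31
    C3: float = 4.49
    C4: float = 10.0

    def __post_init__(self):
        for name in ("C1", "C2", "C3", "C4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Guccione parameter {name} must be positive")


def _to_fibre_frame(E: np.ndarray, f) -> np.ndarray:
    E = 0.5 * (np.asarray(E, dtype=float) + np.asarray(E, dtype=float).T)
    if f is None:
        return E
    R = fibre_frame(f)  # rows are the frame axes
    return R @ E @ R.T


def _Q(E: np.ndarray, p: GuccioneParameters) -> float:
    # E is symmetric, so E12*E21 = E12^2 etc.
    return (
        p.C2 * E[0, 0] ** 2
        + p.C3 * (E[1, 1] ** 2 + E[2, 2] ** 2 + E[1, 2] ** 2)
        + 2.0 * p.C4 * (E[0, 1] * E[1, 0] + E[0, 2] * E[2, 0])
    )


def guccione_energy(Ee: np.ndarray, params: GuccioneParameters | None = None, f=None) -> float:
    """Strain energy density W = C1 exp(Q) in kPa.

    ``Ee`` is the elastic Green-Lagrange strain; if ``f`` is given, ``Ee`` is
    first rotated into the fibre frame (axis 1 = f), otherwise axis 1 of the
    supplied tensor is taken to already be the fibre axis.
    """
    params = params or GuccioneParameters()
    E = _to_fibre_frame(Ee, f)
    return params.C1 * np.exp(_Q(E, params))


def second_pk_stress(
    Ee: np.ndarray,
    params: GuccioneParameters | None = None,
    p: float = 0.0,
    f=None,
) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = dW/dEe - p Ce^-1 (kPa).

    Returned in the same frame the strain was supplied in.
    """
    params = params or GuccioneParameters()
    R = None if f is None else fibre_frame(f)
    E = _to_fibre_frame(Ee, f)
    W = params.C1 * np.exp(_Q(E, params))
    # dQ/dE of the symmetrised energy, entry-wise in the fibre frame
    dQ = np.zeros((3, 3))
    dQ[0, 0] = 2.0 * params.C2 * E[0, 0]
    dQ[1, 1] = 2.0 * params.C3 * E[1, 1]
    dQ[2, 2] = 2.0 * params.C3 * E[2, 2]
    dQ[1, 2] = dQ[2, 1] = params.C3 * E[1, 2]
    dQ[0, 1] = dQ[1, 0] = 2.0 * params.C4 * E[0, 1]
    dQ[0, 2] = dQ[2, 0] = 2.0 * params.C4 * E[0, 2]
    S = W * dQ
    if p != 0.0:
        Ce = 2.0 * E + np.eye(3)
        S = S - p * np.linalg.inv(Ce)
    if R is not None:
        S = R.T @ S @ R
    return S
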