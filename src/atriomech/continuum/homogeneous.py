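"""Homogeneous incompressible active contraction of a tissue block.

The two-field (deformation, pressure) variational problem reduces, for a
traction-free homogeneous block with fibres along axis 1, to a scalar
minimisation: F = diag(lf, lt, lt) with lt = lf^(-1/2) (exact incompressibility
det F = 1 eliminates the pressure algebraically), and the equilibrium stretch
minimises the Guccione energy of the elastic part Fe = F F0(gamma)^-1.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .guccione import GuccioneParameters, guccione_energy
from .kinematics import active_deformation, elastic_strains

__all__ = ["block_energy", "uniaxial_active_contraction"]

_FIBRE = np.array([1.0, 0.0, 0.0])


def block_energy(lam_f: float, gamma: float, params: GuccioneParameters | None = None) -> float:
    """Elastic energy density of the incompressible block at fibre stretch lam_f."""
    if lam_f <= 0:
        raise ValueError("fibre stretch must be positive")
    lam_t = lam_f ** -0.5
    F = np.diag([lam_f, lam_t, lam_t])
    F0 = active_deformation(gamma, _FIBRE)
    _, _, Ee = elastic_strains(F, F0)
    return guccione_energy(Ee, params)


def uniaxial_active_contraction(
    gamma: float,
    params: GuccioneParameters | None = None,
    bracket: tuple[float, float] = (0.5, 1.5),
    xatol: float = 1e-10,
):
    """Equilibrium stretches (lam_f, lam_t) of a traction-free active block.

    For gamma < 0 the fibre direction shortens (lam_f < 1) and the transverse
    directions bulge (lam_t > 1) by incompressibility.
    """
    if not -0.5 < gamma < 0.5:
        raise ValueError(f"active strain gamma must lie in (-0.5, 0.5), got {gamma}")
    res = minimize_scalar(
        block_energy,
        bounds=bracket,
        args=(gamma, params),
        method="bounded",
        options={"xatol": xatol},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(
            f"equilibrium search failed in bracket {bracket}: {res.message}"
        )
    lam_f = float(res.x)
    if min(abs(lam_f - bracket[0]), abs(lam_f - bracket[1])) < 1e-6:
        raise RuntimeError(
            f"equilibrium stretch pinned at bracket edge {lam_f:.6f}; widen bracket {bracket}"
        )
    return lam_f, lam_f ** -0.5
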