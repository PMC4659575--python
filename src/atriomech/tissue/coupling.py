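"""Staggered electro-mechanics co-simulation at desk scale.

The outer loop exchanges fields every dt_mech = 1 ms: the electrophysiology
advances with the current deformation C and exports the active strain gamma
(from the per-node sarcomere length); the mechanics surrogate maps gamma to a
new right Cauchy-Green field C which feeds back into the diffusion operator
D C^-1.  The surrogate is kinematic: fibre shortening F = (1+gamma) f(x)f with
incompressible transverse compensation, preserving the exchange contract of
the full FEM problem without organ-scale elasticity.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grid import TissueGrid
from .monodomain import MonodomainSolver, TissueTrace

__all__ = ["kinematic_deformation", "project_field", "run_coupled"]


def kinematic_deformation(gamma: np.ndarray, grid: TissueGrid) -> np.ndarray:
    """Right Cauchy-Green field from a gamma field via fibre shortening.

    1D: C = (1+gamma)^2 along the cable.
    2D: C = (1+gamma)^2 f(x)f + (1+gamma)^-1 (I - f(x)f) (in-plane
    transverse compensation of an incompressible, plane-isochoric motion).
    """
    gamma = np.asarray(gamma, dtype=float).reshape(grid.shape)
    if np.any(gamma <= -1.0):
        raise ValueError("active strain gamma <= -1 is non-physical")
    lam2 = (1.0 + gamma) ** 2
    if grid.ndim == 1:
        return lam2
    f = grid.fibre
    ff = f[..., :, None] * f[..., None, :]
    eye = np.eye(2)
    return lam2[..., None, None] * ff + ((1.0 + gamma) ** -1.0)[..., None, None] * (eye - ff)


def project_field(src: TissueGrid, field: np.ndarray, dst: TissueGrid) -> np.ndarray:
    """Linear grid-to-grid projection of a nodal scalar field."""
    if src.ndim != dst.ndim:
        raise ValueError(
            f"cannot project between a {src.ndim}D and a {dst.ndim}D grid"
        )
    field = np.asarray(field, dtype=float).reshape(src.shape)
    if src.shape == dst.shape and np.isclose(src.dx, dst.dx):
        return field.copy()
    if src.ndim == 1:
        xs = src.dx * np.arange(src.shape[0])
        xd = np.clip(dst.dx * np.arange(dst.shape[0]), xs[0], xs[-1])
        return np.interp(xd, xs, field)
    ys = src.dx * np.arange(src.shape[0])
    xs = src.dx * np.arange(src.shape[1])
    interp = RegularGridInterpolator((ys, xs), field, bounds_error=False, fill_value=None)
    yd = np.clip(dst.dx * np.arange(dst.shape[0]), ys[0], ys[-1])
    xd = np.clip(dst.dx * np.arange(dst.shape[1]), xs[0], xs[-1])
    Yd, Xd = np.meshgrid(yd, xd, indexing="ij")
    return interp(np.stack([Yd.ravel(), Xd.ravel()], axis=-1)).reshape(dst.shape)


def run_coupled(
    solver: MonodomainSolver,
    t_end: float,
    stimuli=(),
    dt_mech: float = 1.0,
    coupling: str = "kinematic",
    mech_grid: TissueGrid | None = None,
) -> TissueTrace:
    """Staggered loop: EP for dt_mech with C fixed, then gamma -> C update.

    ``coupling="none"`` keeps C frozen (one-way export of gamma only).
    ``mech_grid`` routes the exchange through a coarser mechanics lattice
    (gamma projected EP->mechanics, C computed there, projected back).
    Records V and gamma fields once per dt_mech.
    """
    if coupling not in ("kinematic", "none"):
        raise ValueError(f"unknown coupling mode {coupling!r}")
    grid = solver.grid
    SL0 = solver.rice.SLset
    frames_t, frames_V, frames_g = [], [], []
    act_time = np.full(grid.n_nodes, np.nan)
    act_count = np.zeros(grid.n_nodes, dtype=np.int64)
    last_activity = -np.inf

    n_outer = int(round((t_end - solver.t) / dt_mech))
    for _ in range(n_outer):
        tr = solver.run(solver.t + dt_mech, stimuli=stimuli, record_dt=dt_mech)
        frames_t.append(tr.t[-1])
        frames_V.append(tr.V[-1])
        gamma = (solver.Y[:, 28] - SL0) / SL0
        frames_g.append(gamma.copy())
        newly = np.isnan(act_time) & ~np.isnan(tr.activation_time)
        act_time[newly] = tr.activation_time[newly]
        act_count += tr.activation_count
        last_activity = max(last_activity, tr.last_activity)

        if coupling == "kinematic":
            if mech_grid is not None:
                g_m = project_field(grid, gamma, mech_grid)
                C_m = kinematic_deformation(g_m, mech_grid)
                if mech_grid.ndim == 1:
                    C = project_field(mech_grid, C_m, grid)
                else:
                    C = np.empty(grid.shape + (2, 2))
                    for a in range(2):
                        for b in range(2):
                            C[..., a, b] = project_field(mech_grid, C_m[..., a, b], grid)
            else:
                C = kinematic_deformation(gamma, grid)
            grid.set_deformation(C)
            solver.refresh_operator()

    return TissueTrace(
        t=np.array(frames_t),
        V=np.array(frames_V),
        gamma=np.array(frames_g),
        activation_time=act_time,
        activation_count=act_count,
        last_activity=last_activity,
    )
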