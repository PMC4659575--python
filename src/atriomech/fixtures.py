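"""Synthetic geometry fixtures: cables, fibred sheets, icospheres.

Everything needed to exercise the simulator is generated programmatically —
no external data.  Stochastic fixtures (jittered fibre fields) take an
explicit seeded generator and record the seed in their spec.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import trimesh

from .tissue.grid import TissueGrid, DEFAULT_D_L, DEFAULT_D_T
from .continuum.volume import check_closed_oriented

__all__ = ["FixtureSpec", "make_cable", "make_sheet", "make_icosphere"]


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducibility record for one generated fixture."""

    kind: str
    params: tuple
    seed: int | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def make_cable(
    n_nodes: int,
    dx: float = 0.25,
    region_map=None,
    remodeling: str = "control",
    d_l: float = DEFAULT_D_L,
) -> TissueGrid:
    """1D cable; ``region_map`` may split the cable into regional segments,
    e.g. ``[(0, 50, "RA/PM"), (50, 100, "PV")]``."""
    return TissueGrid.cable(n_nodes, dx=dx, region_map=region_map,
                            remodeling=remodeling, d_l=d_l)


def make_sheet(
    nx: int,
    ny: int,
    dx: float = 0.25,
    fibre_angle: float = 0.0,
    region: str = "RA/PM",
    remodeling: str = "control",
    d_l: float = DEFAULT_D_L,
    d_t: float = DEFAULT_D_T,
    fibre_jitter: float = 0.0,
    seed: int | None = None,
) -> TissueGrid:
    """2D sheet with a uniform (optionally seeded-jittered) fibre field."""
    rng = np.random.default_rng(seed) if seed is not None else None
    grid = TissueGrid.sheet(
        nx, ny, dx=dx, fibre_angle=fibre_angle, region=region,
        remodeling=remodeling, d_l=d_l, d_t=d_t,
        fibre_jitter=fibre_jitter, rng=rng,
    )
    grid.spec = FixtureSpec(
        "sheet", (nx, ny, dx, fibre_angle, region, remodeling, fibre_jitter), seed
    )
    return grid


def make_icosphere(refinement: int = 3, radius: float = 1.0):
    """Closed, consistently outward-oriented triangulated sphere.

    refinement 0 is the 20-triangle icosahedron; each level quadruples the
    face count.  Returns ``(vertices, faces)``.
    """
    if refinement < 0:
        raise ValueError("refinement must be >= 0")
    mesh = trimesh.creation.icosphere(subdivisions=refinement, radius=radius)
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    check_closed_oriented(vertices, faces)
    return vertices, faces
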