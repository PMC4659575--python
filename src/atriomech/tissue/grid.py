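"""Regular-lattice tissue grids (1D cables, 2D fibred sheets).

Each node carries a fibre direction, a diffusion tensor D built from the
longitudinal/transverse conductivities, a right Cauchy-Green deformation
tensor C (identity when undeformed) and a cell-variant assignment
(region x remodeling).  The monodomain operator diffuses with the effective
tensor M = D C^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TissueGrid", "DEFAULT_D_L", "DEFAULT_D_T"]

# printed tissue conductivities, mm^2/ms (3:1 anisotropy ratio)
DEFAULT_D_L = 1.26
DEFAULT_D_T = 0.42


def _fibre_tensor(fibre: np.ndarray, d_l: float, d_t: float) -> np.ndarray:
    """D = d_t I + (d_l - d_t) f (x) f for unit fibre field f of shape (...,2)."""
    eye = np.eye(2)
    ff = fibre[..., :, None] * fibre[..., None, :]
    return d_t * eye + (d_l - d_t) * ff


@dataclass
class TissueGrid:
    """1D or 2D lattice with per-node tensors and cell-variant indices."""

    dx: float                     # mm
    variants: list                # [(region, remodeling), ...]
    variant_idx: np.ndarray       # int array, grid shape
    fibre: np.ndarray | None      # (..., 2) unit vectors (2D only)
    D: np.ndarray                 # (n,) for 1D; (ny, nx, 2, 2) for 2D
    C: np.ndarray = None          # same layout as D; identity default

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.dx}")
        if self.C is None:
            self.C = (
                np.ones_like(self.D)
                if self.ndim == 1
                else np.broadcast_to(np.eye(2), self.D.shape).copy()
            )
        if self.fibre is not None:
            norms = np.linalg.norm(self.fibre, axis=-1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("fibre vectors must be unit length")
        self.check_tensors()

    # --- basic geometry ---------------------------------------------------
    @property
    def ndim(self) -> int:
        return 1 if self.D.ndim == 1 else 2

    @property
    def shape(self) -> tuple:
        return self.variant_idx.shape

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    # --- tensors ----------------------------------------------------------
    def effective_tensor(self) -> np.ndarray:
        """M = D C^-1 per node; raises unless symmetric positive-definite."""
        if self.ndim == 1:
            M = self.D / self.C
            if np.any(M <= 0):
                raise ValueError("effective diffusion must be positive")
            return M
        M = np.einsum("...ij,...jk->...ik", self.D, np.linalg.inv(self.C))
        if not np.allclose(M, np.swapaxes(M, -1, -2), atol=1e-10 * np.abs(M).max()):
            raise ValueError("effective tensor D C^-1 is not symmetric")
        tr = M[..., 0, 0] + M[..., 1, 1]
        det = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
        if np.any(tr <= 0) or np.any(det <= 0):
            raise ValueError("effective tensor D C^-1 is not positive-definite")
        return M

    def check_tensors(self) -> None:
        self.effective_tensor()

    def set_deformation(self, C: np.ndarray) -> None:
        """Install a new right Cauchy-Green field (validated on next use)."""
        C = np.asarray(C, dtype=float)
        if C.shape != np.shape(self.C):
            raise ValueError(f"C field shape {C.shape} != grid layout {np.shape(self.C)}")
        self.C = C
        self.check_tensors()

    # --- constructors -----------------------------------------------------
    @classmethod
    def cable(
        cls,
        n_nodes: int,
        dx: float = 0.25,
        region_map=None,
        remodeling: str = "control",
        d_l: float = DEFAULT_D_L,
    ) -> "TissueGrid":
        """1D cable.  ``region_map`` is a region name or a list of
        (start, stop, region) node ranges covering [0, n_nodes)."""
        from ..ionic import get_region, get_remodeling

        if n_nodes < 2:
            raise ValueError("a cable needs at least 2 nodes")
        if region_map is None:
            region_map = "RA/PM"
        if isinstance(region_map, str):
            region_map = [(0, n_nodes, region_map)]
        remod = get_remodeling(remodeling).name
        variants: list = []
        vidx = np.full(n_nodes, -1, dtype=np.int64)
        for start, stop, region in region_map:
            name = get_region(region).name
            key = (name, remod)
            if key not in variants:
                variants.append(key)
            vidx[start:stop] = variants.index(key)
        if np.any(vidx < 0):
            raise ValueError("region_map does not cover every cable node")
        return cls(
            dx=dx,
            variants=variants,
            variant_idx=vidx,
            fibre=None,
            D=np.full(n_nodes, float(d_l)),
        )

    @classmethod
    def sheet(
        cls,
        nx: int,
        ny: int,
        dx: float = 0.25,
        fibre_angle: float = 0.0,
        region: str = "RA/PM",
        remodeling: str = "control",
        d_l: float = DEFAULT_D_L,
        d_t: float = DEFAULT_D_T,
        fibre_jitter: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> "TissueGrid":
        """2D sheet with a uniform fibre field at ``fibre_angle`` (degrees from
        the x axis), optionally jittered per node by a seeded generator."""
        from ..ionic import get_region, get_remodeling

        if nx < 2 or ny < 2:
            raise ValueError("a sheet needs at least 2x2 nodes")
        angle = np.deg2rad(fibre_angle) * np.ones((ny, nx))
        if fibre_jitter:
            if rng is None:
                raise ValueError("fibre_jitter requires a seeded Generator")
            angle = angle + np.deg2rad(fibre_jitter) * rng.standard_normal((ny, nx))
        fibre = np.stack([np.cos(angle), np.sin(angle)], axis=-1)
        D = _fibre_tensor(fibre, d_l, d_t)
        key = (get_region(region).name, get_remodeling(remodeling).name)
        return cls(
            dx=dx,
            variants=[key],
            variant_idx=np.zeros((ny, nx), dtype=np.int64),
            fibre=fibre,
            D=D,
        )
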