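"""Active-strain kinematics: multiplicative deformation decomposition.

The contraction of the myocyte population enters the continuum problem through
the active strain gamma = (SL - SL0)/SL0 (negative in systole), which prescribes
a microscopic active deformation F0 = I + gamma f (x) f along the local fibre
direction f.  The elastic (passive) part of the total deformation gradient F is
Fe = F F0^-1, and the passive constitutive law is evaluated on Fe alone.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "active_strain",
    "active_deformation",
    "elastic_strains",
    "fibre_frame",
]

_I3 = np.eye(3)


def active_strain(SL: float, SL0: float) -> float:
    """Active strain gamma = (SL - SL0)/SL0.

    gamma > 0 denotes elongation, gamma < 0 contraction.  ``SL0`` is the
    resting sarcomere length (micrometres).
    """
    if SL0 <= 0.0:
        raise ValueError(f"resting sarcomere length must be positive, got {SL0}")
    if SL <= 0.0:
        raise ValueError(f"sarcomere length must be positive, got {SL}")
    return (SL - SL0) / SL0


def _check_unit(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != (3,):
        raise ValueError(f"fibre direction must be a 3-vector, got shape {f.shape}")
    n = np.linalg.norm(f)
    if not np.isclose(n, 1.0, atol=1e-8):
        raise ValueError(f"fibre direction must be a unit vector (|f| = {n:.6g})")
    return f


def active_deformation(gamma: float, f: np.ndarray) -> np.ndarray:
    """Active deformation gradient F0 = I + gamma f (x) f.

    det F0 = 1 + gamma, so gamma <= -1 would be non-invertible and is rejected.
    """
    f = _check_unit(f)
    if gamma <= -1.0:
        raise ValueError(f"active strain gamma must exceed -1, got {gamma}")
    return _I3 + gamma * np.outer(f, f)


def elastic_strains(F: np.ndarray, F0: np.ndarray):
    """Elastic decomposition Fe = F F0^-1, Ce = Fe^T Fe, Ee = (Ce - I)/2.

    Returns ``(Fe, Ce, Ee)``.  Raises on a singular active part.
    """
    F = np.asarray(F, dtype=float)
    F0 = np.asarray(F0, dtype=float)
    if F.shape != (3, 3) or F0.shape != (3, 3):
        raise ValueError("F and F0 must be 3x3 tensors")
    det0 = np.linalg.det(F0)
    if abs(det0) < 1e-12:
        raise ValueError("active deformation F0 is singular")
    Fe = F @ np.linalg.inv(F0)
    Ce = Fe.T @ Fe
    Ee = 0.5 * (Ce - _I3)
    return Fe, Ce, Ee


def fibre_frame(f: np.ndarray) -> np.ndarray:
    """Orthonormal frame (rows) with axis 1 aligned to the fibre direction.

    The second axis is the smallest-index coordinate axis projected orthogonal
    to f (deterministic tie-break); the third completes a right-handed triad.
    """
    f = _check_unit(f)
    # pick the coordinate axis least aligned with f, by smallest index on ties
    idx = int(np.argmin(np.abs(f)))
    e = np.zeros(3)
    e[idx] = 1.0
    s = e - np.dot(e, f) * f
    s /= np.linalg.norm(s)
    n = np.cross(f, s)
    return np.vstack([f, s, n])
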