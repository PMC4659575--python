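"""Enclosed-cavity volume of a closed triangulated surface.

The cavity volume under a deformation phi is evaluated with the divergence
theorem as a surface integral, V = (1/3) * sum over the (deformed) boundary of
x . n dS, which for a piecewise-linear triangulation is the sum of signed
origin-tetrahedron volumes det[a b c]/6.  The mesh must be closed and
consistently outward-oriented; the reference configuration is required to have
positive volume, fixing the sign convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["check_closed_oriented", "enclosed_volume"]


def check_closed_oriented(vertices: np.ndarray, faces: np.ndarray) -> None:
    """Raise ValueError unless every edge is shared by exactly two triangles
    with opposite orientation (closed, consistently oriented 2-manifold)."""
    faces = np.asarray(faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValueError("faces must be an (n, 3) integer array")
    edges = {}
    for tri in faces:
        for k in range(3):
            a, b = int(tri[k]), int(tri[(k + 1) % 3])
            edges[(a, b)] = edges.get((a, b), 0) + 1
    for (a, b), count in edges.items():
        if count != 1:
            raise ValueError(
                f"directed edge ({a},{b}) used {count} times: inconsistent orientation"
            )
        if (b, a) not in edges:
            raise ValueError(f"edge ({a},{b}) has no opposite twin: mesh is not closed")


def enclosed_volume(vertices: np.ndarray, faces: np.ndarray, deformation=None) -> float:
    """Volume (mm^3) enclosed by the (deformed) closed surface.

    ``deformation`` maps reference vertex coordinates (n, 3) to deformed ones;
    None means identity.  Raises if the mesh is open, inconsistently oriented,
    or if the *reference* configuration has non-positive signed volume
    (inward-pointing normals).
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    check_closed_oriented(vertices, faces)

    def signed(v):
        a, b, c = v[faces[:, 0]], v[faces[:, 1]], v[faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    ref = signed(vertices)
    if ref <= 0.0:
        raise ValueError(
            f"reference mesh has signed volume {ref:.6g} <= 0: normals must point outward"
        )
    if deformation is None:
        return ref
    deformed = np.asarray(deformation(vertices), dtype=float)
    if deformed.shape != vertices.shape:
        raise ValueError("deformation must map (n,3) vertex coordinates to (n,3)")
    return signed(deformed)
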