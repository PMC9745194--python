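"""Flower-specific scalar features: sharpness and contour.

Sharpness (S7) is the ratio of the largest to the smallest
vertex-to-centroid distance; a smooth closed bloom gives values near 1
while scanning spikes, torn petals and other defects push it up.

Contour (P8) is the mesh volume divided by the volume of its minimum
enclosing sphere, a fullness measure in (0, 1]: compact buds approach 1,
wide-open flat flowers fall toward 0.  Both are invariant to rigid
motion and uniform scaling, so they are computed on the raw mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMeshError
from .mesh import (
    TriangleMesh,
    compute_centroid,
    mesh_volume,
    min_enclosing_sphere,
    vertex_distances,
)

__all__ = ["FlowerScalars", "sharpness", "contour"]


@dataclass(frozen=True)
class FlowerScalars:
    """The two flower-shape scalars of the fused descriptor."""

    s7: float
    p8: float


def sharpness(mesh: TriangleMesh) -> float:
    """max/min vertex-to-centroid distance ratio (>= 1).

    A vertex coinciding with the centroid would make the ratio blow up;
    that pathological case returns ``inf`` with a warning rather than
    erroring, so batch extraction over imperfect scans survives.
    """
    if mesh.n_vertices < 2:
        raise DegenerateMeshError("sharpness needs at least 2 vertices")
    dist = vertex_distances(mesh, compute_centroid(mesh))
    dmin = float(dist.min())
    dmax = float(dist.max())
    if dmax <= 0.0:
        raise DegenerateMeshError("all vertices coincide with the centroid")
    if dmin <= 1e-12 * dmax:
        warnings.warn(
            "a vertex coincides with the centroid; sharpness is infinite",
            stacklevel=2,
        )
        return float("inf")
    return dmax / dmin


def contour(mesh: TriangleMesh, sphere_seed: int = 0) -> float:
    """Mesh volume over the volume of its minimum enclosing sphere.

    Values near 1 indicate a full, ball-like bloom; open or flat flowers
    score lower.  For open meshes the signed-sum volume convention of
    :func:`florashape.mesh.mesh_volume` applies (a warning is issued).
    """
    _, radius = min_enclosing_sphere(mesh.vertices, seed=sphere_seed)
    if radius <= 0.0:
        raise DegenerateMeshError("degenerate mesh: enclosing sphere has zero radius")
    v_sphere = 4.0 / 3.0 * np.pi * radius**3
    return mesh_volume(mesh) / v_sphere
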