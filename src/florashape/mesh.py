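"""Triangle-mesh container, I/O and basic geometry.

The package operates on colored triangle meshes of flower heads.  This
module provides the in-memory representation (:class:`TriangleMesh`),
readers for PLY (vertex-color dialect) and OBJ (shape-only, optional CSV
color sidecar), centroid / translation / scale normalization, signed-sum
volume, and an exact minimum enclosing sphere.

Normalization follows the maximum-radius convention: vertices are
translated so their centroid is the origin and divided by the largest
centroid-to-vertex distance, so every normalized mesh fits in the unit
ball.  All downstream descriptors are computed on normalized meshes,
which makes them invariant to the placement and overall size of a scan.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import DegenerateMeshError, MeshFormatError

__all__ = [
    "TriangleMesh",
    "NormalizedMesh",
    "load_mesh",
    "save_mesh_ply",
    "compute_centroid",
    "vertex_distances",
    "normalize_mesh",
    "mesh_volume",
    "is_watertight",
    "min_enclosing_sphere",
]


@dataclass
class TriangleMesh:
    """A triangle mesh with optional per-vertex RGB colors.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in model units.
    faces : (m, 3) int array
        Vertex-index triples.
    vertex_colors : (n, 3) uint8 array, optional
        Per-vertex RGB in [0, 255].  ``None`` means shape-only mode.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertex_colors is not None:
            col = np.asarray(self.vertex_colors)
            col = np.clip(np.rint(col[:, :3]), 0, 255).astype(np.uint8)
            if len(col) != len(self.vertices):
                raise MeshFormatError(
                    f"{len(col)} vertex colors for {len(self.vertices)} vertices"
                )
            self.vertex_colors = col
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshFormatError(
                f"face references vertex {self.faces.max()} "
                f"of {len(self.vertices)}"
            )
        if self.faces.size and self.faces.min() < 0:
            raise MeshFormatError("negative face index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def has_colors(self) -> bool:
        return self.vertex_colors is not None

    def validate_for_descriptors(self) -> None:
        """Require the minimum structure every descriptor needs."""
        if self.n_vertices < 4 or self.n_faces < 4:
            raise DegenerateMeshError(
                f"descriptor extraction needs >=4 vertices and >=4 faces, "
                f"got {self.n_vertices} vertices / {self.n_faces} faces"
            )

    def to_trimesh(self) -> trimesh.Trimesh:
        tm = trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )
        if self.has_colors:
            rgba = np.column_stack(
                [self.vertex_colors, np.full(self.n_vertices, 255, dtype=np.uint8)]
            )
            tm.visual.vertex_colors = rgba
        return tm


@dataclass
class NormalizedMesh(TriangleMesh):
    """A :class:`TriangleMesh` after centroid translation and
    maximum-radius scaling; ``center`` and ``scale`` invert the transform."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def metadata_json(self) -> str:
        return json.dumps(
            {"center": [float(c) for c in self.center], "scale": float(self.scale)}
        )


def _colors_from_trimesh(tm: trimesh.Trimesh) -> np.ndarray | None:
    visual = getattr(tm, "visual", None)
    if visual is None or visual.kind != "vertex":
        return None
    col = np.asarray(visual.vertex_colors)
    if col.ndim != 2 or len(col) != len(tm.vertices):
        return None
    # trimesh reports an all-default (white, opaque) array even for
    # colorless meshes; treat that as "no color information".
    if np.all(col[:, :3] == col[0, :3]) and tuple(col[0, :3]) == (255, 255, 255):
        return None
    return col[:, :3]


def load_mesh(
    path: str | Path,
    fmt: str | None = None,
    color_sidecar: str | Path | None = None,
) -> TriangleMesh:
    """Load a PLY or OBJ triangle mesh.

    PLY files may carry per-vertex ``red``/``green``/``blue`` properties
    (ascii or binary-little-endian); OBJ is read shape-only unless a CSV
    sidecar ``vertex_index,r,g,b`` is supplied.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such mesh file: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "obj"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (expected ply/obj)")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # parser errors vary by backend
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path}: no triangle faces found")
    colors = _colors_from_trimesh(tm)
    if color_sidecar is not None:
        colors = _read_color_sidecar(color_sidecar, len(tm.vertices))
    try:
        return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), colors)
    except MeshFormatError as exc:
        raise MeshFormatError(f"{path}: {exc}") from exc


def _read_color_sidecar(path: str | Path, n_vertices: int) -> np.ndarray:
    colors = np.zeros((n_vertices, 3), dtype=np.uint8)
    seen = np.zeros(n_vertices, dtype=bool)
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#") or row[0] == "vertex_index":
                continue
            idx = int(row[0])
            if idx >= n_vertices:
                raise MeshFormatError(
                    f"color sidecar references vertex {idx} of {n_vertices}"
                )
            colors[idx] = np.clip([int(v) for v in row[1:4]], 0, 255)
            seen[idx] = True
    if not seen.all():
        raise MeshFormatError("color sidecar does not cover every vertex")
    return colors


def save_mesh_ply(mesh: TriangleMesh, path: str | Path) -> None:
    """Write an ascii PLY, with uchar red/green/blue when colors exist."""
    data = mesh.to_trimesh().export(file_type="ply", encoding="ascii")
    if isinstance(data, str):
        data = data.encode()
    Path(path).write_bytes(data)


def compute_centroid(mesh: TriangleMesh, area_weighted: bool = False) -> np.ndarray:
    """Centroid of the mesh.

    Defaults to the arithmetic mean of all vertices.  ``area_weighted``
    switches to the surface centroid (triangle centroids weighted by
    area), useful when tessellation density is very uneven.
    """
    if mesh.n_vertices == 0:
        raise DegenerateMeshError("cannot take the centroid of an empty mesh")
    if not area_weighted:
        return mesh.vertices.mean(axis=0)
    tri = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    total = areas.sum()
    if total <= 0:
        raise DegenerateMeshError("zero total surface area")
    return (tri.mean(axis=1) * areas[:, None]).sum(axis=0) / total


def vertex_distances(mesh: TriangleMesh, center: np.ndarray) -> np.ndarray:
    """Euclidean distance of every vertex from ``center`` (order-preserving)."""
    return np.linalg.norm(mesh.vertices - np.asarray(center, dtype=float), axis=1)


def normalize_mesh(mesh: TriangleMesh) -> NormalizedMesh:
    """Translate the centroid to the origin, divide by the maximum
    centroid-to-vertex distance; record center and scale for inversion."""
    if mesh.n_vertices < 2:
        raise DegenerateMeshError("normalization needs at least 2 vertices")
    center = compute_centroid(mesh)
    shifted = mesh.vertices - center
    scale = float(np.linalg.norm(shifted, axis=1).max())
    if scale <= 0.0:
        raise DegenerateMeshError("all vertices coincide; cannot scale-normalize")
    return NormalizedMesh(
        vertices=shifted / scale,
        faces=mesh.faces.copy(),
        vertex_colors=None if mesh.vertex_colors is None else mesh.vertex_colors.copy(),
        center=center,
        scale=scale,
    )


def is_watertight(mesh: TriangleMesh) -> bool:
    """True when every edge is shared by exactly two faces."""
    if mesh.n_faces == 0:
        return False
    edges = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def mesh_volume(mesh: TriangleMesh, warn_open: bool = True) -> float:
    """Volume by the divergence theorem: magnitude of the summed signed
    tetrahedra spanned by each face and the origin.

    For watertight, consistently oriented meshes this is the enclosed
    volume.  For open scan meshes the signed-sum magnitude is still
    returned (and a warning issued): it measures the cone volume swept
    from the centroid over the surface, a useful monotone proxy.  The
    sum is taken about the vertex centroid, which leaves closed-mesh
    volumes unchanged and makes the open-mesh proxy invariant to rigid
    motion.
    """
    if mesh.n_faces == 0:
        return 0.0
    tri = mesh.vertices[mesh.faces] - mesh.vertices.mean(axis=0)
    signed = np.einsum(
        "ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])
    ).sum() / 6.0
    if warn_open and not is_watertight(mesh):
        warnings.warn(
            "mesh is not watertight; volume is the signed-sum magnitude",
            stacklevel=2,
        )
    return abs(float(signed))


# ---------------------------------------------------------------------------
# Minimum enclosing sphere (exact, Welzl move-to-front)
# ---------------------------------------------------------------------------


def _circumsphere(support: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Smallest sphere through all support points (<=4, possibly degenerate).

    Solves for the center within the affine span of the points via a
    least-norm linear solve, which handles collinear/coplanar supports.
    """
    pts = np.asarray(support, dtype=float)
    if len(pts) == 0:
        return np.zeros(3), -1.0  # radius -1: contains nothing
    p0 = pts[0]
    if len(pts) == 1:
        return p0.copy(), 0.0
    a = 2.0 * (pts[1:] - p0)
    b = np.einsum("ij,ij->i", pts[1:] - p0, pts[1:] - p0)
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = p0 + x
    radius = float(np.linalg.norm(pts - center, axis=1).max())
    return center, radius


def _welzl(points: np.ndarray, support: list[np.ndarray], tol: float):
    center, radius = _circumsphere(support)
    if len(support) == 4:
        return center, radius
    for i in range(len(points)):
        p = points[i]
        if np.linalg.norm(p - center) > radius * (1 + tol) + tol:
            center, radius = _welzl(points[:i], support + [p], tol)
    return center, radius


def min_enclosing_sphere(
    points: np.ndarray, seed: int = 0, method: str = "welzl"
) -> tuple[np.ndarray, float]:
    """Exact minimum enclosing sphere of a 3D point set.

    ``method='welzl'`` runs the expected-linear randomized algorithm on
    the convex-hull vertices (deterministic for a given ``seed``);
    ``method='ritter'`` is the fast two-pass approximation.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("min_enclosing_sphere needs at least one point")
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    if method == "ritter":
        return _ritter(pts)
    if method != "welzl":
        raise ValueError(f"unknown method {method!r}")
    # Only hull vertices can touch the optimal sphere.
    work = np.unique(pts, axis=0)
    if len(work) > 8:
        try:
            from scipy.spatial import ConvexHull

            work = work[np.unique(ConvexHull(work).vertices)]
        except Exception:
            pass  # degenerate (flat/collinear) input: use the raw points
    rng = np.random.default_rng(seed)
    work = work[rng.permutation(len(work))]
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(work) + 1000))
    try:
        center, radius = _welzl(work.copy(), [], 1e-12)
    finally:
        sys.setrecursionlimit(old)
    return center, float(radius)


def _ritter(pts: np.ndarray) -> tuple[np.ndarray, float]:
    p = pts[0]
    q = pts[np.argmax(np.linalg.norm(pts - p, axis=1))]
    r = pts[np.argmax(np.linalg.norm(pts - q, axis=1))]
    center = (q + r) / 2.0
    radius = float(np.linalg.norm(q - r) / 2.0)
    for p in pts:
        d = float(np.linalg.norm(p - center))
        if d > radius:
            radius = (radius + d) / 2.0
            center = center + (d - radius) / d * (p - center)
    return center, radius
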