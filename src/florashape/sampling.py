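"""Surface sampling and three-layer equal-volume stratification.

Flower heads are sampled with area-weighted random points on the mesh
surface.  On the normalized mesh (unit enclosing radius about the
centroid) the unit ball is split into three shells of equal volume; the
shell boundaries are (1/3)^(1/3) ~ 0.69 and (2/3)^(1/3) ~ 0.87, so the
"in" layer captures the stamen region, the "mid" layer the inner petal
body and the "out" layer the petal rims.  Random tuples for the
shape-distribution functions are then drawn layer by layer in a fixed
round-robin, so each histogram mixes the geometry of all three layers
instead of being dominated by whichever layer carries most surface area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateMeshError
from .mesh import NormalizedMesh

__all__ = [
    "LAYER_NAMES",
    "LayerBounds",
    "SurfaceSample",
    "SampleSet",
    "equal_volume_radii",
    "assign_layer",
    "sample_surface",
    "stratified_tuples",
]

#: Layer codes: 0 = in (stamen), 1 = mid (petal body), 2 = out (petal rim).
LAYER_NAMES = ("in", "mid", "out")


def equal_volume_radii(parts: int = 3) -> np.ndarray:
    """Radii splitting the unit ball into ``parts`` shells of equal volume.

    Returns the ``parts - 1`` interior radii ``(k/parts)**(1/3)``.  For
    the default three layers these are ~0.693 and ~0.874, commonly
    rounded to 0.7 and 0.87.
    """
    if parts < 2:
        raise ValueError("equal-volume split needs parts >= 2")
    k = np.arange(1, parts)
    return (k / parts) ** (1.0 / 3.0)


@dataclass(frozen=True)
class LayerBounds:
    """Radial boundaries of the three sampling layers (half-open below)."""

    inner_upper: float = float((1.0 / 3.0) ** (1.0 / 3.0))
    outer_lower: float = float((2.0 / 3.0) ** (1.0 / 3.0))

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_upper < self.outer_lower < 1.0):
            raise ValueError("need 0 < inner_upper < outer_lower < 1")


def assign_layer(radius, bounds: LayerBounds = LayerBounds()):
    """Map radii to layer codes: [0, inner) -> in, [inner, outer) -> mid,
    [outer, inf) -> out.  Accepts scalars or arrays."""
    r = np.asarray(radius, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    codes = np.where(r < bounds.inner_upper, 0, np.where(r < bounds.outer_lower, 1, 2))
    return int(codes) if np.isscalar(radius) else codes.astype(np.int8)


@dataclass(frozen=True)
class SurfaceSample:
    """A single sampled surface point with its interpolated color and layer."""

    position: np.ndarray
    radius: float
    layer: str
    color: tuple[int, int, int] | None = None


@dataclass
class SampleSet:
    """Columnar store of surface samples (positions, radii, layers, colors).

    Behaves as a sequence of :class:`SurfaceSample` but keeps contiguous
    arrays so descriptor evaluation stays vectorized.
    """

    positions: np.ndarray
    radii: np.ndarray
    layers: np.ndarray
    colors: np.ndarray | None = None
    bounds: LayerBounds = field(default_factory=LayerBounds)

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, i: int) -> SurfaceSample:
        color = None if self.colors is None else tuple(int(c) for c in self.colors[i])
        return SurfaceSample(
            position=self.positions[i],
            radius=float(self.radii[i]),
            layer=LAYER_NAMES[self.layers[i]],
            color=color,
        )

    def layer_indices(self) -> list[np.ndarray]:
        """Sample indices per layer code 0..2."""
        return [np.flatnonzero(self.layers == c) for c in range(3)]


def sample_surface(
    mesh: NormalizedMesh,
    n: int,
    seed: int | np.random.Generator = 0,
    bounds: LayerBounds = LayerBounds(),
) -> SampleSet:
    """Draw ``n`` area-weighted uniform random points on the mesh surface.

    Faces are chosen with probability proportional to area, positions
    placed uniformly via the square-root barycentric trick; colors are
    barycentrically interpolated (and rounded) when the mesh has them.
    Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tri = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    total = areas.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise DegenerateMeshError("mesh has zero total surface area")
    face_idx = rng.choice(len(areas), size=n, p=areas / total)
    # uniform barycentric coordinates
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    w0 = 1.0 - r1
    w1 = r1 * (1.0 - r2)
    w2 = r1 * r2
    t = tri[face_idx]
    pos = w0[:, None] * t[:, 0] + w1[:, None] * t[:, 1] + w2[:, None] * t[:, 2]
    radii = np.linalg.norm(pos, axis=1)
    layers = assign_layer(radii, bounds)
    colors = None
    if mesh.has_colors:
        vc = mesh.vertex_colors[mesh.faces[face_idx]].astype(float)
        mixed = (
            w0[:, None] * vc[:, 0] + w1[:, None] * vc[:, 1] + w2[:, None] * vc[:, 2]
        )
        colors = np.clip(np.rint(mixed), 0, 255).astype(np.uint8)
    return SampleSet(pos, radii, layers, colors, bounds)


def _draw_without_replacement(
    rng: np.random.Generator, pool: np.ndarray, m: int, k: int
) -> np.ndarray:
    """(m, k) indices into ``pool``; no repeats within a row.

    Rejection-based: rows with duplicate entries are redrawn, which is
    vectorized and fast whenever len(pool) >> k.
    """
    n = len(pool)
    if k > n:
        raise ValueError(f"cannot draw {k} distinct points from a layer of {n}")
    idx = rng.integers(0, n, size=(m, k))
    for _ in range(64):
        dup = (np.sort(idx, axis=1)[:, 1:] == np.sort(idx, axis=1)[:, :-1]).any(axis=1)
        if not dup.any():
            break
        idx[dup] = rng.integers(0, n, size=(int(dup.sum()), k))
    else:  # tiny layers: per-row exact draw
        for row in np.flatnonzero(dup):
            idx[row] = rng.choice(n, size=k, replace=False)
    return pool[idx]


def stratified_tuples(
    samples: SampleSet,
    k: int,
    count: int,
    seed: int | np.random.Generator = 0,
    cross_mode: str = "intra",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``count`` k-tuples of sample indices, cycling layers in turn.

    In the default ``intra`` mode successive tuples come wholly from one
    layer, cycling out -> mid -> in, so all three shells contribute
    equally to every histogram.  ``inter`` mode instead rotates the k
    slots of each tuple through the layers.  Within a layer points are
    drawn uniformly, without replacement inside a tuple and with
    replacement across tuples.  Empty layers are skipped from the cycle.

    Returns ``(indices, tuple_layers)``: indices is (count, k) into
    ``samples``; tuple_layers gives each tuple's layer code (intra mode)
    or the layer of its first slot (inter mode).
    """
    if k < 1 or k > 4:
        raise ValueError("tuple size k must be in 1..4")
    if count < 1:
        raise ValueError("count must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_layer = samples.layer_indices()
    # fixed cycling order: out, mid, in
    cycle = [c for c in (2, 1, 0) if len(per_layer[c]) > 0]
    if not cycle:
        raise DegenerateMeshError("no surface samples in any layer")
    if cross_mode == "inter" and len(cycle) > 1:
        out = np.empty((count, k), dtype=np.int64)
        tuple_layers = np.empty(count, dtype=np.int8)
        slot_layers = np.empty((count, k), dtype=np.int8)
        for t in range(count):
            for j in range(k):
                slot_layers[t, j] = cycle[(t + j) % len(cycle)]
        tuple_layers[:] = slot_layers[:, 0]
        for c in cycle:
            mask = slot_layers == c
            out[mask] = rng.choice(per_layer[c], size=int(mask.sum()))
        return out, tuple_layers
    if cross_mode not in ("intra", "inter"):
        raise ValueError(f"unknown cross_mode {cross_mode!r}")
    # intra: whole tuples per layer, round-robin over non-empty layers
    layer_of_tuple = np.array(
        [cycle[t % len(cycle)] for t in range(count)], dtype=np.int8
    )
    out = np.empty((count, k), dtype=np.int64)
    for c in cycle:
        rows = np.flatnonzero(layer_of_tuple == c)
        if len(rows) == 0:
            continue
        pool = per_layer[c]
        if len(pool) < k:  # fallback: too few points in this layer
            pool = np.arange(len(samples))
        out[rows] = _draw_without_replacement(rng, pool, len(rows), k)
    return out, layer_of_tuple


def redraw_tuples(
    samples: SampleSet,
    indices: np.ndarray,
    tuple_layers: np.ndarray,
    rows: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Redraw the given tuple rows in place, keeping each tuple's layer.

    Used by descriptor evaluation to resample degenerate tuples
    (collinear triples, coincident points) without disturbing the
    round-robin layer balance.
    """
    k = indices.shape[1]
    per_layer = samples.layer_indices()
    for c in np.unique(tuple_layers[rows]):
        sel = rows[tuple_layers[rows] == c]
        pool = per_layer[c]
        if len(pool) < k:
            pool = np.arange(len(samples))
        indices[sel] = _draw_without_replacement(rng, pool, len(sel), k)
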