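"""Parametric generator of colored flower-like triangle meshes.

Real rose-scan collections are rarely shareable, so every stage of the
pipeline is exercised on synthetic flower heads with known ground
truth.  A flower is modeled as a radially deformed sphere: petal lobes
are angular bumps around the vertical axis, a small interior icosphere
plays the stamen, and three controls shape the bloom:

* ``openness`` removes a polar cap (the bloom's mouth) and flattens the
  head, so higher openness strictly lowers the contour feature P8;
* ``damage`` displaces random vertices into radial spikes, driving the
  sharpness feature S7 up;
* ``fullness`` scales the vertical axis, moving P8 between flat and
  ball-like regimes.

Vertex colors are a reference flower color plus Gaussian jitter, with an
optional fraction of leaf-green contamination.  Everything is
deterministic per spec seed.  ``generate_collection`` produces labeled
multi-class collections (optionally written as PLY files plus a CSV
manifest) mirroring a 15-species x 40-sample survey design at any scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .color import REFERENCE_GREEN, ColorReferenceTable
from .mesh import TriangleMesh, save_mesh_ply

__all__ = [
    "FlowerSpec",
    "generate_flower",
    "generate_collection",
    "benchmark_specs",
    "default_class_specs",
]


@dataclass(frozen=True)
class FlowerSpec:
    """Ground-truth parameters of one synthetic flower."""

    n_petals: int = 6
    openness: float = 0.5          # 0 closed bud .. 1 wide open
    fullness: float = 0.8          # vertical plumpness (0, 1]
    petal_length_ratio: float = 0.5  # petal lobe amplitude
    color: int = 1                 # reference color index 1..8
    color_jitter: float = 12.0     # per-channel Gaussian sigma
    leaf_fraction: float = 0.0     # green-contaminated vertex fraction
    damage: float = 0.0            # spike severity 0..1
    seed: int = 0
    resolution: tuple[int, int] = (48, 24)  # azimuthal x polar grid

    def __post_init__(self) -> None:
        if self.n_petals < 3:
            raise ValueError("n_petals must be >= 3")
        if not (0.0 <= self.openness <= 1.0):
            raise ValueError("openness must be in [0, 1]")
        if not (0.0 < self.fullness <= 1.0):
            raise ValueError("fullness must be in (0, 1]")
        if not (1 <= self.color <= 8):
            raise ValueError("color must be a reference index 1..8")
        if not (0.0 <= self.leaf_fraction <= 0.5):
            raise ValueError("leaf_fraction must be in [0, 0.5]")
        if not (0.0 <= self.damage <= 1.0):
            raise ValueError("damage must be in [0, 1]")


def _uv_sphere_grid(n_phi: int, n_theta: int):
    """Vertex grid and faces of a UV sphere with pole vertices."""
    thetas = np.linspace(0.0, np.pi, n_theta + 2)[1:-1]
    phis = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    return tt.ravel(), pp.ravel()


def _grid_faces(n_theta: int, n_phi: int, top: int, bottom: int) -> np.ndarray:
    """Triangulate the ring grid plus the two pole fans."""
    idx = lambda i, j: i * n_phi + (j % n_phi)  # noqa: E731
    faces = []
    for j in range(n_phi):  # top fan (ring 0)
        faces.append([top, idx(0, j), idx(0, j + 1)])
    for i in range(n_theta - 1):
        for j in range(n_phi):
            a, b = idx(i, j), idx(i, j + 1)
            c, d = idx(i + 1, j), idx(i + 1, j + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    for j in range(n_phi):  # bottom fan (last ring)
        faces.append([bottom, idx(n_theta - 1, j + 1), idx(n_theta - 1, j)])
    return np.asarray(faces, dtype=np.int64)


def generate_flower(spec: FlowerSpec, closed: bool = False) -> TriangleMesh:
    """Build the colored flower mesh for ``spec``.

    ``closed=True`` keeps the polar cap (a watertight head regardless of
    openness), for tests that need a well-defined enclosed volume; the
    default removes the cap like a real open scan.
    """
    rng = np.random.default_rng(spec.seed)
    n_phi, n_theta = spec.resolution
    theta, phi = _uv_sphere_grid(n_phi, n_theta)

    # petal lobes: angular bumps, strongest near the equator
    lobe = np.maximum(0.0, np.cos(spec.n_petals * phi / 2.0) ** 2)
    amp = 0.5 * spec.petal_length_ratio
    r = 1.0 + amp * lobe * np.sin(theta) ** 2
    x = r * np.sin(theta) * np.cos(phi)
    y = r * np.sin(theta) * np.sin(phi)
    z = r * np.cos(theta)
    # vertical plumpness and open-bloom flattening
    z *= (0.4 + 0.6 * spec.fullness) * (1.0 - 0.5 * spec.openness)
    top = np.array([0.0, 0.0, (0.4 + 0.6 * spec.fullness)
                    * (1.0 - 0.5 * spec.openness)])
    bottom = np.array([0.0, 0.0, -top[2]])
    verts = np.column_stack([x, y, z])
    verts = np.vstack([verts, top, bottom])
    top_i, bottom_i = len(verts) - 2, len(verts) - 1
    faces = _grid_faces(n_theta, n_phi, top_i, bottom_i)

    if not closed and spec.openness > 0.0:
        # open the bloom: drop faces whose centroid lies inside the
        # polar cap of half-angle openness * 75 degrees
        cap = np.deg2rad(75.0 * spec.openness)
        centroids = verts[faces].mean(axis=1)
        polar = np.arccos(
            np.clip(centroids[:, 2] / np.linalg.norm(centroids, axis=1), -1, 1)
        )
        faces = faces[polar > cap]

    # stamen core
    stamen = trimesh.creation.icosphere(subdivisions=1, radius=0.3)
    sv = np.asarray(stamen.vertices)
    sf = np.asarray(stamen.faces) + len(verts)
    all_verts = np.vstack([verts, sv])
    all_faces = np.vstack([faces, sf])

    # damage spikes: radial displacement of a few random vertices
    if spec.damage > 0.0:
        n_spike = max(1, int(round(6 * spec.damage)))
        outer = np.flatnonzero(np.linalg.norm(all_verts, axis=1) > 0.5)
        hit = rng.choice(outer, size=min(n_spike, len(outer)), replace=False)
        all_verts[hit] *= 1.0 + 2.0 * spec.damage

    # drop vertices orphaned by the cap removal, re-index faces
    used = np.unique(all_faces)
    remap = -np.ones(len(all_verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    all_verts = all_verts[used]
    all_faces = remap[all_faces]

    base_rgb = np.asarray(ColorReferenceTable().rgb_matrix[spec.color - 1])
    colors = base_rgb + rng.normal(0.0, spec.color_jitter, size=(len(all_verts), 3))
    if spec.leaf_fraction > 0.0:
        n_leaf = int(round(spec.leaf_fraction * len(all_verts)))
        leaf_idx = rng.choice(len(all_verts), size=n_leaf, replace=False)
        colors[leaf_idx] = np.asarray(REFERENCE_GREEN) + rng.normal(
            0.0, 5.0, size=(n_leaf, 3)
        )
    colors = np.clip(np.rint(colors), 0, 255).astype(np.uint8)
    return TriangleMesh(vertices=all_verts, faces=all_faces, vertex_colors=colors)


@dataclass
class SyntheticCollection:
    """A labeled synthetic collection with its ground-truth specs."""

    meshes: list[TriangleMesh]
    labels: list[str]
    specs: list[FlowerSpec]
    manifest: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def default_class_specs(n_classes: int, seed: int = 0) -> list[FlowerSpec]:
    """Base specs for ``n_classes`` distinguishable flower species.

    Classes cycle through the reference colors and vary petal count,
    openness and fullness, so neighboring classes differ in several
    coordinates at once; consecutive same-color pairs (when n_classes
    exceeds the 8 reference colors) differ only in shape.
    """
    specs = []
    for c in range(n_classes):
        specs.append(
            FlowerSpec(
                n_petals=4 + (c % 5) * 2,
                openness=0.15 + 0.7 * ((c * 3) % n_classes) / max(1, n_classes - 1),
                fullness=0.5 + 0.5 * ((c * 7) % n_classes) / max(1, n_classes - 1),
                petal_length_ratio=0.3 + 0.5 * (c % 4) / 3.0,
                color=1 + (c % 8),
                seed=seed + c,
            )
        )
    return specs


def benchmark_specs(seed: int = 0) -> list[FlowerSpec]:
    """Ten-class benchmark design for retrieval/classification studies.

    Classes 0-7 pair the eight reference colors with distinct shapes;
    classes 8 and 9 are fine-shape twins of classes 0 and 1 — same
    color, same petal count, differing only in openness respectively
    fullness — so separating them requires the shape features, not the
    color indicator.
    """
    base = [
        FlowerSpec(n_petals=4 + (c % 5) * 2,
                   openness=0.15 + 0.08 * c,
                   fullness=1.0 - 0.07 * c,
                   petal_length_ratio=0.3 + 0.06 * c,
                   color=1 + c,
                   seed=seed + c)
        for c in range(8)
    ]
    twin_a = replace(base[0], openness=min(1.0, base[0].openness + 0.45),
                     seed=seed + 8)
    twin_b = replace(base[1], fullness=max(0.1, base[1].fullness - 0.45),
                     seed=seed + 9)
    return base + [twin_a, twin_b]


def generate_collection(
    n_classes: int = 15,
    per_class: int = 40,
    base_specs: list[FlowerSpec] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    jitter: float = 0.05,
    closed: bool = False,
) -> SyntheticCollection:
    """Generate a labeled multi-class collection of synthetic flowers.

    Per-sample parameters jitter around each class's base spec
    (relative magnitude ``jitter``); with jitter approaching 0, samples
    of one class collapse onto the base spec.  If ``out_dir`` is given,
    meshes are written as ascii PLY and a manifest CSV
    (path, label, seed) accompanies them.
    """
    if n_classes < 2:
        raise ValueError("a collection needs at least two classes")
    if base_specs is None:
        base_specs = default_class_specs(n_classes, seed)
    if len(base_specs) != n_classes:
        raise ValueError("need one base spec per class")
    rng = np.random.default_rng(seed)
    meshes, labels, specs, rows = [], [], [], []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for c, base in enumerate(base_specs):
        label = f"class_{c:02d}"
        for s in range(per_class):
            sample_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                base,
                openness=float(
                    np.clip(base.openness + rng.normal(0, jitter), 0.0, 1.0)
                ),
                fullness=float(
                    np.clip(base.fullness + rng.normal(0, jitter), 0.05, 1.0)
                ),
                petal_length_ratio=float(
                    np.clip(base.petal_length_ratio + rng.normal(0, jitter), 0.05, 1.0)
                ),
                seed=sample_seed,
            )
            mesh = generate_flower(spec, closed=closed)
            meshes.append(mesh)
            labels.append(label)
            specs.append(spec)
            if out_dir is not None:
                name = f"{label}_{s:03d}.ply"
                save_mesh_ply(mesh, out_dir / name)
                rows.append({"path": name, "label": label, "seed": sample_seed})
            else:
                rows.append({"path": None, "label": label, "seed": sample_seed})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return SyntheticCollection(
        meshes=meshes, labels=labels, specs=specs, manifest=manifest
    )
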