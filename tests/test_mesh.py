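"""Mesh I/O, normalization, volume and minimum enclosing sphere."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from florashape import (
    DegenerateMeshError,
    MeshFormatError,
    TriangleMesh,
    compute_centroid,
    load_mesh,
    mesh_volume,
    min_enclosing_sphere,
    normalize_mesh,
    save_mesh_ply,
    vertex_distances,
)
from florashape.mesh import is_watertight


def _tetra(colors=None):
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f, colors)


class TestIO:
    def test_ply_color_roundtrip(self, tmp_path):
        mesh = _tetra(np.tile([217, 32, 37], (4, 1)))
        save_mesh_ply(mesh, tmp_path / "t.ply")
        back = load_mesh(tmp_path / "t.ply")
        assert back.n_vertices == 4 and back.n_faces == 4
        assert back.has_colors
        assert np.all(back.vertex_colors == [217, 32, 37])

    def test_obj_without_colors(self, tmp_path):
        path = tmp_path / "t.obj"
        path.write_text(
            "v 0 0 0\nv 1 0 0\nv 0 1 0\nv 0 0 1\n"
            "f 1 3 2\nf 1 2 4\nf 1 4 3\nf 2 3 4\n"
        )
        mesh = load_mesh(path)
        assert mesh.vertex_colors is None
        assert mesh.n_faces == 4

    def test_obj_color_sidecar(self, tmp_path):
        path = tmp_path / "t.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        side = tmp_path / "colors.csv"
        side.write_text("vertex_index,r,g,b\n0,255,0,0\n1,0,255,0\n2,0,0,255\n")
        mesh = load_mesh(path, color_sidecar=side)
        assert np.all(mesh.vertex_colors[1] == [0, 255, 0])

    def test_out_of_range_face_index_rejected(self, tmp_path):
        path = tmp_path / "bad.ply"
        path.write_text(
            "ply\nformat ascii 1.0\nelement vertex 3\n"
            "property float x\nproperty float y\nproperty float z\n"
            "element face 1\nproperty list uchar int vertex_indices\n"
            "end_header\n0 0 0\n1 0 0\n0 1 0\n3 0 1 99\n"
        )
        with pytest.raises(MeshFormatError):
            load_mesh(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(MeshFormatError):
            load_mesh(tmp_path / "nope.ply")

    def test_direct_bad_face_index(self):
        with pytest.raises(MeshFormatError, match="99"):
            TriangleMesh(np.zeros((10, 3)), np.array([[0, 1, 99]]))


class TestCentroidAndDistances:
    def test_midpoint(self):
        m = TriangleMesh(np.array([[0.0, 0, 0], [2, 0, 0]]), np.zeros((0, 3), int))
        assert np.allclose(compute_centroid(m), [1, 0, 0])

    def test_single_vertex_identity(self):
        m = TriangleMesh(np.array([[5.0, -1, 2]]), np.zeros((0, 3), int))
        assert np.allclose(compute_centroid(m), [5, -1, 2])

    def test_translated_sphere(self, icosphere):
        m = TriangleMesh(icosphere.vertices + [3, 3, 3], icosphere.faces)
        assert np.allclose(compute_centroid(m), [3, 3, 3], atol=1e-9)

    def test_empty_mesh_errors(self):
        with pytest.raises(DegenerateMeshError):
            compute_centroid(TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), int)))

    def test_equivariance_under_rigid_motion(self, rng):
        v = rng.random((30, 3))
        m = TriangleMesh(v, np.array([[0, 1, 2]]))
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        t = np.array([2.0, -1.0, 0.5])
        m2 = TriangleMesh(v @ R.T + t, m.faces)
        assert np.allclose(
            compute_centroid(m2), R @ compute_centroid(m) + t, atol=1e-12
        )

    def test_vertex_distances(self):
        m = TriangleMesh(
            np.array([[3.0, 4, 0], [0, 0, 0]]), np.zeros((0, 3), int)
        )
        assert np.allclose(vertex_distances(m, [0, 0, 0]), [5.0, 0.0])


class TestNormalize:
    def test_hand_computed_two_points(self):
        m = TriangleMesh(np.array([[0.0, 0, 0], [0, 0, 4]]), np.zeros((0, 3), int))
        nm = normalize_mesh(m)
        assert np.allclose(nm.center, [0, 0, 2])
        assert nm.scale == pytest.approx(2.0)
        assert np.allclose(sorted(nm.vertices[:, 2]), [-1, 1])

    def test_scale_recorded(self, icosphere):
        m = TriangleMesh(icosphere.vertices * 7.0, icosphere.faces)
        nm = normalize_mesh(m)
        assert nm.scale == pytest.approx(7.0)
        assert np.linalg.norm(nm.vertices, axis=1).max() == pytest.approx(1.0)

    def test_idempotent(self, icosphere):
        once = normalize_mesh(icosphere)
        twice = normalize_mesh(once)
        assert np.allclose(once.vertices, twice.vertices, atol=1e-9)

    def test_degenerate_coincident_vertices(self):
        m = TriangleMesh(np.ones((5, 3)), np.zeros((0, 3), int))
        with pytest.raises(DegenerateMeshError):
            normalize_mesh(m)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_unit_max_radius_property(self, seed):
        r = np.random.default_rng(seed)
        v = r.normal(size=(20, 3)) * r.uniform(0.1, 50)
        m = TriangleMesh(v, np.array([[0, 1, 2]]))
        nm = normalize_mesh(m)
        assert np.linalg.norm(nm.vertices, axis=1).max() == pytest.approx(
            1.0, abs=1e-9
        )
        assert np.allclose(nm.vertices.mean(axis=0), 0.0, atol=1e-9)


class TestVolume:
    def test_unit_cube(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-9)

    def test_regular_tetrahedron(self, regular_tetrahedron):
        assert mesh_volume(regular_tetrahedron) == pytest.approx(
            np.sqrt(2) / 12, abs=1e-12
        )

    def test_sphere_monotone_convergence(self):
        vols = []
        for k in (1, 2, 3):
            s = trimesh.creation.icosphere(subdivisions=k)
            vols.append(
                mesh_volume(TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces)))
            )
        assert vols[0] < vols[1] < vols[2] < 4 * np.pi / 3
        assert vols[2] == pytest.approx(4 * np.pi / 3, rel=0.01)

    def test_open_mesh_warns(self, unit_cube):
        open_mesh = TriangleMesh(unit_cube.vertices, unit_cube.faces[:-2])
        assert not is_watertight(open_mesh)
        with pytest.warns(UserWarning, match="not watertight"):
            mesh_volume(open_mesh)

    def test_volume_within_enclosing_sphere(self, rng):
        s = trimesh.creation.icosphere(subdivisions=2)
        v = np.asarray(s.vertices) * rng.uniform(0.5, 1.0, size=(len(s.vertices), 1))
        nm = normalize_mesh(TriangleMesh(v, np.asarray(s.faces)))
        _, r = min_enclosing_sphere(nm.vertices)
        assert mesh_volume(nm, warn_open=False) <= 4 / 3 * np.pi * r**3 + 1e-9


def _brute_force_mes(points):
    """Smallest sphere by enumerating all 2/3/4-point support sets."""
    from itertools import combinations

    def sphere_through(sub):
        sub = np.asarray(sub, dtype=float)
        p0 = sub[0]
        a = 2.0 * (sub[1:] - p0)
        b = np.einsum("ij,ij->i", sub[1:] - p0, sub[1:] - p0)
        x, *_ = np.linalg.lstsq(a, b, rcond=None)
        c = p0 + x
        return c, np.linalg.norm(sub - c, axis=1).max()

    best = (None, np.inf)
    for k in (2, 3, 4):
        for sub in combinations(range(len(points)), k):
            c, r = sphere_through(points[list(sub)])
            if r < best[1] and np.all(
                np.linalg.norm(points - c, axis=1) <= r * (1 + 1e-9) + 1e-12
            ):
                best = (c, r)
    return best


class TestMinEnclosingSphere:
    def test_two_points(self):
        c, r = min_enclosing_sphere(np.array([[0.0, 0, 0], [2, 0, 0]]))
        assert r == pytest.approx(1.0)
        assert np.allclose(c, [1, 0, 0])

    def test_points_on_unit_sphere(self, icosphere):
        _, r = min_enclosing_sphere(icosphere.vertices)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force(self, rng):
        pts = rng.random((12, 3))
        _, r = min_enclosing_sphere(pts, seed=0)
        _, r_brute = _brute_force_mes(pts)
        assert r == pytest.approx(r_brute, rel=1e-9)
        assert np.all(
            np.linalg.norm(pts - min_enclosing_sphere(pts)[0], axis=1)
            <= r * (1 + 1e-9)
        )

    def test_rigid_motion_invariance(self, rng):
        pts = rng.random((50, 3))
        _, r = min_enclosing_sphere(pts)
        R = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        _, r2 = min_enclosing_sphere(pts @ R.T + [10, -4, 2])
        assert r2 == pytest.approx(r, rel=1e-9)

    def test_collinear_points(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        c, r = min_enclosing_sphere(pts)
        assert r == pytest.approx(1.5)
        assert np.allclose(c, [1.5, 0, 0])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            min_enclosing_sphere(np.zeros((0, 3)))

    def test_ritter_contains_all_points(self, rng):
        pts = rng.random((100, 3))
        c, r = min_enclosing_sphere(pts, method="ritter")
        assert np.all(np.linalg.norm(pts - c, axis=1) <= r * (1 + 1e-9))
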