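"""Mesh I/O, reflection, smoothing/decimation, clipping and distance maps."""

import numpy as np
import pytest
import trimesh

import arthroshape as ash
from arthroshape._proximity import closest_point_triangles

from conftest import sphere_mesh

TETRA_V = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
TETRA_F = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


class TestPlyIO:
    @pytest.mark.parametrize("dialect", ["binary_le", "ascii"])
    def test_roundtrip_identity(self, tmp_path, dialect):
        mesh = ash.SurfaceMesh(TETRA_V, TETRA_F, bone_label="talus")
        path = tmp_path / "tetra.ply"
        ash.save_mesh(mesh, path, dialect=dialect)
        back = ash.load_mesh(path, bone_label="talus")
        np.testing.assert_array_equal(back.faces, mesh.faces)
        if dialect == "binary_le":
            np.testing.assert_array_equal(back.vertices, mesh.vertices)
        else:
            np.testing.assert_allclose(back.vertices, mesh.vertices, rtol=1e-15)

    def test_dialect_equivalence(self, tmp_path, rng):
        mesh = sphere_mesh(7.5, 2)
        mesh.vertices += rng.normal(0, 0.01, mesh.vertices.shape)
        ash.save_mesh(mesh, tmp_path / "a.ply", dialect="ascii")
        ash.save_mesh(mesh, tmp_path / "b.ply", dialect="binary_le")
        a = ash.load_mesh(tmp_path / "a.ply")
        b = ash.load_mesh(tmp_path / "b.ply")
        np.testing.assert_allclose(a.vertices, b.vertices, rtol=0, atol=1e-12)
        np.testing.assert_array_equal(a.faces, b.faces)

    def test_binary_roundtrip_bit_exact_with_scalars(self, tmp_path, rng):
        mesh = sphere_mesh(3.0, 2)
        field = rng.normal(size=mesh.n_vertices)
        ash.save_mesh(mesh, tmp_path / "m.ply", scalars={"curv": field})
        back = ash.load_mesh(tmp_path / "m.ply")
        np.testing.assert_array_equal(back.vertices, mesh.vertices)
        np.testing.assert_array_equal(back.scalars["curv"], field)

    def test_ascii_scalars_nine_significant_digits(self, tmp_path, rng):
        mesh = ash.SurfaceMesh(TETRA_V, TETRA_F)
        field = rng.normal(size=4)
        ash.save_mesh(mesh, tmp_path / "m.ply", dialect="ascii",
                      scalars={"f": field})
        back = ash.load_mesh(tmp_path / "m.ply")
        np.testing.assert_allclose(back.scalars["f"], field, rtol=1e-9)

    def test_unreferenced_vertex_warns_and_is_retained(self, tmp_path):
        text = ("ply\nformat ascii 1.0\nelement vertex 4\n"
                "property double x\nproperty double y\nproperty double z\n"
                "element face 1\nproperty list uchar int vertex_indices\n"
                "end_header\n0 0 0\n1 0 0\n0 1 0\n5 5 5\n3 0 1 2\n")
        p = tmp_path / "loose.ply"
        p.write_text(text)
        with pytest.warns(UserWarning, match="not referenced"):
            mesh = ash.load_mesh(p)
        assert mesh.n_vertices == 4

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.ply"
        p.write_text("not a ply file\n")
        with pytest.raises(ValueError):
            ash.load_mesh(p)

    def test_quads_rejected_unless_triangulated(self, tmp_path):
        text = ("ply\nformat ascii 1.0\nelement vertex 4\n"
                "property double x\nproperty double y\nproperty double z\n"
                "element face 1\nproperty list uchar int vertex_indices\n"
                "end_header\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n4 0 1 2 3\n")
        p = tmp_path / "quad.ply"
        p.write_text(text)
        with pytest.raises(ValueError, match="non-triangular"):
            ash.load_mesh(p)
        mesh = ash.load_mesh(p, triangulate_quads=True)
        assert mesh.n_faces == 2

    def test_empty_mesh_refused(self, tmp_path):
        empty = ash.SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            ash.save_mesh(empty, tmp_path / "e.ply")


class TestReflect:
    def test_involution(self):
        mesh = sphere_mesh(5.0, 2)
        back = ash.reflect_mesh(ash.reflect_mesh(mesh))
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-12)
        np.testing.assert_array_equal(back.faces, mesh.faces)

    def test_isometry(self, rng):
        mesh = sphere_mesh(5.0, 1)
        mesh.vertices += rng.normal(0, 0.3, mesh.vertices.shape)
        sub = rng.choice(mesh.n_vertices, 30, replace=False)
        before = np.linalg.norm(
            mesh.vertices[sub][:, None] - mesh.vertices[sub][None], axis=-1)
        refl = ash.reflect_mesh(mesh)
        after = np.linalg.norm(
            refl.vertices[sub][:, None] - refl.vertices[sub][None], axis=-1)
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_orientation_and_side(self):
        mesh = sphere_mesh(2.0, 2)
        mesh.side = "left"
        refl = ash.reflect_mesh(mesh)
        assert refl.side == "right"
        assert mesh.signed_volume() > 0
        assert refl.signed_volume() > 0  # winding fixed, outward preserved


class TestPreprocess:
    def test_identity_when_disabled(self):
        mesh = sphere_mesh(1.0, 2)
        out = ash.preprocess_mesh(mesh, smoothing_iterations=0,
                                  target_face_count=mesh.n_faces)
        np.testing.assert_array_equal(out.vertices, mesh.vertices)
        np.testing.assert_array_equal(out.faces, mesh.faces)

    def test_smoothing_reduces_radial_noise(self, rng):
        mesh = sphere_mesh(1.0, 3)
        noisy = mesh.copy()
        noisy.vertices = noisy.vertices + rng.normal(0, 0.05,
                                                     noisy.vertices.shape)
        rms_pre = np.sqrt(np.mean(
            (np.linalg.norm(noisy.vertices, axis=1) - 1.0) ** 2))
        smoothed = ash.preprocess_mesh(noisy, smoothing_iterations=10)
        rms_post = np.sqrt(np.mean(
            (np.linalg.norm(smoothed.vertices, axis=1) - 1.0) ** 2))
        assert rms_post < rms_pre

    def test_decimation_preserves_area(self):
        mesh = sphere_mesh(1.0, 4)
        out = ash.preprocess_mesh(mesh, smoothing_iterations=0,
                                  target_face_count=mesh.n_faces // 2)
        assert out.n_faces <= mesh.n_faces // 2
        assert abs(out.area - 4 * np.pi) / (4 * np.pi) < 0.02

    def test_tiny_target_rejected(self):
        with pytest.raises(ValueError):
            ash.preprocess_mesh(sphere_mesh(1.0, 1), target_face_count=3)


class TestClip:
    def cylinder(self, height=80.0):
        tm = trimesh.creation.cylinder(radius=10.0, height=height, sections=32)
        tm.apply_translation([0, 0, height / 2])
        return ash.SurfaceMesh(tm.vertices, tm.faces)

    def test_halfspace_respected(self):
        mesh = self.cylinder()
        out = ash.clip_mesh(mesh, ash.Plane([0, 0, 70.0], [0, 0, 1.0]))
        assert out.vertices[:, 2].max() <= 70 + 1e-9

    def test_plane_missing_mesh_is_identity(self):
        # plane below the mesh, normal pointing away: nothing discarded
        mesh = self.cylinder()
        out = ash.clip_mesh(mesh, ash.Plane([0, 0, -5.0], [0, 0, -1.0]))
        np.testing.assert_array_equal(out.vertices, mesh.vertices)

    def test_plane_engulfing_mesh_empties(self):
        # plane below the mesh, normal toward it: everything discarded
        mesh = self.cylinder()
        out = ash.clip_mesh(mesh, ash.Plane([0, 0, -5.0], [0, 0, 1.0]))
        assert out.n_faces == 0

    def test_clip_through_vertex_no_degenerate_faces(self):
        mesh = sphere_mesh(1.0, 2)
        z0 = float(mesh.vertices[10, 2])  # plane exactly through a vertex
        out = ash.clip_mesh(mesh, ash.Plane([0, 0, z0], [0, 0, 1.0]))
        out.validate()
        assert (out.face_areas() > 1e-12).all()
        e = np.sort(np.vstack([out.faces[:, [0, 1]], out.faces[:, [1, 2]],
                               out.faces[:, [2, 0]]]), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        assert counts.max() <= 2  # manifold edges only

    def test_area_conservation(self):
        mesh = sphere_mesh(1.0, 3)
        plane = ash.Plane([0, 0, 0.31], [0, 0, 1.0])
        kept = ash.clip_mesh(mesh, plane)
        removed = ash.clip_mesh(mesh, ash.Plane([0, 0, 0.31], [0, 0, -1.0]))
        assert abs(kept.area + removed.area - mesh.area) < 1e-6 * mesh.area


class TestSurfaceDistance:
    def test_self_distance_zero(self):
        mesh = sphere_mesh(5.0, 2)
        d = ash.surface_to_surface_distance(mesh, mesh)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_translated_plane(self):
        from arthroshape.synthetic import SyntheticJointSpec, make_joint
        a, _, _ = make_joint(SyntheticJointSpec(family="plane_pair",
                                                radius_a=5, resolution=0.5))
        b = a.copy()
        b.vertices = b.vertices + np.array([0, 0, 1.0])
        d = ash.surface_to_surface_distance(a, b)
        np.testing.assert_allclose(d, 1.0, atol=1e-9)

    def test_concentric_spheres(self):
        inner = sphere_mesh(10.0, 3)
        outer = sphere_mesh(12.0, 3)
        d = ash.surface_to_surface_distance(inner, outer)
        np.testing.assert_allclose(d, 2.0, atol=0.05)

    def test_matches_brute_force(self, rng):
        target = sphere_mesh(1.0, 1)  # 80 faces
        pts_mesh = ash.SurfaceMesh(rng.normal(scale=1.5, size=(40, 3)),
                                   TETRA_F)
        d = ash.surface_to_surface_distance(pts_mesh, target)
        d2, _ = closest_point_triangles(pts_mesh.vertices,
                                        target.vertices[target.faces])
        np.testing.assert_allclose(d, np.sqrt(d2.min(axis=1)), atol=0)

    def test_empty_target_rejected(self):
        mesh = sphere_mesh(1.0, 1)
        empty = ash.SurfaceMesh(np.zeros((1, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            ash.surface_to_surface_distance(mesh, empty)


def test_point_triangle_core_against_optimizer(rng):
    """The closest-point projection agrees with direct minimization over
    barycentric coordinates (independent of the region classification)."""
    from scipy.optimize import minimize

    tri = rng.normal(size=(6, 3, 3))
    pts = rng.normal(scale=2.0, size=(6, 3))
    d2, _ = closest_point_triangles(pts, tri)
    for i in range(6):
        for j in range(6):
            a, b, c = tri[j]

            def f(uv, i=i, a=a, b=b, c=c):
                u, v = uv
                q = a + u * (b - a) + v * (c - a)
                return ((pts[i] - q) ** 2).sum()

            best = min(minimize(f, x0, method="SLSQP",
                                bounds=[(0, 1), (0, 1)],
                                constraints=[{"type": "ineq",
                                              "fun": lambda x: 1 - x[0] - x[1]}]).fun
                       for x0 in ([0.3, 0.3], [0.0, 0.0], [0.9, 0.05]))
            assert d2[i, j] <= best + 1e-8
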