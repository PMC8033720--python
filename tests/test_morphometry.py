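"""Morphometry: OBJ parsing, calibration, 2D/3D distance measurement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ptosiskit import morphometry as mm
from ptosiskit.errors import (
    CalibrationError,
    GeometryError,
    MeasurementError,
    MeshFormatError,
)


# ---------------------------------------------------------------------------
# OBJ i/o


class TestReadObj:
    def test_triangle(self, tmp_path):
        p = tmp_path / "t.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        mesh = mm.read_obj_mesh(p)
        assert mesh.n_vertices == 3 and mesh.n_faces == 1

    def test_quad_fan_triangulation(self, tmp_path):
        p = tmp_path / "q.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        mesh = mm.read_obj_mesh(p)
        assert mesh.n_faces == 2
        np.testing.assert_array_equal(mesh.faces, [[0, 1, 2], [0, 2, 3]])

    def test_index_out_of_range(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 9\n")
        with pytest.raises(MeshFormatError):
            mm.read_obj_mesh(p)

    def test_non_numeric_vertex(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 zero 0\n")
        with pytest.raises(MeshFormatError):
            mm.read_obj_mesh(p)

    def test_slash_indices_and_comments(self, tmp_path):
        p = tmp_path / "s.obj"
        p.write_text("# comment\nvn 0 0 1\nv 0 0 0\nv 1 0 0\nv 0 1 0\nf 1/1/1 2/2/2 3/3/3\n")
        mesh = mm.read_obj_mesh(p)
        assert mesh.n_faces == 1

    def test_write_read_roundtrip_matches_trimesh(self, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        rng = np.random.default_rng(3)
        verts = rng.normal(size=(10, 3))
        faces = np.array([[0, 1, 2], [2, 3, 4], [5, 6, 7], [7, 8, 9]])
        path = tmp_path / "m.obj"
        mm.write_obj_mesh(mm.TriMesh(verts, faces), path)
        ours = mm.read_obj_mesh(path)
        theirs = trimesh.load(str(path), process=False)
        np.testing.assert_allclose(ours.vertices, theirs.vertices, atol=1e-5)
        np.testing.assert_array_equal(ours.faces, theirs.faces)


# ---------------------------------------------------------------------------
# calibration


class TestCalibrateScale:
    @pytest.mark.parametrize(
        "diameters, expected",
        [([98.0, 100.0, 102.0], 10.0), ([10.0], 1.0), ([50, 50, 50, 50], 5.0)],
    )
    def test_mean_over_real_diameter(self, diameters, expected):
        cal = mm.calibrate_scale(diameters)
        assert cal.s_px_per_mm == pytest.approx(expected)
        assert cal.di_px == pytest.approx(expected * 10.0)

    @pytest.mark.parametrize("bad", [[], [0.0], [-5.0, 100.0], [np.nan]])
    def test_rejects_unusable_measurements(self, bad):
        with pytest.raises(CalibrationError):
            mm.calibrate_scale(bad)


# ---------------------------------------------------------------------------
# 2D measurement


def _landmarks_2d(**overrides):
    pts = {
        "eye_center": (0.0, 0.0),
        "upper_lid_margin": (0.0, -30.0),  # 30 px above center (image y down)
        "lower_lid_margin": (0.0, 25.0),
        "inner_canthus": (0.0, 0.0),
        "epicanthus": (-10.0, 0.0),
        "outer_canthus": (300.0, 40.0),
        "fissure_upper": (10.0, -30.0),
        "fissure_lower": (10.0, 25.0),
    }
    pts.update(overrides)
    return mm.LandmarkSet("e1", {k: np.array(v) for k, v in pts.items()})


class TestMeasure2D:
    def test_hand_computed_distances(self):
        cal = mm.calibrate_scale([100.0])
        d = mm.measure_2d(_landmarks_2d(), cal)
        assert d.mrd1 == pytest.approx(3.0)
        assert d.mrd2 == pytest.approx(2.5)
        assert d.fissure_length == pytest.approx(30.0)
        # hypotenuse sqrt(300^2 + 40^2) / 10
        assert d.canthal_distance == pytest.approx(30.2655, abs=5e-4)
        assert d.inner_canthus_center == pytest.approx(0.0)
        assert d.fissure_width == pytest.approx(5.5)

    def test_mrd1_signed_negative_when_lid_covers_reflex(self):
        cal = mm.calibrate_scale([100.0])
        d = mm.measure_2d(_landmarks_2d(upper_lid_margin=(0.0, 12.0)), cal)
        assert d.mrd1 == pytest.approx(-1.2)

    def test_missing_landmark_named_in_error(self):
        pts = _landmarks_2d().points
        del pts["epicanthus"]
        lm = mm.LandmarkSet("e1", pts)
        with pytest.raises(MeasurementError, match="epicanthus"):
            mm.measure_2d(lm, mm.calibrate_scale([100.0]))

    @given(c=st.floats(min_value=0.1, max_value=50.0))
    def test_scale_equivariance(self, c):
        """Scaling pixels and disc diameters together leaves mm unchanged."""
        base = mm.measure_2d(_landmarks_2d(), mm.calibrate_scale([100.0]))
        lm = _landmarks_2d()
        scaled = mm.LandmarkSet("e1", {k: v * c for k, v in lm.points.items()})
        d = mm.measure_2d(scaled, mm.calibrate_scale([100.0 * c]))
        for name in mm.DISTANCE_NAMES:
            assert getattr(d, name) == pytest.approx(getattr(base, name), rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# surfaces


def _sphere_cap_mesh(radius=1.0, cap=0.8, n=81):
    """Dense grid mesh of the upper cap of a sphere of given radius."""
    xs = np.linspace(-cap * radius, cap * radius, n)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    mask = np.hypot(gx, gy) <= cap * radius
    gz = np.where(mask, np.sqrt(np.maximum(radius**2 - gx**2 - gy**2, 0.0)), np.nan)
    verts, faces, idx = [], [], -np.ones((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if mask[i, j]:
                idx[i, j] = len(verts)
                verts.append([gx[i, j], gy[i, j], gz[i, j]])
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]
            if min(a, b, c) >= 0:
                faces.append([a, b, c])
            if min(a, c, d) >= 0:
                faces.append([a, c, d])
    return mm.TriMesh(np.array(verts), np.array(faces))


@pytest.fixture(scope="module")
def sphere_surface():
    return mm.fit_eye_surface(_sphere_cap_mesh())


class TestFitEyeSurface:
    def test_planar_mesh_is_flat(self):
        xs = np.linspace(-1, 1, 5)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        faces = [[0, 1, 6], [0, 6, 5]]
        surf = mm.fit_eye_surface(mm.TriMesh(verts, np.array(faces)))
        pts = np.random.default_rng(0).uniform(-0.9, 0.9, size=(20, 2))
        np.testing.assert_allclose(surf.height(pts), 0.0, atol=1e-12)

    def test_interpolates_vertices(self, sphere_surface):
        mesh = _sphere_cap_mesh()
        sample = mesh.vertices[::37]
        np.testing.assert_allclose(
            sphere_surface.height(sample[:, :2]), sample[:, 2], atol=1e-6
        )

    def test_between_vertices_matches_analytic_sphere(self, sphere_surface):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-0.5, 0.5, size=(50, 2))
        analytic = np.sqrt(1.0 - (pts**2).sum(axis=1))
        rel = np.abs(sphere_surface.height(pts) - analytic) / analytic
        assert rel.max() < 0.01

    def test_landmark_outside_extent_rejected(self, sphere_surface):
        mesh = _sphere_cap_mesh()
        lm = mm.LandmarkSet("e", {"eye_center": np.array([5.0, 5.0, 0.0])})
        with pytest.raises(GeometryError):
            mm.fit_eye_surface(mesh, lm)


class TestSurfaceDistance:
    def test_plane_geodesic_equals_chord(self):
        surf = mm.EyeSurface.from_function(lambda x, y: np.zeros_like(x), (-10, 10, -10, 10))
        d = mm.surface_distance(surf, np.array([0.0, 0.0, 0.0]), np.array([3.0, 4.0, 0.0]))
        assert d == pytest.approx(5.0, rel=1e-6)

    def test_great_circle_quarter_arc(self, sphere_surface):
        """Two points 90 degrees apart: arc pi/2, chord sqrt(2)."""
        a = np.array([-np.sqrt(0.5), 0.0])
        b = np.array([np.sqrt(0.5), 0.0])
        d = mm.surface_distance(sphere_surface, a, b)
        assert d == pytest.approx(np.pi / 2, rel=0.01)
        assert d > np.sqrt(2)

    def test_exceeds_chord_everywhere(self, sphere_surface):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p, q = rng.uniform(-0.55, 0.55, size=(2, 2))
            lifted = sphere_surface.lift(np.vstack([p, q]))
            chord = np.linalg.norm(lifted[1] - lifted[0])
            assert mm.surface_distance(sphere_surface, p, q) >= chord - 1e-9

    def test_refinement_converges(self, sphere_surface):
        a, b = np.array([-0.6, 0.1]), np.array([0.55, -0.2])
        coarse = mm.surface_distance(sphere_surface, a, b, rel_tol=1e-4)
        fine = mm.surface_distance(sphere_surface, a, b, n_init=4096)
        assert abs(coarse - fine) / fine < 1e-4

    def test_outside_region_rejected(self, sphere_surface):
        with pytest.raises(GeometryError):
            mm.surface_distance(sphere_surface, np.array([0.0, 0.0]), np.array([5.0, 5.0]))


class TestMeasure3D:
    def _flat_face(self):
        xs = np.linspace(-20, 20, 41)
        ys = np.linspace(-10, 10, 21)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        ny = len(ys)
        faces = []
        for i in range(len(xs) - 1):
            for j in range(ny - 1):
                a = i * ny + j
                faces.append([a, a + ny, a + ny + 1])
                faces.append([a, a + ny + 1, a + 1])
        pts = {
            "eye_center": [0.0, 0.0, 0.0],
            "upper_lid_margin": [0.0, 4.0, 0.0],
            "lower_lid_margin": [0.0, -5.0, 0.0],
            "inner_canthus": [-14.0, 0.0, 0.0],
            "epicanthus": [-15.0, 0.5, 0.0],
            "outer_canthus": [14.0, 0.0, 0.0],
            "fissure_upper": [1.0, 4.0, 0.0],
            "fissure_lower": [1.0, -5.0, 0.0],
        }
        lm = mm.LandmarkSet("flat", {k: np.array(v) for k, v in pts.items()})
        return mm.TriMesh(verts, np.array(faces)), lm

    def test_flat_face_equals_planar_distances(self):
        mesh, lm = self._flat_face()
        d = mm.measure_3d(mesh, lm, model_units_per_mm=1.0)
        assert d.mrd1 == pytest.approx(4.0, rel=1e-6)
        assert d.mrd2 == pytest.approx(5.0, rel=1e-6)
        assert d.canthal_distance == pytest.approx(28.0, rel=1e-6)
        assert d.fissure_length == pytest.approx(28.0, rel=1e-6)
        assert d.fissure_width == pytest.approx(9.0, rel=1e-6)

    def test_unit_scale_declared_in_manifest(self):
        mesh, lm = self._flat_face()
        d = mm.measure_3d(mesh, lm, model_units_per_mm=2.0)
        assert d.mrd1 == pytest.approx(2.0, rel=1e-6)

    def test_chord_mode_never_exceeds_surface_mode(self, class_phenotypes):
        from ptosiskit import synthcohort as sc
        from ptosiskit.synthcohort import SurgeryLabel

        mesh, lm = sc.build_eye_mesh(class_phenotypes[SurgeryLabel.NO_SURGERY])
        surf = mm.measure_3d(mesh, lm, 1.0, mode="surface")
        chord = mm.measure_3d(mesh, lm, 1.0, mode="chord")
        for name in mm.DISTANCE_NAMES:
            assert abs(getattr(chord, name)) <= abs(getattr(surf, name)) + 1e-9

    def test_purity(self):
        mesh, lm = self._flat_face()
        a = mm.measure_3d(mesh, lm, 1.0)
        b = mm.measure_3d(mesh, lm, 1.0)
        assert a == b

    def test_3d_canthal_at_least_2d(self, class_phenotypes):
        """Surface path between canthi >= planar projection of its chord."""
        from ptosiskit import synthcohort as sc
        from ptosiskit.synthcohort import SurgeryLabel

        phen = class_phenotypes[SurgeryLabel.NO_SURGERY]
        mesh, lm3 = sc.build_eye_mesh(phen)
        lm2 = sc.render_landmarks_2d(phen, pixels_per_mm=10.0)
        d3 = mm.measure_3d(mesh, lm3, 1.0)
        d2 = mm.measure_2d(lm2, mm.calibrate_scale(lm2.disc_diameters_px))
        assert d3.canthal_distance >= d2.canthal_distance
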