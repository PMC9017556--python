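"""Tests for Delaunay/constrained tetrahedral meshing and sliver removal.

scipy.spatial (Qhull) serves as the independent oracle for hull volumes;
the empty-circumsphere property is checked by brute force.
"""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from medsegmesh import tetmesh as tm
from medsegmesh.errors import (
    DegenerateGeometryError,
    DuplicateVertexError,
    FlipRejectedError,
    InvalidParameterError,
)
from medsegmesh.phantom_eval import make_volume_fixtures

UNIT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


def brute_force_delaunay_check(mesh, points):
    """True iff no input point lies strictly inside any tet's circumsphere."""
    for ti in range(len(mesh.tets)):
        tp = mesh.tet_points(ti)
        tv = set(mesh.tets[ti])
        for qi in range(len(points)):
            if qi in tv:
                continue
            if tm.in_circumsphere(tp, points[qi]) == "inside":
                return False
    return True


class TestPredicates:
    def test_circumcenter_inside(self):
        assert tm.in_circumsphere(UNIT_TET, [0.5, 0.5, 0.5]) == "inside"

    def test_far_point_outside(self):
        assert tm.in_circumsphere(UNIT_TET, [2, 2, 2]) == "outside"

    def test_on_sphere_point(self):
        # circumsphere: center (1/2,1/2,1/2), R^2 = 3/4; |(1,1,1)-c|^2 = 3/4
        assert tm.in_circumsphere(UNIT_TET, [1, 1, 1]) == "on"

    def test_degenerate_tet_rejected(self):
        flat = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        with pytest.raises(DegenerateGeometryError):
            tm.in_circumsphere(flat, [0.5, 0.5, 0.5])


class TestSuperTetrahedron:
    def test_contains_all_points(self, rng):
        pts = rng.normal(2.0, 5.0, (40, 3))
        sup = tm.super_tetrahedron(pts)
        faces = [(1, 3, 2), (0, 2, 3), (0, 3, 1), (0, 1, 2)]
        for p in pts:
            assert all(tm.orient3d(sup[i], sup[j], sup[k], p) > 0 for i, j, k in faces)

    def test_single_point(self):
        sup = tm.super_tetrahedron([[1.0, 2.0, 3.0]])
        assert tm.orient3d(*sup) > 0

    def test_margin_scales_insphere_radius(self):
        pts = np.array([[0, 0, 0], [1, 1, 1.0]])

        def insphere_radius(sup):
            c = sup.mean(axis=0)
            a, b, d = sup[0], sup[1], sup[2]
            n = np.cross(b - a, d - a)
            return abs(float((c - a) @ n)) / np.linalg.norm(n)

        r1 = insphere_radius(tm.super_tetrahedron(pts, margin=1.5))
        r2 = insphere_radius(tm.super_tetrahedron(pts, margin=3.0))
        assert r2 == pytest.approx(2 * r1, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            tm.super_tetrahedron([])


class TestInsertion:
    def test_centroid_split_gives_four_tets(self):
        mesh = tm.delaunay_tetrahedralize(UNIT_TET, keep_super=True)
        tm.insert_point(mesh, UNIT_TET.mean(axis=0))
        tm.strip_super(mesh)
        assert len(mesh.tets) == 4
        assert tm.total_volume(mesh) == pytest.approx(1 / 6)

    def test_duplicate_insert_rejected(self):
        mesh = tm.delaunay_tetrahedralize(UNIT_TET, keep_super=True)
        tm.insert_point(mesh, [0.25, 0.25, 0.25])
        with pytest.raises(DuplicateVertexError):
            tm.insert_point(mesh, [0.25, 0.25, 0.25])

    def test_volume_conserved_across_random_insertions(self, rng):
        base = rng.uniform(0, 1, (10, 3))
        mesh = tm.delaunay_tetrahedralize(base, keep_super=True)
        v0 = tm.total_volume(mesh)
        for p in rng.uniform(0.2, 0.8, (15, 3)):
            tm.insert_point(mesh, p)
            assert tm.total_volume(mesh) == pytest.approx(v0, rel=1e-9)
            fm = mesh.facet_map()
            assert all(len(v) <= 2 for v in fm.values())


class TestDelaunay:
    def test_four_points_single_tet(self):
        mesh = tm.delaunay_tetrahedralize(UNIT_TET)
        assert len(mesh.tets) == 1

    def test_centroid_star(self):
        pts = np.vstack([UNIT_TET, UNIT_TET.mean(axis=0)])
        assert len(tm.delaunay_tetrahedralize(pts).tets) == 4

    def test_coplanar_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 1, 0.0]])
        with pytest.raises(DegenerateGeometryError):
            tm.delaunay_tetrahedralize(pts)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_empty_circumsphere_and_hull_volume(self, seed):
        pts = np.random.default_rng(seed).uniform(0, 1, (50, 3))
        mesh = tm.delaunay_tetrahedralize(pts)
        assert brute_force_delaunay_check(mesh, pts)
        hull = ConvexHull(pts).volume
        assert tm.total_volume(mesh) == pytest.approx(hull, rel=1e-8)

    def test_deterministic_for_fixed_input_order(self):
        pts = np.random.default_rng(9).uniform(0, 1, (30, 3))
        m1 = tm.delaunay_tetrahedralize(pts)
        m2 = tm.delaunay_tetrahedralize(pts)
        assert m1.tets == m2.tets


class TestConstraints:
    def test_convex_cube_all_faces_present(self):
        pts, cons, _ = make_volume_fixtures("cube")
        mesh = tm.constrained_delaunay(pts, cons)
        me, mf = tm.detect_lost_constraints(mesh, cons)
        assert me == [] and mf == []

    def test_empty_constraints_nothing_missing(self):
        pts = np.random.default_rng(4).uniform(0, 1, (20, 3))
        mesh = tm.delaunay_tetrahedralize(pts)
        me, mf = tm.detect_lost_constraints(mesh, tm.ConstraintSet())
        assert me == [] and mf == []

    def test_missing_face_detected(self):
        pts, cons, _ = make_volume_fixtures("cube")
        mesh = tm.constrained_delaunay(pts, cons)
        # claim a face with the other diagonal of a boundary quad: absent
        f0 = cons.faces[0]
        fake = tm.ConstraintSet(faces=[(f0[1], f0[2], (f0[0] + 4) % 8)])
        _, mf = tm.detect_lost_constraints(mesh, fake)
        assert len(mf) == 1

    def test_open_surface_rejected(self):
        pts, cons, _ = make_volume_fixtures("cube")
        open_cons = tm.ConstraintSet(faces=cons.faces[:-1])
        with pytest.raises(InvalidParameterError):
            tm.constrained_delaunay(pts, open_cons)

    @pytest.mark.parametrize(
        "name,n_interior,expected",
        [("cube", 0, 1.0), ("Lprism", 0, 0.75), ("cube", 15, 1.0), ("Lprism", 10, 0.75)],
    )
    def test_dyed_volume_matches_analytic(self, name, n_interior, expected):
        pts, cons, vol = make_volume_fixtures(name, n_interior=n_interior, seed=3)
        assert vol == expected
        mesh = tm.constrained_delaunay(pts, cons)
        assert tm.total_volume(mesh) == pytest.approx(expected, rel=1e-8)
        me, mf = tm.detect_lost_constraints(mesh, cons)
        assert me == [] and mf == []
        fm = mesh.facet_map()
        assert all(len(v) <= 2 for v in fm.values())

    def test_icosphere_volume_matches_polyhedron(self):
        pts, cons, vol = make_volume_fixtures("icosphere")
        mesh = tm.constrained_delaunay(pts, cons)
        assert tm.total_volume(mesh) == pytest.approx(vol, rel=1e-9)


class TestSlivers:
    @pytest.fixture
    def edge_star(self):
        """Three tets around edge AC with link vertices B, D, E."""
        pts = [(0, 0, 0), (0.5, 1, 0), (1, 0, 0), (0.5, -0.5, 0.8), (0.5, -0.5, -0.8)]
        mesh = tm.TetMesh(points=pts, tets=[(0, 1, 2, 3), (0, 2, 3, 4), (0, 2, 4, 1)])
        mesh.tets = [tm._oriented(mesh, t) for t in mesh.tets]
        return mesh

    def test_regular_tet_not_flagged(self):
        mesh = tm.TetMesh(points=[(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], tets=[])
        mesh.tets = [tm._oriented(mesh, (0, 1, 2, 3))]
        assert tm.find_slivers(mesh) == []
        q = tm.mesh_quality(mesh)
        assert q["min_dihedral"] == pytest.approx(np.degrees(np.arccos(1 / 3)))
        assert q["min_dihedral"] == pytest.approx(q["mean_dihedral"])

    def test_near_flat_tet_flagged(self):
        mesh = tm.TetMesh(points=[(0, 0, 0), (1, 0, 0), (0, 1, 0), (0.5, 0.5, 1e-6)], tets=[])
        mesh.tets = [tm._oriented(mesh, (0, 1, 2, 3))]
        reports = tm.find_slivers(mesh)
        assert len(reports) == 1 and reports[0].category == "type2"

    def test_empty_mesh_quality(self):
        q = tm.mesh_quality(tm.TetMesh())
        assert q["n_tets"] == 0 and q["min_dihedral"] is None

    def test_flip32_conserves_volume_and_count(self, edge_star):
        v0 = tm.total_volume(edge_star)
        n0 = len(edge_star.tets)
        tm.remove_sliver_flip32(edge_star, 0)
        assert len(edge_star.tets) == n0 - 1
        assert tm.total_volume(edge_star) == pytest.approx(v0, abs=1e-10)
        assert all(tm.tet_volume(*edge_star.tet_points(i)) > 0 for i in range(2))

    def test_flip_then_reverse_restores_configuration(self, edge_star):
        orig = {frozenset(t) for t in edge_star.tets}
        tm.remove_sliver_flip32(edge_star, 0)
        tm.flip23(edge_star, (1, 3, 4))
        assert {frozenset(t) for t in edge_star.tets} == orig

    def test_flip32_rejects_non_type1(self):
        mesh = tm.TetMesh(points=list(UNIT_TET), tets=[])
        mesh.tets = [tm._oriented(mesh, (0, 1, 2, 3))]
        with pytest.raises(InvalidParameterError):
            tm.remove_sliver_flip32(mesh, 0)

    def test_smooth_improves_free_apex(self):
        pts = [(0, 0, 0), (1, 0, 0), (0.5, 1, 0), (0.5, 0.4, 0.02)]
        mesh = tm.TetMesh(points=pts, tets=[])
        mesh.tets = [tm._oriented(mesh, (0, 1, 2, 3))]
        before = tm.mesh_quality(mesh)["min_dihedral"]
        mesh, ok = tm.remove_sliver_smooth(mesh, 0, immovable={0, 1, 2})
        assert ok
        assert tm.mesh_quality(mesh)["min_dihedral"] > before
        assert tm.tet_volume(*mesh.tet_points(0)) > 0

    def test_all_boundary_vertices_unresolved(self):
        pts = [(0, 0, 0), (1, 0, 0), (0.5, 1, 0), (0.5, 0.4, 0.02)]
        mesh = tm.TetMesh(points=pts, tets=[])
        mesh.tets = [tm._oriented(mesh, (0, 1, 2, 3))]
        _, ok = tm.remove_sliver_smooth(mesh, 0)  # every vertex is on the hull
        assert not ok

    def test_optimize_monotone_and_no_inversion(self):
        pts, cons, _ = make_volume_fixtures("cube", n_interior=25, seed=2)
        mesh = tm.constrained_delaunay(pts, cons)
        before = tm.mesh_quality(mesh)
        out = tm.optimize_slivers(mesh, rounds=4)
        after = tm.mesh_quality(out)
        assert after["min_dihedral"] >= before["min_dihedral"] - 1e-12
        assert after["total_volume"] == pytest.approx(before["total_volume"], rel=1e-9)
        assert all(tm.tet_volume(*out.tet_points(i)) > 0 for i in range(len(out.tets)))
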