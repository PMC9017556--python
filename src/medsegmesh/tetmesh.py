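"""Tetrahedral meshing: incremental (Bowyer-Watson) Delaunay construction,
constrained Delaunay with boundary recovery and dyeing-method exterior
deletion, and sliver elimination.

Points are inserted one at a time into an enclosing super-tetrahedron: the
tetrahedra whose circumspheres contain the new point are deleted, forming a
cavity, and the point is connected to every cavity boundary facet.  A
constraint surface (edges + triangular faces of a closed boundary) is then
enforced by local re-diagonalization flips and, if needed, Steiner points
placed on the offending constraint entity; finally a flood fill seeded at
the super-tetrahedron vertices ("dyeing") marks and removes everything
outside the constraint surface.

Slivers — near-zero-volume tets with nearly coplanar vertices — fall into
two categories by their neighborhood: if two facet-neighbors share a common
fifth node the sliver and those neighbors form three tets around an edge
and a 3-2 flip removes it; otherwise one of its vertices is relocated
("pulled") to maximize the worst element quality of its star, without ever
inverting an element.

Geometric predicates (orientation, insphere) are evaluated as determinants
accumulated in extended precision with a relative tolerance of 1e-10;
points on a circumsphere are treated as outside the insertion cavity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    DuplicateVertexError,
    FlipRejectedError,
    InvalidParameterError,
    RobustnessError,
    WatertightnessError,
)

log = logging.getLogger(__name__)

_REL_TOL = 1e-10


@dataclass
class ConstraintSet:
    """Boundary edges and triangular faces of a reconstructed surface model."""

    edges: list = field(default_factory=list)
    faces: list = field(default_factory=list)

    def __post_init__(self):
        self.edges = [tuple(int(i) for i in e) for e in self.edges]
        self.faces = [tuple(int(i) for i in f) for f in self.faces]
        for f in self.faces:
            if len(set(f)) != 3:
                raise InvalidParameterError(f"constraint face has repeated vertices: {f}")
        if self.edges and self.faces:
            face_edges = {
                frozenset((f[i], f[(i + 1) % 3])) for f in self.faces for i in range(3)
            }
            for e in self.edges:
                if frozenset(e) not in face_edges:
                    raise InvalidParameterError(f"edge {e} is not an edge of any face")

    def is_closed_surface(self) -> bool:
        """Every face edge shared by exactly two faces."""
        count: dict = {}
        for f in self.faces:
            for i in range(3):
                k = frozenset((f[i], f[(i + 1) % 3]))
                count[k] = count.get(k, 0) + 1
        return bool(count) and all(v == 2 for v in count.values())


@dataclass
class SliverReport:
    """One flagged thin element and its classification."""

    tet_index: int
    category: str  # "type1" | "type2"
    min_dihedral: float  # degrees
    quality: float  # volume / longest_edge^3


class TetMesh:
    """Points plus positively oriented tetrahedra.

    ``points`` is a growable list of 3-vectors, ``tets`` a list of 4-tuples
    of vertex indices with positive signed volume, ``super_vertices`` the
    indices of the enclosing tetrahedron's corners (empty after exterior
    deletion).
    """

    def __init__(self, points=None, tets=None, super_vertices=()):
        self.points = [np.asarray(p, dtype=float) for p in (points or [])]
        self.tets = [tuple(int(i) for i in t) for t in (tets or [])]
        self.super_vertices = tuple(super_vertices)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def point_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)

    def scale(self) -> float:
        if not self.points:
            return 1.0
        pts = self.point_array()
        ext = float(np.max(pts.max(axis=0) - pts.min(axis=0)))
        return ext if ext > 0 else 1.0

    def data_scale(self) -> float:
        """Extent of the non-super points (tolerance reference: the huge
        super-tet must not inflate data-relative tolerances)."""
        sup = set(self.super_vertices)
        pts = [p for i, p in enumerate(self.points) if i not in sup]
        if not pts:
            return self.scale()
        arr = np.asarray(pts)
        ext = float(np.max(arr.max(axis=0) - arr.min(axis=0)))
        return ext if ext > 0 else 1.0

    def facet_map(self) -> dict:
        """frozenset(3 vertices) -> list of incident tet indices."""
        fmap: dict = {}
        for ti, t in enumerate(self.tets):
            for i in range(4):
                f = frozenset(t[:i] + t[i + 1 :])
                fmap.setdefault(f, []).append(ti)
        return fmap

    def edge_set(self) -> set:
        es = set()
        for t in self.tets:
            for i in range(4):
                for j in range(i + 1, 4):
                    es.add(frozenset((t[i], t[j])))
        return es

    def tet_points(self, ti: int) -> np.ndarray:
        return np.asarray([self.points[v] for v in self.tets[ti]])

    def copy(self) -> "TetMesh":
        return TetMesh(list(self.points), list(self.tets), self.super_vertices)


# ---------------------------------------------------------------- predicates


def _det3(m):
    a, b, c = m
    return (
        a[0] * (b[1] * c[2] - b[2] * c[1])
        - a[1] * (b[0] * c[2] - b[2] * c[0])
        + a[2] * (b[0] * c[1] - b[1] * c[0])
    )


def _orient3d_exact(a, b, c, d):
    """Exact orientation sign via rational arithmetic (floats are exact)."""
    from fractions import Fraction

    rows = [
        [Fraction(float(p[i])) - Fraction(float(a[i])) for i in range(3)] for p in (b, c, d)
    ]
    return _det3(rows)


def orient3d(a, b, c, d) -> float:
    """Signed 6x volume of tet (a, b, c, d); > 0 for positive orientation.

    Evaluated in extended precision; when the result is below the error
    filter it is recomputed exactly in rational arithmetic, so the sign
    (and exact zero for coplanar points) is always reliable.
    """
    ld = np.longdouble
    rows = [np.asarray(p, dtype=ld) - np.asarray(a, dtype=ld) for p in (b, c, d)]
    det = float(_det3(rows))
    scale = max(float(np.max(np.abs(r))) for r in rows) or 1.0
    if abs(det) > 1e-12 * scale**3:
        return det
    return float(_orient3d_exact(a, b, c, d))


def tet_volume(a, b, c, d) -> float:
    return orient3d(a, b, c, d) / 6.0


def in_circumsphere(tet_points, q) -> str:
    """Position of q relative to the circumsphere: 'inside'/'outside'/'on'.

    Uses the standard insphere determinant on a positively oriented tet,
    accumulated in extended precision; |det| below 1e-10 * scale^5 counts
    as 'on'.  A degenerate tet raises.
    """
    pts = [np.asarray(p, dtype=float) for p in tet_points]
    q = np.asarray(q, dtype=float)
    scale = max(float(np.max(np.abs(p - q))) for p in pts) or 1.0
    orient = orient3d(*tet_points)
    if abs(orient) <= _REL_TOL * scale**3 and _orient3d_exact(*tet_points) == 0:
        raise DegenerateGeometryError("circumsphere test on a degenerate tet")
    if orient < 0:
        pts = [pts[0], pts[2], pts[1], pts[3]]

    def det_of(rows):
        d = 0
        for i in range(4):
            minor = [rows[j][:3] for j in range(4) if j != i]
            d += (-1) ** (i + 3) * rows[i][3] * _det3(minor)
        return d

    ld_rows = []
    for p in pts:
        r = np.asarray(p, dtype=np.longdouble) - np.asarray(q, dtype=np.longdouble)
        ld_rows.append([r[0], r[1], r[2], r[0] ** 2 + r[1] ** 2 + r[2] ** 2])
    det = float(det_of(ld_rows))
    if abs(det) <= _REL_TOL * scale**5:
        # below the error filter: decide exactly in rational arithmetic
        from fractions import Fraction

        fr_rows = []
        for p in pts:
            r = [Fraction(float(p[i])) - Fraction(float(q[i])) for i in range(3)]
            fr_rows.append([r[0], r[1], r[2], r[0] ** 2 + r[1] ** 2 + r[2] ** 2])
        det_exact = det_of(fr_rows)
        if det_exact == 0:
            return "on"
        det = 1.0 if det_exact > 0 else -1.0
    # with rows (p_i - q, |p_i - q|^2) and positive orientation, the
    # determinant is negative when q lies inside the circumsphere
    return "inside" if det < 0 else "outside"


def _oriented(mesh: TetMesh, t) -> tuple:
    """Return t reordered to positive orientation (raises on degenerate)."""
    pts = [mesh.points[v] for v in t]
    vol = orient3d(*pts)
    if vol == 0:
        raise DegenerateGeometryError(f"zero-volume tet {t}")
    return tuple(t) if vol > 0 else (t[0], t[2], t[1], t[3])


# ---------------------------------------------------------------- insertion


def super_tetrahedron(points, margin: float = 1.5) -> np.ndarray:
    """Regular tetrahedron whose insphere encloses the points' bounding sphere.

    Centered on the bounding-box center; the insphere radius is ``margin``
    times the bounding box's circumscribed-sphere radius, so every input
    point is strictly inside.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise InvalidParameterError("super_tetrahedron needs at least one point")
    pts = pts.reshape(-1, 3)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    center = (lo + hi) / 2.0
    r_bbox = float(np.linalg.norm(hi - lo)) / 2.0 or 1.0
    r_in = margin * r_bbox
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    dirs /= np.sqrt(3.0)
    verts = center + 3.0 * r_in * dirs  # circumradius of a regular tet = 3 * insphere
    if orient3d(*verts) < 0:
        verts = verts[[0, 2, 1, 3]]
    return verts


def _containing_tet(mesh: TetMesh, p):
    faces = [(1, 3, 2), (0, 2, 3), (0, 3, 1), (0, 1, 2)]
    for ti, t in enumerate(mesh.tets):
        pts = [mesh.points[v] for v in t]
        if all(orient3d(pts[i], pts[j], pts[k], p) >= 0.0 for i, j, k in faces):
            return ti
    return None


def _insert_vertex(mesh: TetMesh, vi: int) -> None:
    """Bowyer-Watson insertion of mesh vertex ``vi`` into the current tets."""
    p = mesh.points[vi]
    inside = set()
    for ti in range(len(mesh.tets)):
        if in_circumsphere(mesh.tet_points(ti), p) == "inside":
            inside.add(ti)
    cont = _containing_tet(mesh, p)
    if cont is None:
        raise RobustnessError(f"point {p} lies outside the current mesh")
    if not inside:
        inside = {cont}
    elif cont not in inside:
        inside.add(cont)
    # restrict to the connected component containing the containing tet
    fmap = mesh.facet_map()
    comp, queue = {cont}, [cont]
    while queue:
        ti = queue.pop()
        t = mesh.tets[ti]
        for i in range(4):
            f = frozenset(t[:i] + t[i + 1 :])
            for tj in fmap[f]:
                if tj in inside and tj not in comp:
                    comp.add(tj)
                    queue.append(tj)
    cavity = comp
    # repair until star-shaped: every boundary facet must see p strictly on
    # the same side as the cavity tet it bounds, otherwise connecting p to
    # it would create an inverted/overlapping element (the mesh need not be
    # Delaunay here — recovery flips may have preceded this insertion)
    for _ in range(len(mesh.tets)):
        bad = None
        boundary = []
        for ti in cavity:
            t = mesh.tets[ti]
            for i in range(4):
                f = t[:i] + t[i + 1 :]
                others = [tj for tj in fmap[frozenset(f)] if tj != ti]
                if others and others[0] in cavity:
                    continue
                boundary.append((f, t[i], others[0] if others else None))
        for f, opp, nb in boundary:
            a, b, c = (mesh.points[v] for v in f)
            s_p = orient3d(a, b, c, p)
            s_v = orient3d(a, b, c, mesh.points[opp])
            if s_p == 0.0 or (s_p > 0) != (s_v > 0):
                bad = nb
                break
        if bad is None:
            break
        if bad is not None and bad not in cavity:
            cavity.add(bad)
        else:
            raise RobustnessError(f"non-star-shaped cavity while inserting {p}")
    else:
        raise RobustnessError(f"cavity repair did not terminate for {p}")
    new_tets = []
    for f, _opp, _nb in boundary:
        a, b, c = (mesh.points[v] for v in f)
        if orient3d(a, b, c, p) > 0:
            new_tets.append((f[0], f[1], f[2], vi))
        else:
            new_tets.append((f[0], f[2], f[1], vi))
    mesh.tets = [t for ti, t in enumerate(mesh.tets) if ti not in cavity] + new_tets


def insert_point(mesh: TetMesh, p) -> TetMesh:
    """Insert a point into the mesh (must lie strictly inside it).

    Deletes every tet whose circumsphere contains the point, verifies the
    cavity is star-shaped around it, and connects the point to each cavity
    boundary facet.  Mutates and returns ``mesh``.
    """
    p = np.asarray(p, dtype=float)
    tol = 1e-9 * mesh.data_scale()
    for q in mesh.points:
        if np.linalg.norm(q - p) < tol:
            raise DuplicateVertexError(f"point {p} coincides with an existing vertex")
    mesh.points.append(p)
    try:
        _insert_vertex(mesh, len(mesh.points) - 1)
    except Exception:
        mesh.points.pop()
        raise
    return mesh


def delaunay_tetrahedralize(
    points, keep_super: bool = False, super_margin: float = 1e4
) -> TetMesh:
    """Incremental Delaunay tetrahedralization of a point set.

    Points are inserted in input order (deterministic) into a super-
    tetrahedron; afterwards every tet incident to a super-tet vertex is
    deleted, unless ``keep_super`` (used by the constrained pipeline, which
    needs the exterior tets for dyeing).  The enclosing tetrahedron is made
    very large (``super_margin``) so that thin hull elements — whose
    circumspheres can be much bigger than the input extent — survive; the
    exact-arithmetic predicate fallback keeps the large coordinates safe.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 4:
        raise InvalidParameterError("need at least 4 points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * (np.abs(pts).max() or 1.0)) < 3:
        raise DegenerateGeometryError("all points are coplanar")
    n = pts.shape[0]
    sup = super_tetrahedron(pts, margin=super_margin)
    mesh = TetMesh(
        points=list(pts) + list(sup),
        tets=[(n, n + 1, n + 2, n + 3)],
        super_vertices=(n, n + 1, n + 2, n + 3),
    )
    for vi in range(n):
        _insert_vertex(mesh, vi)
    if not keep_super:
        strip_super(mesh)
    return mesh


def strip_super(mesh: TetMesh) -> TetMesh:
    """Remove super-tet vertices and every tet incident to them."""
    sup = set(mesh.super_vertices)
    if not sup:
        return mesh
    mesh.tets = [t for t in mesh.tets if not (set(t) & sup)]
    used_super = sup & {v for t in mesh.tets for v in t}
    if used_super:  # pragma: no cover - defensive
        raise RobustnessError("super vertices still referenced after stripping")
    keep = [i for i in range(len(mesh.points)) if i not in sup]
    remap = {old: new for new, old in enumerate(keep)}
    mesh.points = [mesh.points[i] for i in keep]
    mesh.tets = [tuple(remap[v] for v in t) for t in mesh.tets]
    mesh.super_vertices = ()
    return mesh


# ---------------------------------------------------------------- constraints


def _on_segment(p, a, b, tol):
    ab = b - a
    L2 = float(ab @ ab)
    if L2 == 0:
        return None
    t = float((p - a) @ ab) / L2
    if t < -tol or t > 1 + tol:
        return None
    closest = a + t * ab
    if np.linalg.norm(p - closest) > tol * np.sqrt(L2):
        return None
    return t


def _tri_frame(a, b, c):
    n = np.cross(b - a, c - a)
    area2 = np.linalg.norm(n)
    if area2 == 0:
        raise DegenerateGeometryError("degenerate constraint face")
    return n / area2, area2 / 2.0


def _in_triangle(p, a, b, c, tol):
    """True if p lies on the (closed) triangle abc within tolerance."""
    n, _ = _tri_frame(a, b, c)
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a))
    if abs(float((p - a) @ n)) > tol * scale:
        return False
    # barycentric via projected areas
    d = float(np.cross(b - a, c - a) @ n)
    u = float(np.cross(b - p, c - p) @ n) / d
    v = float(np.cross(c - p, a - p) @ n) / d
    w = 1.0 - u - v
    return u >= -tol and v >= -tol and w >= -tol


def detect_lost_constraints(mesh: TetMesh, constraints: ConstraintSet):
    """Constraint edges/faces not realized as unions of mesh edges/facets.

    An edge is present when the mesh vertices lying on it, walked from one
    endpoint to the other, are pairwise connected by mesh edges; a face is
    present when the mesh facets whose vertices lie on it tile its full
    area.  Returns ``(missing_edges, missing_faces)``.
    """
    tol = 1e-9
    pts = mesh.point_array()
    edges = mesh.edge_set()
    missing_edges = []
    for a, b in constraints.edges:
        on = []
        for vi in range(len(pts)):
            t = _on_segment(pts[vi], pts[a], pts[b], tol)
            if t is not None:
                on.append((t, vi))
        on.sort()
        chain_ok = (
            len(on) >= 2
            and on[0][1] == a
            and on[-1][1] == b
            and all(
                frozenset((on[i][1], on[i + 1][1])) in edges for i in range(len(on) - 1)
            )
        )
        if not chain_ok:
            missing_edges.append((a, b))
    fmap = mesh.facet_map()
    missing_faces = []
    for f in constraints.faces:
        a, b, c = pts[f[0]], pts[f[1]], pts[f[2]]
        _n, area = _tri_frame(a, b, c)
        on_face = {vi for vi in range(len(pts)) if _in_triangle(pts[vi], a, b, c, tol)}
        covered = 0.0
        for facet in fmap:
            vs = tuple(facet)
            if all(v in on_face for v in vs):
                p0, p1, p2 = pts[vs[0]], pts[vs[1]], pts[vs[2]]
                covered += float(np.linalg.norm(np.cross(p1 - p0, p2 - p0))) / 2.0
        if abs(covered - area) > 1e-6 * area:
            missing_faces.append(f)
    return missing_edges, missing_faces


def _rediagonalize_edge(mesh: TetMesh, a: int, b: int) -> bool:
    """Try to realize segment ab by flipping a crossing coplanar diagonal.

    Looks for a mesh edge cd crossing ab with (a, c, b, d) planar; on each
    side of the plane with a single apex e, the pair of tets {c,d,a,e},
    {c,d,b,e} is replaced by {a,b,c,e}, {a,b,d,e} (a 2-2 / 4-4 flip).
    """
    pts = mesh.point_array()
    pa, pb = pts[a], pts[b]
    vol_tol = _REL_TOL * mesh.data_scale() ** 3
    for cd in mesh.edge_set():
        c, d = tuple(cd)
        if len({a, b, c, d}) != 4:
            continue
        pc, pd = pts[c], pts[d]
        if abs(orient3d(pa, pb, pc, pd)) > vol_tol:
            continue  # not coplanar
        # segments ab and cd must cross in their interiors (2-D test in-plane)
        n = np.cross(pb - pa, pd - pc)
        if np.linalg.norm(n) == 0:
            continue
        u = np.cross(n, pb - pa)
        v = np.cross(n, pd - pc)
        denom_cd = float((pd - pc) @ u)
        denom_ab = float((pb - pa) @ v)
        if abs(denom_cd) < 1e-14 or abs(denom_ab) < 1e-14:
            continue
        t_cd = float((pa - pc) @ u) / denom_cd
        t_ab = float((pc - pa) @ v) / denom_ab
        if not (1e-9 < t_cd < 1 - 1e-9 and 1e-9 < t_ab < 1 - 1e-9):
            continue
        incident = [ti for ti, t in enumerate(mesh.tets) if c in t and d in t]
        partners: dict = {}
        for ti in incident:
            rest = [v_ for v_ in mesh.tets[ti] if v_ not in (c, d)]
            for e in rest:
                other = rest[0] if rest[1] == e else rest[1]
                partners.setdefault(e, {})[other] = ti
        # the flip must consume every tet around cd (both sides of the
        # quad plane), otherwise it would leave a cracked interface
        apexes = [
            e
            for e, mates in partners.items()
            if e not in (a, b) and {a, b} <= set(mates)
        ]
        covered = {ti for e in apexes for ti in (partners[e][a], partners[e][b])}
        if len(covered) != len(incident):
            continue
        new_tets = []
        ok = True
        for e in apexes:
            new1 = _try_orient(mesh, (a, b, c, e), vol_tol)
            new2 = _try_orient(mesh, (a, b, d, e), vol_tol)
            if new1 is None or new2 is None:
                ok = False
                break
            new_tets += [new1, new2]
        if not ok:
            continue
        drop = set(incident)
        mesh.tets = [t for ti, t in enumerate(mesh.tets) if ti not in drop] + new_tets
        return True
    return False


def _try_orient(mesh: TetMesh, t, vol_tol):
    pts = [mesh.points[v] for v in t]
    vol = orient3d(*pts)
    if abs(vol) <= vol_tol:
        return None
    return tuple(t) if vol > 0 else (t[0], t[2], t[1], t[3])


def recover_constraints(mesh: TetMesh, constraints: ConstraintSet, max_rounds: int = 50):
    """Enforce the constraint edges and faces in the mesh.

    Strategy: local re-diagonalization flips first (sufficient for planar
    boundary mismatches, the common case for piecewise-planar solids); when
    no flip applies, a Steiner point is inserted on the first unrealized
    constraint entity (midpoint of the missing sub-segment for an edge,
    centroid for a face) and the loop re-detects.  Raises after
    ``max_rounds`` without success.
    """
    pts0 = None
    for _ in range(max_rounds):
        missing_edges, missing_faces = detect_lost_constraints(mesh, constraints)
        if not missing_edges and not missing_faces:
            return mesh
        progressed = False
        for a, b in missing_edges:
            if _rediagonalize_edge(mesh, a, b):
                progressed = True
        if progressed:
            continue
        pts0 = mesh.point_array()
        candidates = []
        if missing_edges:
            a, b = missing_edges[0]
            tol = 1e-9
            on = sorted(
                (t, vi)
                for vi in range(len(pts0))
                if (t := _on_segment(pts0[vi], pts0[a], pts0[b], tol)) is not None
            )
            edges = mesh.edge_set()
            for i in range(len(on) - 1):
                if frozenset((on[i][1], on[i + 1][1])) not in edges:
                    t_mid = (on[i][0] + on[i + 1][0]) / 2.0
                    candidates.append(pts0[a] + t_mid * (pts0[b] - pts0[a]))
            candidates.append((pts0[a] + pts0[b]) / 2.0)
        else:
            f = missing_faces[0]
            a, b, c = pts0[f[0]], pts0[f[1]], pts0[f[2]]
            # an edge piercing the face interior blocks it; the crossing
            # point lies on the face, so it is an admissible Steiner point
            candidates.extend(_face_piercings(mesh, a, b, c))
            centroid = (a + b + c) / 3.0
            candidates.append(centroid)
            # fallbacks stay inside the face: blend centroid toward corners
            candidates.extend(0.5 * centroid + 0.5 * v for v in (a, b, c))
        dup_tol = 1e-9 * mesh.data_scale()
        for cand in candidates:
            if any(np.linalg.norm(q - cand) < dup_tol for q in mesh.points):
                continue
            insert_point(mesh, cand)
            break
        else:
            raise RobustnessError("no admissible Steiner point for a lost constraint")
    raise RobustnessError("constraint recovery did not converge")


def _face_piercings(mesh: TetMesh, a, b, c):
    """Points where mesh edges cross the open interior of triangle abc."""
    pts = mesh.point_array()
    n, _area = _tri_frame(a, b, c)
    out = []
    for uv in sorted(mesh.edge_set(), key=sorted):
        u, v = (pts[i] for i in tuple(uv))
        du = float((u - a) @ n)
        dv = float((v - a) @ n)
        if du * dv >= 0:  # same side or touching the plane
            continue
        t = du / (du - dv)
        x = u + t * (v - u)
        d = float(np.cross(b - a, c - a) @ n)
        w1 = float(np.cross(b - x, c - x) @ n) / d
        w2 = float(np.cross(c - x, a - x) @ n) / d
        w3 = 1.0 - w1 - w2
        if min(w1, w2, w3) > 1e-9:  # strictly interior crossing
            out.append(x)
    return out


def _facet_is_constrained(mesh: TetMesh, facet, constraints: ConstraintSet, tol=1e-9):
    pts = mesh.point_array()
    vs = tuple(facet)
    centroid = pts[list(vs)].mean(axis=0)
    for f in constraints.faces:
        a, b, c = pts[f[0]], pts[f[1]], pts[f[2]]
        if all(_in_triangle(pts[v], a, b, c, tol) for v in vs) and _in_triangle(
            centroid, a, b, c, tol
        ):
            return True
    return False


def dye_exterior(mesh: TetMesh, constraints: ConstraintSet) -> TetMesh:
    """Delete everything outside the constraint surface by flood fill.

    Seeds: all tets incident to a super-tet vertex (guaranteed exterior).
    The fill never crosses a facet lying on a constraint face.  Exterior
    tets are deleted along with the super-tet vertices.  Raises if the fill
    consumes the entire mesh (a leak through the surface).
    """
    missing_e, missing_f = detect_lost_constraints(mesh, constraints)
    if missing_e or missing_f:
        raise InvalidParameterError("all constraint entities must be present before dyeing")
    sup = set(mesh.super_vertices)
    fmap = mesh.facet_map()
    constrained_cache: dict = {}

    def is_constrained(f):
        if f not in constrained_cache:
            constrained_cache[f] = _facet_is_constrained(mesh, f, constraints)
        return constrained_cache[f]

    exterior = {ti for ti, t in enumerate(mesh.tets) if set(t) & sup}
    queue = list(exterior)
    while queue:
        ti = queue.pop()
        t = mesh.tets[ti]
        for i in range(4):
            f = frozenset(t[:i] + t[i + 1 :])
            if is_constrained(f):
                continue
            for tj in fmap[f]:
                if tj not in exterior:
                    exterior.add(tj)
                    queue.append(tj)
    kept = [t for ti, t in enumerate(mesh.tets) if ti not in exterior]
    if not kept:
        raise WatertightnessError("exterior fill consumed the whole mesh (surface leak)")
    mesh.tets = kept
    strip_super(mesh)
    return mesh


def constrained_delaunay(points, constraints: ConstraintSet) -> TetMesh:
    """Constrained Delaunay tetrahedralization of a closed surface + points.

    Runs the incremental Delaunay construction (keeping the super-tet),
    detects lost boundary edges/faces, recovers them (flips, then Steiner
    points restricted to the constraint entities), and deletes the exterior
    by dyeing.  Every constraint edge/face is present in the result as a
    union of mesh edges/facets.
    """
    if not constraints.faces:
        raise InvalidParameterError("constrained_delaunay needs constraint faces")
    if not constraints.is_closed_surface():
        raise InvalidParameterError("constraint faces do not form a closed surface")
    mesh = delaunay_tetrahedralize(points, keep_super=True)
    recover_constraints(mesh, constraints)
    return dye_exterior(mesh, constraints)


# ---------------------------------------------------------------- quality


def _dihedrals_deg(pts4) -> np.ndarray:
    """The 6 interior dihedral angles of a tet, in degrees."""
    pts4 = np.asarray(pts4, dtype=float)
    angles = []
    for i in range(4):
        for j in range(i + 1, 4):
            k, l = [m for m in range(4) if m not in (i, j)]
            u = pts4[j] - pts4[i]
            u = u / (np.linalg.norm(u) or 1.0)
            v1 = pts4[k] - pts4[i]
            v2 = pts4[l] - pts4[i]
            v1 = v1 - (v1 @ u) * u
            v2 = v2 - (v2 @ u) * u
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                angles.append(0.0)
                continue
            cosang = np.clip((v1 @ v2) / (n1 * n2), -1.0, 1.0)
            angles.append(float(np.degrees(np.arccos(cosang))))
    return np.asarray(angles)


def _quality(pts4) -> float:
    """Volume over cubed longest edge (regular tet ~ 0.1178)."""
    pts4 = np.asarray(pts4, dtype=float)
    vol = abs(tet_volume(*pts4))
    longest = max(
        np.linalg.norm(pts4[i] - pts4[j]) for i in range(4) for j in range(i + 1, 4)
    )
    return vol / longest**3 if longest > 0 else 0.0


def find_slivers(mesh: TetMesh, dihedral_deg: float = 5.0, q_thresh: float = 0.01):
    """Flag thin elements and classify them.

    A tet is a sliver when its minimum dihedral is below ``dihedral_deg``
    or its volume/(longest edge)^3 ratio is below ``q_thresh``.  It is
    ``type1`` when it has all four facet-neighbors and two of them share a
    common fifth node (three tets around an edge — removable by a 3-2
    flip); otherwise ``type2``.
    """
    fmap = mesh.facet_map()
    reports = []
    for ti, t in enumerate(mesh.tets):
        pts4 = mesh.tet_points(ti)
        mind = float(_dihedrals_deg(pts4).min())
        q = _quality(pts4)
        if mind >= dihedral_deg and q >= q_thresh:
            continue
        n_neighbors = sum(
            1
            for i in range(4)
            if len(fmap[frozenset(t[:i] + t[i + 1 :])]) == 2
        )
        cat = "type2"  # boundary slivers (missing neighbors) stay type2
        if n_neighbors == 4 and _type1_config(mesh, ti, fmap) is not None:
            cat = "type1"
        reports.append(SliverReport(ti, cat, mind, q))
    return reports


def _type1_config(mesh: TetMesh, ti: int, fmap=None):
    """If two facet-neighbors of tet ``ti`` share a fifth node, return
    ``(neighbor1, neighbor2, shared_edge, other_two, fifth_node)``."""
    fmap = fmap or mesh.facet_map()
    t = mesh.tets[ti]
    nbs = []  # (opposite vertex of sliver, neighbor tet index, extra vertex)
    for i in range(4):
        f = frozenset(t[:i] + t[i + 1 :])
        others = [tj for tj in fmap[f] if tj != ti]
        if others:
            tj = others[0]
            extra = next(v for v in mesh.tets[tj] if v not in f)
            nbs.append((t[i], tj, extra))
    for x in range(len(nbs)):
        for y in range(x + 1, len(nbs)):
            if nbs[x][2] == nbs[y][2] and nbs[x][2] not in t:
                v1, t1, e = nbs[x]
                v2, t2, _ = nbs[y]
                shared = [v for v in t if v not in (v1, v2)]
                return (t1, t2, tuple(shared), (v1, v2), e)
    return None


def remove_sliver_flip32(mesh: TetMesh, tet_index: int) -> TetMesh:
    """Remove a type-1 sliver by a 3-2 flip.

    The sliver and the two neighbors sharing the fifth node E form three
    tets around the shared edge; they are replaced by the two tets joining
    the remaining triangle to each end of that edge.  Total volume is
    conserved and the tet count drops by one.
    """
    cfg = _type1_config(mesh, tet_index)
    if cfg is None:
        raise InvalidParameterError("tet is not in a type-1 sliver configuration")
    t1, t2, (p, q_), (r, s), e = cfg
    vol_tol = _REL_TOL * mesh.data_scale() ** 3
    new1 = _try_orient(mesh, (r, s, e, p), vol_tol)
    new2 = _try_orient(mesh, (r, s, e, q_), vol_tol)
    if new1 is None or new2 is None:
        raise FlipRejectedError("3-2 flip would create a non-positive element")
    drop = {tet_index, t1, t2}
    mesh.tets = [t for ti, t in enumerate(mesh.tets) if ti not in drop] + [new1, new2]
    return mesh


def flip23(mesh: TetMesh, facet) -> TetMesh:
    """2-3 flip: replace the two tets sharing ``facet`` by three around the
    edge joining their apexes (the inverse of the 3-2 flip).

    Requires the apex-apex segment to pass through the shared facet, so the
    three new tets are all positively orientable.
    """
    f = frozenset(facet)
    tis = [ti for ti, t in enumerate(mesh.tets) if f <= set(t)]
    if len(tis) != 2:
        raise InvalidParameterError("facet is not shared by exactly two tets")
    apexes = [next(v for v in mesh.tets[ti] if v not in f) for ti in tis]
    a, c = apexes
    x, y, z = tuple(f)
    vol_tol = _REL_TOL * mesh.data_scale() ** 3
    new = []
    for p, q_ in ((x, y), (y, z), (z, x)):
        t = _try_orient(mesh, (a, c, p, q_), vol_tol)
        if t is None:
            raise FlipRejectedError("2-3 flip would create a non-positive element")
        new.append(t)
    mesh.tets = [t for ti, t in enumerate(mesh.tets) if ti not in tis] + new
    return mesh


def boundary_vertices(mesh: TetMesh) -> set:
    """Vertices on facets bounded by exactly one tet."""
    out = set()
    for f, tis in mesh.facet_map().items():
        if len(tis) == 1:
            out |= set(f)
    return out


def remove_sliver_smooth(mesh: TetMesh, tet_index: int, immovable=None):
    """Try to remove a type-2 sliver by relocating one of its vertices.

    Each movable vertex (not on the boundary / constraint surface) is
    optimized to maximize the minimum quality ratio over its star of tets,
    rejecting any position that inverts an element; the best strictly
    improving move is accepted.  Returns ``(mesh, resolved)``; an
    unresolvable sliver (e.g. all vertices immovable) is reported, not
    raised.
    """
    from scipy.optimize import minimize

    immovable = boundary_vertices(mesh) if immovable is None else set(immovable)
    t = mesh.tets[tet_index]
    movable = [v for v in t if v not in immovable]
    if not movable:
        log.info("sliver %d unresolved: all vertices on the boundary", tet_index)
        return mesh, False

    def star_min_quality(v, pos):
        worst = np.inf
        for tt in mesh.tets:
            if v not in tt:
                continue
            pts4 = [pos if vv == v else mesh.points[vv] for vv in tt]
            if orient3d(*pts4) <= 0:
                return -1.0
            worst = min(worst, _quality(pts4))
        return worst

    best = (None, None, -np.inf)
    for v in movable:
        base = star_min_quality(v, mesh.points[v])
        res = minimize(
            lambda x, v=v: -star_min_quality(v, x),
            mesh.points[v],
            method="Nelder-Mead",
            options={"maxiter": 200, "xatol": 1e-8, "fatol": 1e-12},
        )
        gain = -res.fun - base
        if -res.fun > 0 and gain > 1e-12 and -res.fun > best[2]:
            best = (v, res.x, -res.fun)
    v, pos, _ = best
    if v is None:
        log.info("sliver %d unresolved: no improving relocation found", tet_index)
        return mesh, False
    mesh.points[v] = np.asarray(pos, dtype=float)
    return mesh, True


def mesh_quality(mesh: TetMesh) -> dict:
    """Aggregate quality summary: dihedral stats, quality ratio, counts."""
    if not mesh.tets:
        return {
            "n_tets": 0,
            "min_dihedral": None,
            "mean_dihedral": None,
            "min_quality": None,
            "total_volume": 0.0,
        }
    dih = np.concatenate([_dihedrals_deg(mesh.tet_points(ti)) for ti in range(len(mesh.tets))])
    quals = [_quality(mesh.tet_points(ti)) for ti in range(len(mesh.tets))]
    return {
        "n_tets": len(mesh.tets),
        "min_dihedral": float(dih.min()),
        "mean_dihedral": float(dih.mean()),
        "min_quality": float(min(quals)),
        "total_volume": total_volume(mesh),
    }


def total_volume(mesh: TetMesh) -> float:
    return float(sum(tet_volume(*mesh.tet_points(ti)) for ti in range(len(mesh.tets))))


def optimize_slivers(
    mesh: TetMesh, dihedral_deg: float = 5.0, q_thresh: float = 0.01, rounds: int = 3
) -> TetMesh:
    """Sliver-elimination pass: 3-2 flips for type-1, relocation for type-2.

    An operation is accepted only if it does not lower the global minimum
    dihedral angle; elements are never inverted.
    """
    for _ in range(rounds):
        reports = find_slivers(mesh, dihedral_deg, q_thresh)
        if not reports:
            break
        before = mesh_quality(mesh)["min_dihedral"]
        changed = False
        for rep in sorted(reports, key=lambda r: r.min_dihedral):
            if rep.tet_index >= len(mesh.tets):
                continue  # indices shifted by an earlier accepted operation
            trial = mesh.copy()
            try:
                if rep.category == "type1":
                    remove_sliver_flip32(trial, rep.tet_index)
                    ok = True
                else:
                    trial, ok = remove_sliver_smooth(trial, rep.tet_index)
            except (InvalidParameterError, FlipRejectedError):
                ok = False
            if ok and mesh_quality(trial)["min_dihedral"] >= before - 1e-12:
                mesh.points, mesh.tets = trial.points, trial.tets
                changed = True
                break  # re-detect with fresh indices
        if not changed:
            break
    return mesh
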