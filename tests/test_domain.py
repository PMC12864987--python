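"""Meshing, boundary extraction, deformation and conservative remapping."""

import numpy as np
import pytest
from matplotlib.tri import Triangulation

from limbrd import (
    BoundaryCurve,
    MeshingError,
    RemapError,
    deform_vertices,
    extract_boundary_mesh,
    remap_fields,
    triangulate_domain,
)
from limbrd.fixtures import LimbTrajectoryParams, make_limb_trajectory


def square(side=1.0):
    return BoundaryCurve(np.array([[0.0, 0.0], [side, 0], [side, side], [0, side]]))


class TestTriangulation:
    def test_unit_square_tiles_exactly(self):
        mesh = triangulate_domain(square(), 0.1)
        assert abs(mesh.areas.sum() - 1.0) < 1e-9
        assert (mesh.areas > 0).all()  # CCW winding throughout

    def test_boundary_edge_length_bound(self):
        mesh = triangulate_domain(square(), 0.1)
        nb = mesh.n_boundary
        b = mesh.vertices[:nb]
        seg = np.linalg.norm(np.roll(b, -1, axis=0) - b, axis=1)
        assert seg.max() <= 1.5 * 0.1

    def test_limb_and_flank_union_meshes_as_one_region(self):
        th = np.linspace(0, np.pi, 40)
        arc = np.column_stack([0.5 * np.cos(th), 0.9 * np.sin(th)])
        verts = np.vstack([arc, [[-0.5, -0.25], [0.5, -0.25]]])
        bc = BoundaryCurve(verts, flank_edge=(len(arc) - 1, 0))
        mesh = triangulate_domain(bc, 0.08)
        assert abs(mesh.areas.sum() - bc.polygon.area) < 1e-9 * bc.polygon.area
        # connected: every triangle reachable through adjacency
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        M = len(mesh.triangles)
        i, j = mesh.adj_tris[:, 0], mesh.adj_tris[:, 1]
        g = coo_matrix((np.ones(len(i)), (i, j)), shape=(M, M))
        n_comp, _ = connected_components(g, directed=False)
        assert n_comp == 1

    def test_self_intersecting_boundary_rejected(self):
        with pytest.raises(MeshingError):
            BoundaryCurve(np.array([[0.0, 0], [1, 1], [1, 0], [0, 1]]))  # bow-tie

    def test_clockwise_boundary_rejected(self):
        with pytest.raises(MeshingError, match="counter-clockwise"):
            BoundaryCurve(np.array([[0.0, 0], [0, 1], [1, 1], [1, 0]]))

    def test_determinism(self):
        a = triangulate_domain(square(), 0.13)
        b = triangulate_domain(square(), 0.13)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        np.testing.assert_array_equal(a.triangles, b.triangles)

    def test_adjacency_is_symmetric(self):
        mesh = triangulate_domain(square(), 0.1)
        nb = mesh.neighbors
        for ti, row in enumerate(nb):
            for tj in row[row >= 0]:
                assert ti in nb[tj]


class TestBoundaryMesh:
    def test_closed_chain_covers_perimeter(self):
        bc = square()
        mesh = triangulate_domain(bc, 0.1)
        bm = extract_boundary_mesh(mesh, bc)
        assert bm.closed
        assert abs(bm.lengths(mesh.vertices).sum() - 4.0) < 1e-9

    def test_every_element_coincides_with_one_triangle_edge(self):
        bc = square()
        mesh = triangulate_domain(bc, 0.1)
        bm = extract_boundary_mesh(mesh, bc)
        edges = {}
        for ti, tri in enumerate(mesh.triangles):
            for u, v in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                edges.setdefault((min(u, v), max(u, v)), []).append(ti)
        for (u, v), owner in zip(bm.elements, bm.owner_triangle):
            owners = edges[(min(u, v), max(u, v))]
            assert owners == [owner]

    def test_flank_edge_yields_open_chain(self):
        th = np.linspace(0, np.pi, 30)
        arc = np.column_stack([0.5 * np.cos(th), 0.8 * np.sin(th)])
        verts = np.vstack([arc, [[-0.5, -0.2], [0.5, -0.2]]])
        bc = BoundaryCurve(verts, flank_edge=(len(arc) - 1, 0))
        mesh = triangulate_domain(bc, 0.09)
        bm = extract_boundary_mesh(mesh, bc)
        assert not bm.closed
        # chain interior elements have two neighbours, the two ends one each
        pairs = bm.chain_pairs()
        deg = np.zeros(len(bm.elements), int)
        for i, j in pairs:
            deg[i] += 1
            deg[j] += 1
        assert sorted(deg)[:2] == [1, 1] and (deg[1:-1] == 2).all()


@pytest.fixture(scope="module")
def frame():
    return make_limb_trajectory(
        LimbTrajectoryParams(start_stage="mE10:09", end_stage="mE10:12",
                             target_edge_length=0.15)
    )


class TestDeformation:

    def test_s0_is_identity(self, frame):
        f = frame.frames[0]
        np.testing.assert_array_equal(deform_vertices(f, 0.0), f.mesh.vertices)

    def test_s1_lands_on_next_boundary(self, frame):
        f0, f1 = frame.frames[0], frame.frames[1]
        end = deform_vertices(f0, 1.0)
        nb = f0.mesh.n_boundary
        assert np.abs(end[:nb] - f1.boundary.vertices).max() < 1e-12

    def test_midpoint_of_linear_blend(self, frame):
        f = frame.frames[0]
        mid = deform_vertices(f, 0.5)
        np.testing.assert_allclose(mid, 0.5 * (f.mesh.vertices + f.end_positions))
        assert (f.mesh.triangle_areas(mid) > 0).all()

    def test_fraction_outside_unit_interval_rejected(self, frame):
        with pytest.raises(ValueError):
            deform_vertices(frame.frames[0], 1.5)


@pytest.fixture(scope="module")
def meshes():
    return triangulate_domain(square(), 0.1), triangulate_domain(square(), 0.13)


class TestRemap:

    def test_identity_remap(self, meshes):
        old, _ = meshes
        u = np.linspace(0, 1, len(old.triangles))
        v = remap_fields(old, old, u)
        np.testing.assert_allclose(v, u, atol=1e-12)

    def test_integral_preserved(self, meshes):
        old, new = meshes
        rng = np.random.default_rng(5)
        u = rng.random(len(old.triangles))
        v = remap_fields(old, new, u)
        before = float((u * old.areas).sum())
        after = float((v * new.areas).sum())
        assert abs(after - before) < 1e-8 * before

    def test_constant_preserved_pointwise(self, meshes):
        old, new = meshes
        v = remap_fields(old, new, np.full(len(old.triangles), 2.5))
        np.testing.assert_allclose(v, 2.5, atol=1e-9)

    def test_round_trip_smooths_but_conserves(self, meshes):
        old, new = meshes
        rng = np.random.default_rng(11)
        u = rng.random(len(old.triangles))
        back = remap_fields(new, old, remap_fields(old, new, u))
        assert abs((back * old.areas).sum() - (u * old.areas).sum()) < 1e-8
        # spatial variance cannot increase under averaging
        A = old.areas

        def wvar(f):
            m = (f * A).sum() / A.sum()
            return ((f - m) ** 2 * A).sum() / A.sum()

        assert wvar(back) <= wvar(u) + 1e-12

    def test_monte_carlo_point_sampling_oracle(self, meshes):
        """Per-element remapped values agree with dense point sampling."""
        old, new = meshes
        rng = np.random.default_rng(7)
        u = rng.random(len(old.triangles))
        v = remap_fields(old, new, u)

        tri = Triangulation(old.vertices[:, 0], old.vertices[:, 1], old.triangles)
        finder = tri.get_trifinder()
        n_pts = 4000
        for ei in range(0, len(new.triangles), 7):
            a, b, c = new.vertices[new.triangles[ei]]
            r1 = np.sqrt(rng.random(n_pts))
            r2 = rng.random(n_pts)
            pts = (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (
                r1 * r2
            )[:, None] * c
            which = finder(pts[:, 0], pts[:, 1])
            vals = u[np.where(which >= 0, which, 0)]
            est = vals[which >= 0].mean()
            sem = vals[which >= 0].std() / np.sqrt((which >= 0).sum())
            assert abs(v[ei] - est) < max(5 * sem, 1e-3)

    def test_disjoint_meshes_rejected(self, meshes):
        old, _ = meshes
        far = BoundaryCurve(np.array([[10.0, 10], [11, 10], [11, 11], [10, 11]]))
        new = triangulate_domain(far, 0.2)
        with pytest.raises(RemapError):
            remap_fields(old, new, np.ones(len(old.triangles)))
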