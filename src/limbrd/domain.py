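"""Dynamic 2D simulation domains: meshing, deformation and conservative remap.

The simulation domain is a simple closed polygon (the limb-bud outline plus a
rectangular flank) discretised with triangular elements (the mesenchyme) and,
along the limb arc, with linear boundary elements (the ectoderm). The domain
grows and deforms over developmental time: within each hourly stage frame the
mesh vertices move linearly from their start to their end configuration; at
frame changeover a fresh mesh is built on the new boundary and all per-element
concentrations are transferred conservatively, proportional to element
overlap areas.

Conventions: fields are *concentrations*; remapping conserves the integral
(amount), not pointwise values. Coordinates use an arbitrary consistent length
unit with y increasing distally. Element indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon
from shapely.strtree import STRtree

__all__ = [
    "BoundaryCurve",
    "TriMesh",
    "BoundaryMesh",
    "StageFrame",
    "DomainTrajectory",
    "MeshingError",
    "RemapError",
    "triangulate_domain",
    "extract_boundary_mesh",
    "deform_vertices",
    "remap_fields",
    "remap_chain_fields",
]


class MeshingError(ValueError):
    """Raised for degenerate boundaries or failed mesh generation."""


class RemapError(ValueError):
    """Raised when two meshes do not cover (nearly) the same region."""


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class BoundaryCurve:
    """Closed simple polyline bounding the simulation domain.

    ``flank_edge`` is an inclusive, forward-wrapping vertex index range
    ``(start, end)`` marking the proximal (body-side) flank portion of the
    outline; boundary edges inside it carry no ectoderm elements (the flank
    abuts the embryo body and is a zero-flux wall). ``None`` means the whole
    outline carries ectoderm (closed chain).
    """

    vertices: np.ndarray  # (n, 2), implicit closure
    stage_label: Optional[str] = None
    flank_edge: Optional[tuple[int, int]] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise MeshingError("boundary needs at least 3 two-dimensional vertices")
        ring = shapely.LinearRing(self.vertices)
        if not ring.is_simple or not ring.is_valid:
            raise MeshingError("boundary polyline is self-intersecting or degenerate")
        if _signed_area(self.vertices) <= 0:
            raise MeshingError("boundary must be counter-clockwise oriented")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def flank_vertex_mask(self) -> np.ndarray:
        """Boolean mask of vertices belonging to the flank portion."""
        n = len(self.vertices)
        mask = np.zeros(n, dtype=bool)
        if self.flank_edge is None:
            return mask
        s, e = self.flank_edge
        i = s % n
        while True:
            mask[i] = True
            if i == e % n:
                break
            i = (i + 1) % n
        return mask


@dataclass
class TriMesh:
    """Triangular mesh with precomputed finite-volume geometry.

    ``vertices[:n_boundary]`` are the boundary-curve vertices in boundary
    order (the triangulator subdivides boundary segments but never moves
    them); interior vertices follow.
    """

    vertices: np.ndarray  # (N, 2)
    triangles: np.ndarray  # (M, 3) CCW
    n_boundary: int = 0
    # adjacency: per interior edge, the two triangles and the two shared vertices
    adj_tris: np.ndarray = field(default=None, repr=False)  # (K, 2)
    adj_verts: np.ndarray = field(default=None, repr=False)  # (K, 2)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.adj_tris is None:
            self._build_adjacency()
        areas = self.triangle_areas(self.vertices)
        if np.any(areas <= 0):
            raise MeshingError("mesh contains non-positive-area or misoriented triangles")

    def _build_adjacency(self):
        edges: dict[tuple[int, int], list[int]] = {}
        for ti, (a, b, c) in enumerate(self.triangles):
            for u, v in ((a, b), (b, c), (c, a)):
                edges.setdefault((min(u, v), max(u, v)), []).append(ti)
        pairs, verts = [], []
        for (u, v), tris in edges.items():
            if len(tris) == 2:
                pairs.append(tris)
                verts.append((u, v))
            elif len(tris) > 2:
                raise MeshingError("non-manifold edge in mesh")
        self.adj_tris = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        self.adj_verts = np.asarray(verts, dtype=np.int64).reshape(-1, 2)

    # -- geometry, recomputable for deformed vertex positions ---------------

    def triangle_areas(self, positions: Optional[np.ndarray] = None) -> np.ndarray:
        p = self.vertices if positions is None else positions
        a, b, c = (p[self.triangles[:, k]] for k in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))

    def centroids(self, positions: Optional[np.ndarray] = None) -> np.ndarray:
        p = self.vertices if positions is None else positions
        return p[self.triangles].mean(axis=1)

    def edge_geometry(self, positions: Optional[np.ndarray] = None):
        """Shared-edge lengths and centroid distances per adjacent pair."""
        p = self.vertices if positions is None else positions
        ev = p[self.adj_verts]
        lengths = np.linalg.norm(ev[:, 1] - ev[:, 0], axis=1)
        cent = self.centroids(positions)
        dists = np.linalg.norm(cent[self.adj_tris[:, 1]] - cent[self.adj_tris[:, 0]], axis=1)
        return lengths, dists

    @property
    def areas(self) -> np.ndarray:
        return self.triangle_areas()

    @property
    def neighbors(self) -> np.ndarray:
        """Per-triangle neighbour triples (-1 where the edge is exterior)."""
        out = np.full((len(self.triangles), 3), -1, dtype=np.int64)
        count = np.zeros(len(self.triangles), dtype=np.int64)
        for i, j in self.adj_tris:
            out[i, count[i]] = j
            count[i] += 1
            out[j, count[j]] = i
            count[j] += 1
        return out

    def boundary_edge_triangle(self, u: int, v: int) -> int:
        """The unique triangle owning boundary edge (u, v); -1 if absent."""
        key = (min(u, v), max(u, v))
        for ti, (a, b, c) in enumerate(self.triangles):
            for p, q in ((a, b), (b, c), (c, a)):
                if (min(p, q), max(p, q)) == key:
                    return ti
        return -1


@dataclass
class BoundaryMesh:
    """1D chain of linear elements along the limb arc (the ectoderm).

    Each element coincides with exactly one boundary edge of the mesenchyme
    mesh; ``owner_triangle[i]`` is that triangle. The chain is open when the
    boundary has a flank portion, closed otherwise.
    """

    elements: np.ndarray  # (E, 2) vertex index pairs, chained in order
    owner_triangle: np.ndarray  # (E,)
    closed: bool = False

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.owner_triangle = np.asarray(self.owner_triangle, dtype=np.int64)

    def lengths(self, positions: np.ndarray) -> np.ndarray:
        p = positions[self.elements]
        return np.linalg.norm(p[:, 1] - p[:, 0], axis=1)

    def midpoints(self, positions: np.ndarray) -> np.ndarray:
        return positions[self.elements].mean(axis=1)

    def chain_pairs(self) -> np.ndarray:
        """Adjacent element index pairs along the chain."""
        e = len(self.elements)
        pairs = [(i, i + 1) for i in range(e - 1)]
        if self.closed and e > 2:
            pairs.append((e - 1, 0))
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


@dataclass
class StageFrame:
    """One hourly stage: mesh + boundary + deformation to the interval end."""

    index: int
    boundary: BoundaryCurve
    mesh: TriMesh
    ectoderm: BoundaryMesh
    end_positions: np.ndarray  # (N, 2) vertex positions at interval end

    def __post_init__(self):
        self.end_positions = np.asarray(self.end_positions, dtype=float)
        if self.end_positions.shape != self.mesh.vertices.shape:
            raise MeshingError("end_positions shape mismatch with mesh vertices")
        self.is_static = bool(np.array_equal(self.end_positions, self.mesh.vertices))


@dataclass
class DomainTrajectory:
    frames: list[StageFrame]
    frame_duration: float = 1.0  # hours

    def __post_init__(self):
        if not self.frames:
            raise MeshingError("trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def total_duration(self) -> float:
        return self.n_frames * self.frame_duration


# ---------------------------------------------------------------------------
# Triangulation
# ---------------------------------------------------------------------------


def _subdivide_boundary(vertices: np.ndarray, target: float):
    """Subdivide polygon segments so edges ≤ ~1.4·target; vertices stay put.

    Returns (points, orig_index) where orig_index[i] is the position of
    original vertex i in the new boundary point list.
    """
    n = len(vertices)
    points: list[np.ndarray] = []
    orig_index = np.zeros(n, dtype=np.int64)
    for i in range(n):
        a, b = vertices[i], vertices[(i + 1) % n]
        orig_index[i] = len(points)
        points.append(a)
        length = float(np.linalg.norm(b - a))
        nsub = max(1, int(round(length / target)))
        if length / nsub > 1.4 * target:
            nsub = int(np.ceil(length / (1.4 * target)))
        for k in range(1, nsub):
            points.append(a + (b - a) * (k / nsub))
    return np.asarray(points), orig_index


def _hex_interior_points(polygon: Polygon, h: float, margin: float) -> np.ndarray:
    minx, miny, maxx, maxy = polygon.bounds
    dy = h * np.sqrt(3) / 2
    rows = int(np.floor((maxy - miny) / dy)) + 1
    pts = []
    for r in range(rows + 1):
        yv = miny + r * dy
        offset = (h / 2) if (r % 2) else 0.0
        xs = np.arange(minx + offset, maxx + h, h)
        pts.append(np.column_stack([xs, np.full_like(xs, yv)]))
    pts = np.vstack(pts)
    eroded = polygon.buffer(-margin * h)
    if eroded.is_empty:
        return np.empty((0, 2))
    keep = shapely.contains_xy(eroded, pts[:, 0], pts[:, 1])
    return pts[keep]


def _attempt_triangulation(boundary_pts: np.ndarray, polygon: Polygon,
                           h: float, margin: float):
    interior = _hex_interior_points(polygon, h, margin)
    all_pts = np.vstack([boundary_pts, interior]) if len(interior) else boundary_pts
    tri = Delaunay(all_pts)
    simplices = tri.simplices
    # orient CCW
    p = all_pts[simplices]
    areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = areas < 0
    simplices[flip] = simplices[flip][:, ::-1]
    areas = np.abs(areas)
    # keep triangles with centroid inside the polygon and non-degenerate area
    cent = all_pts[simplices].mean(axis=1)
    inside = shapely.contains_xy(polygon, cent[:, 0], cent[:, 1])
    keep = inside & (areas > 1e-12 * h * h)
    simplices = simplices[keep]
    # drop unused interior points, reindex (boundary points always retained)
    used = np.unique(simplices)
    nb = len(boundary_pts)
    if used[0] != 0 or not np.array_equal(used[used < nb], np.arange(nb)):
        return None
    remap = -np.ones(len(all_pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return all_pts[used], remap[simplices], nb


def _verify_mesh(vertices, triangles, nb, polygon) -> bool:
    edge_count: dict[tuple[int, int], int] = {}
    for a, b, c in triangles:
        for u, v in ((a, b), (b, c), (c, a)):
            key = (min(u, v), max(u, v))
            edge_count[key] = edge_count.get(key, 0) + 1
    # every consecutive boundary pair must be an edge of exactly one triangle
    for i in range(nb):
        j = (i + 1) % nb
        if edge_count.get((min(i, j), max(i, j)), 0) != 1:
            return False
    # no other exterior edges
    for (u, v), cnt in edge_count.items():
        if cnt == 1:
            i, j = min(u, v), max(u, v)
            if not (j < nb and (j == i + 1 or (i == 0 and j == nb - 1))):
                return False
    p = vertices[triangles]
    areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    if np.any(areas <= 0):
        return False
    return abs(float(np.sum(areas)) - polygon.area) <= 1e-6 * polygon.area


def triangulate_domain(boundary: BoundaryCurve, target_edge_length: float) -> TriMesh:
    """Triangulate the polygon bounded by ``boundary``.

    Boundary segments are subdivided (never moved) so no boundary edge exceeds
    ~1.5 × ``target_edge_length``; the interior is seeded with a hexagonal
    point lattice and triangulated by Delaunay, then filtered to the polygon.
    The result is verified to tile the polygon exactly (every boundary segment
    appears as exactly one triangle edge; summed area matches the polygon).
    Deterministic for given inputs.
    """
    if target_edge_length <= 0:
        raise MeshingError("target_edge_length must be positive")
    polygon = boundary.polygon
    if not polygon.is_valid:
        raise MeshingError("boundary polygon is invalid")
    bpts, orig_index = _subdivide_boundary(boundary.vertices, target_edge_length)
    # interior lattice slightly denser than the boundary spacing keeps the
    # longest edge under 1.5x target and the minimum angle above ~20 degrees
    for margin in (0.5, 0.65, 0.85):
        result = _attempt_triangulation(bpts, polygon, 0.9 * target_edge_length, margin)
        if result is None:
            continue
        vertices, triangles, nb = result
        if _verify_mesh(vertices, triangles, nb, polygon):
            mesh = TriMesh(vertices=vertices, triangles=triangles, n_boundary=nb)
            mesh.boundary_orig_index = orig_index  # original -> mesh boundary index
            return mesh
    raise MeshingError(
        "could not produce a boundary-conforming triangulation; "
        "try a smaller target_edge_length"
    )


def extract_boundary_mesh(mesh: TriMesh, boundary: BoundaryCurve) -> BoundaryMesh:
    """Build the 1D ectoderm chain along the limb arc of ``mesh``.

    Elements are the mesh boundary edges outside the flank portion, in
    boundary order; each is matched to the unique triangle sharing that edge.
    """
    nb = mesh.n_boundary
    if nb < 3:
        raise MeshingError("mesh does not record its boundary vertices")
    orig_index = getattr(mesh, "boundary_orig_index", None)
    # owner lookup for all boundary edges
    owners: dict[tuple[int, int], int] = {}
    for ti, (a, b, c) in enumerate(mesh.triangles):
        for u, v in ((a, b), (b, c), (c, a)):
            if u < nb and v < nb:
                owners[(min(u, v), max(u, v))] = ti

    if boundary.flank_edge is None:
        starts = list(range(nb))
        closed = True
    else:
        s, e = boundary.flank_edge
        n_orig = len(boundary.vertices)
        if orig_index is not None:
            # mesh boundary indices of the flank endpoints
            ms = orig_index[s % n_orig]
            me = orig_index[e % n_orig]
        else:
            ms, me = s % nb, e % nb
        # arc runs forward from flank end to flank start
        starts = []
        i = me
        while i != ms:
            starts.append(i)
            i = (i + 1) % nb
        closed = False
    elements, owner = [], []
    for i in starts:
        j = (i + 1) % nb
        ti = owners.get((min(i, j), max(i, j)))
        if ti is None:
            raise MeshingError(f"boundary edge ({i}, {j}) not found in mesh")
        elements.append((i, j))
        owner.append(ti)
    return BoundaryMesh(
        elements=np.asarray(elements), owner_triangle=np.asarray(owner), closed=closed
    )


def deform_vertices(frame: StageFrame, s: float) -> np.ndarray:
    """Vertex positions at fraction ``s`` ∈ [0, 1] through the frame interval.

    Growth within a stage frame is treated as smooth and continuous; positions
    blend linearly from the frame's start configuration to its end
    configuration (which lies on the next frame's boundary).
    """
    if not (0.0 <= s <= 1.0):
        raise ValueError("deformation fraction s must be in [0, 1]")
    if frame.is_static or s == 0.0:
        return frame.mesh.vertices.copy()
    if s == 1.0:
        return frame.end_positions.copy()
    return (1.0 - s) * frame.mesh.vertices + s * frame.end_positions


# ---------------------------------------------------------------------------
# Conservative remapping
# ---------------------------------------------------------------------------


def remap_fields(
    old_mesh: TriMesh,
    new_mesh: TriMesh,
    fields: dict[str, np.ndarray] | np.ndarray,
    old_positions: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray] | np.ndarray:
    """Transfer per-element concentrations between overlapping meshes.

    Each new element receives the area-weighted average of the old elements it
    intersects (exact polygon clipping, candidates via an STR bounding-box
    tree): ``u_new = Σ u_old · A_int / Σ A_int``. When the meshes tile the
    same region this conserves the integral ∫u dA to float precision and
    preserves constants exactly. Essentially uncovered elements (covered area
    < 1e-6 of their own) take the nearest covered element's value.

    Raises :class:`RemapError` when overall overlap is below 99%.
    """
    single = isinstance(fields, np.ndarray)
    fdict = {"_": fields} if single else fields

    pos = old_mesh.vertices if old_positions is None else old_positions
    old_polys = [Polygon(pos[t]) for t in old_mesh.triangles]
    tree = STRtree(old_polys)
    new_tris = new_mesh.triangles
    new_areas = new_mesh.areas
    M = len(new_tris)

    cover = np.zeros(M)
    weights: list[tuple[np.ndarray, np.ndarray]] = []  # (old indices, areas)
    for i in range(M):
        poly = Polygon(new_mesh.vertices[new_tris[i]])
        cand = tree.query(poly)
        idx, ars = [], []
        for j in cand:
            inter = poly.intersection(old_polys[j])
            a = inter.area
            if a > 1e-12 * new_areas[i]:
                idx.append(j)
                ars.append(a)
        idx, ars = np.asarray(idx, dtype=np.int64), np.asarray(ars)
        weights.append((idx, ars))
        cover[i] = ars.sum() if len(ars) else 0.0

    total_overlap = float(cover.sum())
    if total_overlap < 0.99 * float(new_areas.sum()):
        raise RemapError(
            f"meshes overlap on only {total_overlap / new_areas.sum():.1%} of the target area"
        )

    covered = cover >= 1e-6 * new_areas
    out = {}
    for name, u in fdict.items():
        u = np.asarray(u, dtype=float)
        if len(u) != len(old_mesh.triangles):
            raise RemapError(
                f"field {name!r} has {len(u)} values for {len(old_mesh.triangles)} elements"
            )
        v = np.zeros(M)
        for i in range(M):
            idx, ars = weights[i]
            if covered[i]:
                v[i] = float(np.dot(u[idx], ars)) / cover[i]
        if not covered.all():
            good = np.flatnonzero(covered)
            if len(good) == 0:
                raise RemapError("no element of the new mesh is covered by the old mesh")
            kd = cKDTree(new_mesh.centroids()[good])
            bad = np.flatnonzero(~covered)
            _, nn = kd.query(new_mesh.centroids()[bad])
            v[bad] = v[good[nn]]
        out[name] = v
    return out["_"] if single else out


def remap_chain_fields(
    old_chain: BoundaryMesh,
    old_positions: np.ndarray,
    new_chain: BoundaryMesh,
    new_positions: np.ndarray,
    fields: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """1D analogue of :func:`remap_fields` for the ectoderm chain.

    Both chains are parameterised by cumulative arc length from their first
    vertex; each new element averages old-element values over interval
    overlap, conserving ∫u ds when the chains trace the same polyline.
    """

    def intervals(chain: BoundaryMesh, positions: np.ndarray) -> np.ndarray:
        L = chain.lengths(positions)
        ends = np.concatenate([[0.0], np.cumsum(L)])
        return np.column_stack([ends[:-1], ends[1:]])

    old_iv = intervals(old_chain, old_positions)
    new_iv = intervals(new_chain, new_positions)
    # normalise to a common [0, 1] parameterisation (same polyline, possibly
    # different total length bookkeeping at float level)
    old_iv = old_iv / old_iv[-1, 1]
    new_iv = new_iv / new_iv[-1, 1]

    out = {}
    starts = old_iv[:, 0]
    for name, u in fields.items():
        u = np.asarray(u, dtype=float)
        v = np.zeros(len(new_iv))
        for i, (a, b) in enumerate(new_iv):
            j0 = max(0, int(np.searchsorted(starts, a, side="right")) - 1)
            acc = w = 0.0
            for j in range(j0, len(old_iv)):
                oa, ob = old_iv[j]
                if oa >= b:
                    break
                ov = min(b, ob) - max(a, oa)
                if ov > 0:
                    acc += u[j] * ov
                    w += ov
            v[i] = acc / w if w > 0 else 0.0
        out[name] = v
    return out
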