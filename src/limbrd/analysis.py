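"""Image digitisation, pattern comparison and parameter fitting.

Digitisation maps image intensity (e.g. an in situ hybridisation stain) onto
the elements of a stage frame's mesh: pixel centres are pushed through a
user-supplied affine alignment into domain coordinates and averaged per
containing triangle. Staging — assigning a developmental stage to an image —
is external; the caller supplies the stage frame and alignment.

Pattern comparison is image subtraction on the mesh with an area-weighted RMS
summary. Parameter fitting wraps the simulator in a least-squares objective
against digitised (or simulated reference) target fields and minimises it
with a bounded, derivative-free simplex search with seeded random restarts —
simulation output is noisy and non-smooth under remeshing, so gradients are
avoided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from matplotlib.tri import Triangulation
from scipy import optimize

from .domain import StageFrame, TriMesh
from .engine import Morphomovie, SimulationConfig, simulate
from .modelspec import ModelSpec

__all__ = [
    "AlignmentTransform",
    "DigitisedPattern",
    "FitTarget",
    "ObjectiveSpec",
    "FitResult",
    "DigitisationError",
    "digitise_image",
    "pattern_difference",
    "objective_value",
    "fit_parameters",
]


class DigitisationError(ValueError):
    pass


@dataclass
class AlignmentTransform:
    """Affine map from pixel coordinates (col, row, origin top-left) to domain
    coordinates: ``p_domain = A @ (col, row) + b`` with ``matrix = [A | b]``.

    ``invert_intensity`` flips the intensity scale before normalisation (dark
    in situ stain = high expression).
    """

    matrix: np.ndarray  # (2, 3)
    invert_intensity: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-300:
            raise DigitisationError("alignment transform is singular")

    @classmethod
    def fit_bounds(cls, image_shape: tuple[int, int], mesh: TriMesh,
                   invert_intensity: bool = False) -> "AlignmentTransform":
        """Axis-aligned transform mapping the full image onto the mesh bbox
        (row 0 at the top of the domain)."""
        h, w = image_shape
        lo = mesh.vertices.min(axis=0)
        hi = mesh.vertices.max(axis=0)
        sx = (hi[0] - lo[0]) / w
        sy = (hi[1] - lo[1]) / h
        m = np.array([[sx, 0.0, lo[0]], [0.0, -sy, hi[1]]])
        return cls(matrix=m, invert_intensity=invert_intensity)

    def pixel_to_domain(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        A, b = self.matrix[:, :2], self.matrix[:, 2]
        pts = np.column_stack([cols, rows]) @ A.T + b
        return pts

    def domain_to_pixel(self, points: np.ndarray) -> np.ndarray:
        A, b = self.matrix[:, :2], self.matrix[:, 2]
        return (np.asarray(points) - b) @ np.linalg.inv(A).T


@dataclass
class DigitisedPattern:
    """Per-element intensity in [0, 1] on one stage frame's mesh."""

    values: np.ndarray
    frame: Optional[StageFrame] = None
    image_id: Optional[str] = None
    transform: Optional[AlignmentTransform] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise DigitisationError("digitised values must lie in [0, 1]")


def _bit_scale(image: np.ndarray) -> float:
    if image.dtype == np.uint8:
        return 255.0
    if image.dtype == np.uint16:
        return 65535.0
    if np.issubdtype(image.dtype, np.floating):
        if image.min() < 0 or image.max() > 1:
            raise DigitisationError("float images must be normalised to [0, 1]")
        return 1.0
    raise DigitisationError(f"unsupported image dtype {image.dtype}")


def digitise_image(
    image: np.ndarray,
    transform: AlignmentTransform,
    mesh: TriMesh,
    frame: Optional[StageFrame] = None,
    image_id: Optional[str] = None,
) -> DigitisedPattern:
    """Map a single-channel raster onto mesh elements.

    Each element receives the mean of the pixel intensities whose centres
    (col + ½, row + ½, mapped through the affine alignment) fall inside it,
    normalised to [0, 1] by the image bit depth (inverted first when
    ``invert_intensity``). Elements containing no pixel centre take the mean
    of the nearest-pixel intensities at their three vertices.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise DigitisationError(
            f"expected a single-channel image, got shape {image.shape}"
        )
    scale = _bit_scale(image)
    vals = image.astype(float)
    if transform.invert_intensity:
        vals = scale - vals
    vals /= scale

    h, w = image.shape
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    pts = transform.pixel_to_domain(cols.ravel(), rows.ravel())

    tri = Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.triangles)
    finder = tri.get_trifinder()
    elem = finder(pts[:, 0], pts[:, 1])
    inside = elem >= 0
    if not inside.any():
        raise DigitisationError("transform maps the mesh entirely outside the image")

    M = len(mesh.triangles)
    sums = np.bincount(elem[inside], weights=vals.ravel()[inside], minlength=M)
    counts = np.bincount(elem[inside], minlength=M)
    out = np.zeros(M)
    covered = counts > 0
    out[covered] = sums[covered] / counts[covered]

    if not covered.all():
        # nearest pixel at each vertex of the empty element
        empty = np.flatnonzero(~covered)
        for ei in empty:
            vpix = transform.domain_to_pixel(mesh.vertices[mesh.triangles[ei]])
            c = np.clip(np.round(vpix[:, 0] - 0.5).astype(int), 0, w - 1)
            r = np.clip(np.round(vpix[:, 1] - 0.5).astype(int), 0, h - 1)
            out[ei] = float(vals[r, c].mean())

    return DigitisedPattern(
        values=np.clip(out, 0.0, 1.0), frame=frame, image_id=image_id,
        transform=transform,
    )


def pattern_difference(
    a: np.ndarray, b: np.ndarray, mesh: TriMesh
) -> tuple[np.ndarray, float]:
    """Image-subtraction on the mesh: per-element difference a − b and the
    area-weighted RMS ``sqrt(Σ (a_i − b_i)² A_i / Σ A_i)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    M = len(mesh.triangles)
    if len(a) != M or len(b) != M:
        raise ValueError(
            f"field lengths ({len(a)}, {len(b)}) do not match the mesh ({M} elements)"
        )
    diff = a - b
    areas = mesh.areas
    rms = float(np.sqrt(np.sum(diff**2 * areas) / np.sum(areas)))
    return diff, rms


# ---------------------------------------------------------------------------
# Objective and fitting
# ---------------------------------------------------------------------------


@dataclass
class FitTarget:
    reactant: str
    values: np.ndarray | DigitisedPattern  # reference per-element field
    time: float
    weight: float = 1.0

    def field(self) -> np.ndarray:
        v = self.values.values if isinstance(self.values, DigitisedPattern) else self.values
        return np.asarray(v, dtype=float)


@dataclass
class ObjectiveSpec:
    model: ModelSpec
    trajectory: object  # DomainTrajectory
    config: SimulationConfig
    fittable: dict[str, tuple[float, float]]  # name -> (lo, hi)
    targets: list[FitTarget] = field(default_factory=list)

    def __post_init__(self):
        declared = {p.name: p for p in self.model.parameters}
        for name in self.fittable:
            if name not in declared:
                raise KeyError(f"fittable parameter {name!r} not in the model")
            if not declared[name].fittable:
                raise ValueError(f"parameter {name!r} is not marked fittable")


@dataclass
class FitResult:
    parameters: dict[str, float]
    objective: float
    n_evaluations: int
    converged: bool
    trace: list[tuple[dict[str, float], float]] = field(default_factory=list)


def objective_value(params: dict[str, float], objective: ObjectiveSpec) -> float:
    """Weighted area-mean squared discrepancy between simulation and targets.

    Runs the model with the given parameter overrides and sums, over targets,
    ``weight × Σ(u_i − target_i)² A_i / Σ A_i`` with the simulated reactant
    evaluated at the snapshot nearest the target time.
    """
    for name, value in params.items():
        lo, hi = objective.fittable[name]
        if not (lo <= value <= hi):
            raise ValueError(f"parameter {name!r}={value} outside bounds [{lo}, {hi}]")
    movie = simulate(
        objective.model, objective.trajectory, objective.config,
        param_overrides=dict(params),
    )
    total = 0.0
    for tgt in objective.targets:
        snap = movie.snapshot_at(tgt.time)
        u = snap.state.mesenchyme.get(tgt.reactant)
        if u is None:
            u = snap.state.ectoderm[tgt.reactant]
            frame = objective.trajectory.frames[snap.frame_index]
            wgts = frame.ectoderm.lengths(snap.positions)
        else:
            frame = objective.trajectory.frames[snap.frame_index]
            wgts = frame.mesh.triangle_areas(snap.positions)
        ref = tgt.field()
        total += tgt.weight * float(np.sum((u - ref) ** 2 * wgts) / np.sum(wgts))
    return total


def fit_parameters(
    objective: ObjectiveSpec,
    start: dict[str, float],
    budget: int = 200,
    seed: int = 0,
    n_restarts: int = 0,
) -> FitResult:
    """Bounded derivative-free local search (Nelder–Mead) with seeded restarts.

    Never evaluates outside the declared bounds; returns the best point seen.
    Reproducible for a given (seed, budget, start).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    names = sorted(objective.fittable)
    lo = np.array([objective.fittable[n][0] for n in names])
    hi = np.array([objective.fittable[n][1] for n in names])
    x0 = np.array([start[n] for n in names])
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("start point outside bounds")

    rng = np.random.default_rng(seed)
    trace: list[tuple[dict[str, float], float]] = []
    best = {"x": None, "f": np.inf}
    evals = 0

    def fun(x):
        nonlocal evals
        x = np.clip(x, lo, hi)
        params = dict(zip(names, map(float, x)))
        f = objective_value(params, objective)
        evals += 1
        trace.append((params, f))
        if f < best["f"]:
            best["x"], best["f"] = x.copy(), f
        return f

    f0 = fun(x0)
    converged = False
    if f0 <= 1e-15:
        converged = True
    else:
        starts = [x0] + [lo + rng.random(len(names)) * (hi - lo) for _ in range(n_restarts)]
        for xs in starts:
            remaining = budget - evals
            if remaining < 2:
                break
            res = optimize.minimize(
                fun, np.clip(xs, lo, hi), method="Nelder-Mead",
                bounds=optimize.Bounds(lo, hi),
                options={"maxfev": remaining, "xatol": 1e-8, "fatol": 1e-12},
            )
            converged = converged or bool(res.success)

    return FitResult(
        parameters=dict(zip(names, map(float, best["x"]))),
        objective=float(best["f"]),
        n_evaluations=evals,
        converged=converged,
        trace=trace,
    )
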