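"""Numerical integration of compiled models over domain trajectories.

One explicit update per time step, with reaction, diffusion, compartment
coupling, intervention sources and noise all evaluated from the same pre-step
state (no operator splitting):

    u ← u + dt·(f + ∇·(D∇u) + coupling + sources) + η·√dt·ξ,   ξ ~ N(0, 1)

Diffusion uses a two-point finite-volume flux between adjacent elements
(shared-edge length × concentration gradient along the centroid line, with
the harmonic mean of the two element diffusivities); exterior edges are
zero-flux. The ectoderm chain uses the analogous 1D scheme with element
lengths in place of areas. Noise follows the Euler–Maruyama discretisation of
a Wiener process, one independent standard-normal draw per element per
species per step.

Domain growth advects material passively: after each step the field is
diluted by the per-element area ratio so the per-element amount u·A is
invariant under deformation; at each frame changeover fields are remapped
conservatively onto the next frame's mesh.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from matplotlib.tri import Triangulation

from . import domain as dom
from .expressions import Expression
from .modelspec import (
    ECTODERM,
    GLOBAL,
    MESENCHYME,
    InterventionSpec,
    ModelSpec,
    validate_model,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "FieldState",
    "Snapshot",
    "Morphomovie",
    "CompiledModel",
    "SimulationError",
    "StabilityError",
    "compile_model",
    "diffusion_rates",
    "chain_diffusion_rates",
    "integrate_step",
    "apply_growth_dilution",
    "place_bead",
    "stability_limit",
    "simulate",
]


class SimulationError(RuntimeError):
    """Non-finite state or other runtime failure, with time/species context."""


class StabilityError(SimulationError):
    """dt exceeds the explicit-diffusion stability bound (stability_check on)."""


@dataclass
class SimulationConfig:
    """Integration settings.

    ``noise_sqrt_area_scaling`` divides each noise draw by the square root of
    the element measure (area or length), the SPDE-consistent discretisation
    whose ensemble statistics are invariant under mesh refinement; off by
    default, where amplitudes are per element as written in the model.
    """

    dt: float = 0.01  # hours
    seed: int = 0
    output_every: int = 100  # steps between snapshots
    t0: float = 0.0
    t_end: Optional[float] = None  # default: full trajectory span
    stability_check: bool = False
    noise_sqrt_area_scaling: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.output_every < 1:
            raise ValueError("output_every must be >= 1")
        if self.t_end is not None and self.t_end <= self.t0:
            raise ValueError("t_end must exceed t0")


@dataclass
class FieldState:
    """Per-reactant element concentrations at one time."""

    time: float
    mesenchyme: dict[str, np.ndarray] = field(default_factory=dict)
    ectoderm: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "FieldState":
        return FieldState(
            time=self.time,
            mesenchyme={k: v.copy() for k, v in self.mesenchyme.items()},
            ectoderm={k: v.copy() for k, v in self.ectoderm.items()},
        )


@dataclass
class Snapshot:
    time: float
    frame_index: int
    positions: np.ndarray  # vertex positions at snapshot time
    state: FieldState


@dataclass
class Morphomovie:
    """The simulator's compound output: fields over the moving mesh."""

    model: ModelSpec
    trajectory: dom.DomainTrajectory
    config: SimulationConfig
    snapshots: list[Snapshot] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([s.time for s in self.snapshots])

    def snapshot_at(self, time: float, tol: Optional[float] = None) -> Snapshot:
        times = self.times
        i = int(np.argmin(np.abs(times - time)))
        if tol is not None and abs(times[i] - time) > tol:
            raise KeyError(f"no snapshot within {tol} h of t={time}")
        return self.snapshots[i]


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------


@dataclass
class _CompartmentPlan:
    variables: list  # VariableDef, topologically ordered
    reactants: list  # ReactantDef
    patterns: list  # PredefinedPatternDef


class CompiledModel:
    """Evaluation plan binding a validated model to a trajectory.

    Variables are topologically ordered so each is computed before use;
    per-compartment evaluation is vectorised over elements. The plan is a
    deterministic function of (spec, trajectory).
    """

    def __init__(self, spec: ModelSpec, trajectory: dom.DomainTrajectory,
                 param_overrides: Optional[dict[str, float]] = None):
        diags = validate_model(spec)
        if diags:
            raise ValueError(
                "model is invalid:\n" + "\n".join(f"  {d}" for d in diags)
            )
        self.spec = spec
        self.trajectory = trajectory
        self.params = spec.parameter_values()
        if param_overrides:
            unknown = set(param_overrides) - set(self.params)
            if unknown:
                raise KeyError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
            self.params.update(param_overrides)

        # topological order over variables (validation guarantees acyclicity)
        var_names = {v.name for v in spec.variables}
        order: list = []
        done: set[str] = set()

        def visit(v):
            if v.name in done:
                return
            done.add(v.name)
            for d in sorted(v.expr.free_symbols & var_names):
                visit(next(w for w in spec.variables if w.name == d))
            order.append(v)

        for v in spec.variables:
            visit(v)
        self.variables_order = order

        self.plans = {
            comp: _CompartmentPlan(
                variables=[v for v in order if v.compartment == comp],
                reactants=[r for r in spec.reactants if r.compartment == comp],
                patterns=[p for p in spec.patterns if p.compartment == comp],
            )
            for comp in (GLOBAL, MESENCHYME, ECTODERM)
        }

        # pattern frame counts must match the trajectory
        for p in spec.patterns:
            if p.frames is not None:
                if len(p.frames) != trajectory.n_frames:
                    raise ValueError(
                        f"pattern {p.name!r} has {len(p.frames)} frames but the "
                        f"trajectory has {trajectory.n_frames}"
                    )
                for k, arr in enumerate(p.frames):
                    frame = trajectory.frames[k]
                    want = (
                        len(frame.mesh.triangles)
                        if p.compartment == MESENCHYME
                        else len(frame.ectoderm.elements)
                    )
                    if len(arr) != want:
                        raise ValueError(
                            f"pattern {p.name!r} frame {k}: {len(arr)} values for "
                            f"{want} elements"
                        )

    # -- expression resolution (interventions may override) -----------------

    def active_expr(self, entity: str, base: Expression, t: float) -> Expression:
        for iv in self.spec.interventions:
            if iv.kind == "expression_override" and iv.target == entity:
                if iv.window[0] <= t < iv.window[1]:
                    return iv.expr
        return base

    def eval_env(self, comp: str, t: float, centroids: Optional[np.ndarray],
                 state: Optional[FieldState], frame_index: int) -> dict:
        """Environment for expressions of one compartment at time t."""
        env: dict = dict(self.params)
        env["t"] = t
        if centroids is not None:
            env["x"] = centroids[:, 0]
            env["y"] = centroids[:, 1]
        plan = self.plans[comp]
        for p in plan.patterns:
            if p.expr is not None:
                env[p.name] = p.expr(env)
            else:
                env[p.name] = p.frames[frame_index]
        if state is not None:
            fields = state.mesenchyme if comp == MESENCHYME else state.ectoderm
            env.update(fields)
        # global variables first (scalars), then compartment variables
        genv = dict(self.params)
        genv["t"] = t
        for v in self.plans[GLOBAL].variables:
            genv[v.name] = self.active_expr(v.name, v.expr, t)(genv)
            env[v.name] = genv[v.name]
        for v in plan.variables:
            if comp != GLOBAL:
                env[v.name] = self.active_expr(v.name, v.expr, t)(env)
        return env


def compile_model(spec: ModelSpec, trajectory: dom.DomainTrajectory,
                  param_overrides: Optional[dict[str, float]] = None) -> CompiledModel:
    return CompiledModel(spec, trajectory, param_overrides)


# ---------------------------------------------------------------------------
# Spatial operators
# ---------------------------------------------------------------------------


def diffusion_rates(
    areas: np.ndarray,
    adj_tris: np.ndarray,
    edge_lengths: np.ndarray,
    centroid_dists: np.ndarray,
    u: np.ndarray,
    D: np.ndarray,
) -> np.ndarray:
    """Finite-volume du/dt from diffusion on the triangle mesh.

    Flux through the shared edge of adjacent elements i, j:
    ``F_ij = D_ij · L_ij · (u_j − u_i) / d_ij`` with D_ij the harmonic mean of
    the element diffusivities; ``rate_i = Σ_j F_ij / A_i``. Exterior edges are
    zero-flux, so Σ rate·A = 0 to machine precision.
    """
    rate = np.zeros_like(u)
    if len(adj_tris) == 0:
        return rate
    i, j = adj_tris[:, 0], adj_tris[:, 1]
    Di, Dj = D[i], D[j]
    s = Di + Dj
    with np.errstate(divide="ignore", invalid="ignore"):
        Dij = np.where(s > 0, 2.0 * Di * Dj / np.where(s > 0, s, 1.0), 0.0)
    F = Dij * edge_lengths * (u[j] - u[i]) / centroid_dists
    np.add.at(rate, i, F)
    np.add.at(rate, j, -F)
    return rate / areas


def chain_diffusion_rates(
    lengths: np.ndarray,
    chain_pairs: np.ndarray,
    midpoint_dists: np.ndarray,
    u: np.ndarray,
    D: np.ndarray,
) -> np.ndarray:
    """1D finite-volume diffusion along the ectoderm chain (lengths as volumes)."""
    rate = np.zeros_like(u)
    if len(chain_pairs) == 0:
        return rate
    i, j = chain_pairs[:, 0], chain_pairs[:, 1]
    Di, Dj = D[i], D[j]
    s = Di + Dj
    Dij = np.where(s > 0, 2.0 * Di * Dj / np.where(s > 0, s, 1.0), 0.0)
    F = Dij * (u[j] - u[i]) / midpoint_dists
    np.add.at(rate, i, F)
    np.add.at(rate, j, -F)
    return rate / lengths


def apply_growth_dilution(state: FieldState, mes_ratio: np.ndarray,
                          ect_ratio: Optional[np.ndarray] = None) -> FieldState:
    """Dilute concentrations by A_before/A_after so per-element amount is invariant."""
    for name in state.mesenchyme:
        state.mesenchyme[name] = state.mesenchyme[name] * mes_ratio
    if ect_ratio is not None:
        for name in state.ectoderm:
            state.ectoderm[name] = state.ectoderm[name] * ect_ratio
    return state


def stability_limit(areas, adj_tris, edge_lengths, centroid_dists, D) -> float:
    """Explicit-diffusion CFL bound: dt ≤ 0.5 · min_i A_i / Σ_j D_ij·L_ij/d_ij."""
    if len(adj_tris) == 0 or np.all(D == 0):
        return np.inf
    i, j = adj_tris[:, 0], adj_tris[:, 1]
    s = D[i] + D[j]
    Dij = np.where(s > 0, 2.0 * D[i] * D[j] / np.where(s > 0, s, 1.0), 0.0)
    w = Dij * edge_lengths / centroid_dists
    acc = np.zeros(len(areas))
    np.add.at(acc, i, w)
    np.add.at(acc, j, w)
    with np.errstate(divide="ignore"):
        lim = np.where(acc > 0, 0.5 * areas / np.where(acc > 0, acc, 1.0), np.inf)
    return float(np.min(lim))


# ---------------------------------------------------------------------------
# Geometry cache per frame
# ---------------------------------------------------------------------------


class _FrameGeometry:
    def __init__(self, frame: dom.StageFrame):
        self.frame = frame
        self.mesh = frame.mesh
        self.ecto = frame.ectoderm
        self.chain_pairs = self.ecto.chain_pairs()

    def at(self, positions: np.ndarray):
        mesh = self.mesh
        areas = mesh.triangle_areas(positions)
        edge_len, cdist = mesh.edge_geometry(positions)
        lengths = self.ecto.lengths(positions)
        mids = self.ecto.midpoints(positions)
        if len(self.chain_pairs):
            mdist = np.linalg.norm(
                mids[self.chain_pairs[:, 1]] - mids[self.chain_pairs[:, 0]], axis=1
            )
        else:
            mdist = np.empty(0)
        return areas, edge_len, cdist, lengths, mids, mdist


# ---------------------------------------------------------------------------
# Beads
# ---------------------------------------------------------------------------


def _find_triangle(mesh: dom.TriMesh, positions: np.ndarray, point) -> int:
    tri = Triangulation(positions[:, 0], positions[:, 1], mesh.triangles)
    finder = tri.get_trifinder()
    return int(finder(float(point[0]), float(point[1])))


def place_bead(spec: InterventionSpec, trajectory: dom.DomainTrajectory,
               frame_duration: Optional[float] = None) -> int:
    """Resolve the mesh element containing the bead at its activation time.

    Raises :class:`SimulationError` when the position lies outside the domain
    at t_on. During simulation the bead tracks its material point: its element
    centroid is carried through the deformation and re-located after each
    remesh.
    """
    if spec.kind != "bead":
        raise ValueError("not a bead intervention")
    fd = frame_duration or trajectory.frame_duration
    k = min(int(spec.window[0] / fd), trajectory.n_frames - 1)
    frame = trajectory.frames[k]
    s = spec.window[0] / fd - k
    positions = dom.deform_vertices(frame, min(max(s, 0.0), 1.0))
    ti = _find_triangle(frame.mesh, positions, spec.position)
    if ti < 0:
        raise SimulationError(
            f"bead position {spec.position} lies outside the domain at t={spec.window[0]}"
        )
    return ti


class _BeadTracker:
    def __init__(self, spec: InterventionSpec):
        self.spec = spec
        self.element: Optional[int] = None  # resolved lazily at t_on
        self.point = np.asarray(spec.position, dtype=float)

    def active(self, t: float) -> bool:
        return self.spec.window[0] <= t < self.spec.window[1]

    def resolve(self, mesh: dom.TriMesh, positions: np.ndarray):
        ti = _find_triangle(mesh, positions, self.point)
        if ti < 0:
            raise SimulationError(
                f"bead position {tuple(self.point)} lies outside the domain"
            )
        self.element = ti


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------


def integrate_step(
    state: FieldState,
    model: CompiledModel,
    geometry: dict,
    dt: float,
    rng: Optional[np.random.Generator],
    frame_index: int = 0,
    beads: Optional[list[_BeadTracker]] = None,
    noise_scale: Optional[dict[str, np.ndarray]] = None,
) -> FieldState:
    """One explicit Euler–Maruyama step from the pre-step state.

    ``geometry`` carries the instantaneous mesh geometry (areas, edge lengths,
    centroid distances, chain lengths/midpoints, centroids) as produced inside
    :func:`simulate`; all right-hand-side contributions are evaluated from
    ``state`` and applied in a single update. Clamped species are floored at 0
    afterwards. Noise draws are species-major in reactant declaration order
    (species with an identically-zero noise amplitude draw nothing, so
    noiseless runs are seed-independent).
    """
    t = state.time
    spec = model.spec
    new = state.copy()
    new.time = t + dt

    envs = {}
    for comp, centroids in ((MESENCHYME, geometry["mes_centroids"]),
                            (ECTODERM, geometry["ect_midpoints"])):
        envs[comp] = model.eval_env(comp, t, centroids, state, frame_index)

    # reaction + diffusion + sources, same pre-step state throughout
    updates: dict[tuple[str, str], np.ndarray] = {}
    for r in spec.reactants:
        comp = r.compartment
        env = envs[comp]
        u = (state.mesenchyme if comp == MESENCHYME else state.ectoderm)[r.name]
        rhs_expr = model.active_expr(r.name, r.rhs, t)
        with np.errstate(all="ignore"):
            f = np.broadcast_to(np.asarray(rhs_expr(env), dtype=float), u.shape).copy()
            D = np.broadcast_to(np.asarray(r.diffusion(env), dtype=float), u.shape)
        if np.any(D != 0):
            if comp == MESENCHYME:
                f += diffusion_rates(
                    geometry["areas"], model.trajectory.frames[frame_index].mesh.adj_tris,
                    geometry["edge_lengths"], geometry["centroid_dists"], u, D,
                )
            else:
                f += chain_diffusion_rates(
                    geometry["lengths"], geometry["chain_pairs"],
                    geometry["midpoint_dists"], u, D,
                )
        updates[(comp, r.name)] = f

    # mesenchyme <-> ectoderm exchange through owner triangles. The ectoderm
    # element sees k·(u_m − u_e); its owner triangle sees the opposite flux
    # weighted by L_e/A_m so the combined amount Σu·A + Σu·L is conserved.
    for c in spec.couplings:
        k = float(c.exchange_rate(model.eval_env(GLOBAL, t, None, None, frame_index)))
        owners = model.trajectory.frames[frame_index].ectoderm.owner_triangle
        u_m = state.mesenchyme[c.mesenchyme_reactant][owners]
        u_e = state.ectoderm[c.ectoderm_reactant]
        L = geometry["lengths"]
        A = geometry["areas"]
        updates[(ECTODERM, c.ectoderm_reactant)] += k * (u_m - u_e)
        np.add.at(
            updates[(MESENCHYME, c.mesenchyme_reactant)],
            owners,
            k * (u_e - u_m) * L / A[owners],
        )

    if beads:
        for b in beads:
            if b.active(t) and b.element is not None:
                r = spec.reactant(b.spec.target)
                updates[(r.compartment, r.name)][b.element] += b.spec.rate

    sqrt_dt = np.sqrt(dt)
    for r in spec.reactants:
        comp = r.compartment
        fields = new.mesenchyme if comp == MESENCHYME else new.ectoderm
        u = fields[r.name]
        u = u + dt * updates[(comp, r.name)]
        if not r.noise.is_zero:
            env = envs[comp]
            with np.errstate(all="ignore"):
                eta = np.broadcast_to(np.asarray(r.noise(env), dtype=float), u.shape)
            xi = rng.standard_normal(u.shape)
            if noise_scale is not None:
                xi = xi * noise_scale[comp]
            u = u + eta * sqrt_dt * xi
        if r.clamp_nonnegative:
            u = np.maximum(u, 0.0)
        bad = ~np.isfinite(u)
        if bad.any():
            el = int(np.flatnonzero(bad)[0])
            raise SimulationError(
                f"non-finite value for species {r.name!r} at t={t + dt:.6g}, "
                f"element {el} ({comp})"
            )
        fields[r.name] = u
    return new


# ---------------------------------------------------------------------------
# Full simulation loop
# ---------------------------------------------------------------------------


def _initial_state(model: CompiledModel, t0: float, geometry: dict,
                   frame_index: int) -> FieldState:
    state = FieldState(time=t0)
    for r in model.spec.reactants:
        comp = r.compartment
        centroids = (geometry["mes_centroids"] if comp == MESENCHYME
                     else geometry["ect_midpoints"])
        env = model.eval_env(comp, t0, centroids, None, frame_index)
        n = len(centroids)
        with np.errstate(all="ignore"):
            u = np.broadcast_to(np.asarray(r.initial(env), dtype=float), (n,)).copy()
        if r.clamp_nonnegative:
            u = np.maximum(u, 0.0)
        (state.mesenchyme if comp == MESENCHYME else state.ectoderm)[r.name] = u
    return state


def _check_stability(model: CompiledModel, geom: _FrameGeometry, positions,
                     state: FieldState, dt: float, t: float, frame_index: int,
                     strict: bool):
    areas, edge_len, cdist, lengths, mids, mdist = geom.at(positions)
    cents = geom.mesh.centroids(positions)
    for r in model.spec.reactants:
        if r.compartment != MESENCHYME:
            continue
        env = model.eval_env(MESENCHYME, t, cents, state, frame_index)
        with np.errstate(all="ignore"):
            D = np.broadcast_to(
                np.asarray(r.diffusion(env), dtype=float), (len(areas),)
            )
        lim = stability_limit(areas, geom.mesh.adj_tris, edge_len, cdist, D)
        if dt > lim:
            msg = (f"dt={dt} exceeds the diffusion stability bound {lim:.3g} "
                   f"for species {r.name!r} at t={t:.6g}")
            if strict:
                raise StabilityError(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)


def simulate(
    spec: ModelSpec,
    trajectory: dom.DomainTrajectory,
    config: SimulationConfig,
    param_overrides: Optional[dict[str, float]] = None,
    progress: Optional[Callable[[float], None]] = None,
) -> Morphomovie:
    """Integrate a model over a trajectory, producing a :class:`Morphomovie`.

    Per step: evaluate patterns and variables, advance reactants one explicit
    Euler–Maruyama step, move the mesh along the within-frame deformation and
    dilute by the area change. At each frame boundary, remap all fields onto
    the next frame's mesh (mesenchyme by area overlap, ectoderm by length
    overlap). Snapshots are recorded every ``output_every`` steps, starting at
    t0. With all noise amplitudes 0 the result is a deterministic function of
    (spec, trajectory, config), independent of the seed.
    """
    model = compile_model(spec, trajectory, param_overrides)
    fd = trajectory.frame_duration
    t0 = config.t0
    t_end = config.t_end if config.t_end is not None else trajectory.total_duration
    if t_end > trajectory.total_duration + 1e-9:
        raise ValueError(
            f"t_end={t_end} exceeds the trajectory span {trajectory.total_duration}"
        )
    steps_per_frame = fd / config.dt
    if abs(steps_per_frame - round(steps_per_frame)) > 1e-9 * steps_per_frame:
        raise ValueError("dt must divide the frame duration")
    steps_per_frame = int(round(steps_per_frame))
    n_steps = int(round((t_end - t0) / config.dt))

    rng = np.random.default_rng(config.seed)
    beads = [_BeadTracker(iv) for iv in spec.interventions if iv.kind == "bead"]

    start_frame = min(int(t0 / fd + 1e-12), trajectory.n_frames - 1)
    geom = _FrameGeometry(trajectory.frames[start_frame])
    frame_index = start_frame
    s0 = t0 / fd - start_frame
    positions = dom.deform_vertices(geom.frame, s0)

    def geometry_dict(positions):
        areas, edge_len, cdist, lengths, mids, mdist = geom.at(positions)
        return {
            "areas": areas,
            "edge_lengths": edge_len,
            "centroid_dists": cdist,
            "lengths": lengths,
            "midpoint_dists": mdist,
            "chain_pairs": geom.chain_pairs,
            "mes_centroids": geom.mesh.centroids(positions),
            "ect_midpoints": mids,
        }

    g = geometry_dict(positions)
    state = _initial_state(model, t0, g, frame_index)
    _check_stability(model, geom, positions, state, config.dt, t0, frame_index,
                     config.stability_check)

    movie = Morphomovie(model=spec, trajectory=trajectory, config=config)
    movie.snapshots.append(
        Snapshot(time=t0, frame_index=frame_index, positions=positions.copy(),
                 state=state.copy())
    )

    for b in beads:
        if b.spec.window[0] <= t0:
            b.resolve(geom.mesh, positions)

    for step in range(n_steps):
        t = t0 + step * config.dt
        # fraction through the current frame, before and after this step
        s_now = (t - frame_index * fd) / fd
        s_next = (t + config.dt - frame_index * fd) / fd
        positions = dom.deform_vertices(geom.frame, min(s_now, 1.0))
        g = geometry_dict(positions)

        for b in beads:
            if b.element is None and b.active(t):
                b.resolve(geom.mesh, positions)

        noise_scale = None
        if config.noise_sqrt_area_scaling:
            noise_scale = {
                MESENCHYME: 1.0 / np.sqrt(g["areas"]),
                ECTODERM: 1.0 / np.sqrt(g["lengths"]) if len(g["lengths"]) else
                np.empty(0),
            }
        state = integrate_step(state, model, g, config.dt, rng, frame_index, beads,
                               noise_scale=noise_scale)

        # growth dilution to the end-of-step geometry
        new_positions = dom.deform_vertices(geom.frame, min(s_next, 1.0))
        new_areas = geom.mesh.triangle_areas(new_positions)
        new_lengths = geom.ecto.lengths(new_positions)
        apply_growth_dilution(
            state, g["areas"] / new_areas,
            g["lengths"] / new_lengths if len(new_lengths) else None,
        )
        positions = new_positions

        # frame changeover: conservative remap onto the next frame's mesh
        at_frame_end = s_next >= 1.0 - 1e-12
        if at_frame_end and frame_index + 1 < trajectory.n_frames and step + 1 < n_steps:
            old_frame = geom.frame
            new_frame = trajectory.frames[frame_index + 1]
            # static trajectories share one mesh object across frames; the
            # identity remap is then a no-op and is skipped
            static = (new_frame.mesh is old_frame.mesh
                      and np.array_equal(old_frame.end_positions, new_frame.mesh.vertices))
            if not static:
                state.mesenchyme = dom.remap_fields(
                    old_frame.mesh, new_frame.mesh, state.mesenchyme,
                    old_positions=old_frame.end_positions,
                )
                if state.ectoderm:
                    state.ectoderm = dom.remap_chain_fields(
                        old_frame.ectoderm, old_frame.end_positions,
                        new_frame.ectoderm, new_frame.mesh.vertices,
                        state.ectoderm,
                    )
            for b in beads:
                if b.element is not None:
                    cent = old_frame.end_positions[
                        old_frame.mesh.triangles[b.element]
                    ].mean(axis=0)
                    b.point = cent
                    b.element = None  # re-resolve on the new mesh
            frame_index += 1
            geom = _FrameGeometry(new_frame)
            positions = new_frame.mesh.vertices.copy()
            for b in beads:
                if b.active(state.time):
                    b.resolve(geom.mesh, positions)
            _check_stability(model, geom, positions, state, config.dt, state.time,
                             frame_index, config.stability_check)
            logger.info("frame %d -> %d at t=%.3f", frame_index - 1, frame_index,
                        state.time)

        if (step + 1) % config.output_every == 0:
            movie.snapshots.append(
                Snapshot(time=state.time, frame_index=frame_index,
                         positions=positions.copy(), state=state.copy())
            )
        if progress is not None and (step + 1) % max(1, n_steps // 100) == 0:
            progress((step + 1) / n_steps)

    return movie
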