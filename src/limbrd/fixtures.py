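"""Synthetic stand-ins for hosted assets: domains, builtin models, test images.

The canonical hourly limb-bud boundary trajectory used by the original
platform is a database asset; this module generates a *synthetic* analogue
that reproduces its bookkeeping — hourly stage frames labelled
``mE{day}:{hh}``, a flank rectangle joined to a smoothly elongating limb arc,
strictly monotone growth, and exact boundary hand-over between consecutive
frames — without claiming to match the real mouse hindlimb outline
geometrically. Likewise the builtin model catalogue ships structurally
analogous toy parameterisations of classic patterning systems (Brusselator,
activator–inhibitor Turing pair, a six-species proximodistal feedforward
network, a PORD-style oscillator), not the published parameter sets.

All generators are pure functions of their parameters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .domain import (
    BoundaryCurve,
    BoundaryMesh,
    DomainTrajectory,
    StageFrame,
    TriMesh,
    extract_boundary_mesh,
    triangulate_domain,
)
from .modelspec import ModelSpec, loads_model, validate_model

__all__ = [
    "LimbTrajectoryParams",
    "stage_to_hour",
    "hour_to_stage",
    "make_limb_trajectory",
    "make_static_domain",
    "builtin_models",
    "builtin_model",
    "make_synthetic_image",
]

_STAGE_RE = re.compile(r"^mE(\d+):(\d{1,2})$")


def stage_to_hour(label: str) -> int:
    """``mE{d}:{hh}`` → absolute hour index d·24 + hh (mE10:09 → 249)."""
    m = _STAGE_RE.match(label)
    if not m:
        raise ValueError(f"bad stage label {label!r} (expected e.g. 'mE10:09')")
    day, hour = int(m.group(1)), int(m.group(2))
    if hour >= 24:
        raise ValueError(f"bad stage label {label!r}: hour must be < 24")
    return day * 24 + hour


def hour_to_stage(hour: int) -> str:
    return f"mE{hour // 24}:{hour % 24:02d}"


@dataclass
class LimbTrajectoryParams:
    """Shape and growth parameters of the synthetic limb trajectory.

    Lengths use the arbitrary domain unit (the default limb is ~1 unit wide at
    the base); rates are per hour. ``distal_bulge`` widens the distal half of
    the bud progressively along the trajectory (paddle formation);
    ``flank_fraction`` sets the flank rectangle height as a fraction of the
    current limb length.
    """

    start_stage: str = "mE10:09"
    end_stage: str = "mE12:08"
    base_width: float = 1.0
    initial_length: float = 0.8
    elongation_rate: float = 0.04  # length units / hour
    distal_bulge: float = 0.25
    flank_fraction: float = 0.2
    target_edge_length: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if stage_to_hour(self.end_stage) <= stage_to_hour(self.start_stage):
            raise ValueError("end_stage must be after start_stage")
        for f in ("base_width", "initial_length", "target_edge_length"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def n_frames(self) -> int:
        return stage_to_hour(self.end_stage) - stage_to_hour(self.start_stage) + 1


def _limb_outline(params: LimbTrajectoryParams, hour_offset: int, n_total: int,
                  n_arc: int = 720) -> tuple[np.ndarray, np.ndarray]:
    """Densely sampled smooth outline at a given hour.

    Returns (arc_points, flank_path): the limb arc from the right base corner
    over the distal tip to the left base corner, and the flank polyline from
    the left base corner around the rectangle back to the right base corner.
    """
    w = params.base_width / 2.0
    L = params.initial_length + params.elongation_rate * hour_offset
    progress = hour_offset / max(1, n_total - 1)
    bulge = params.distal_bulge * progress
    th = np.linspace(0.0, np.pi, n_arc)
    widen = 1.0 + bulge * np.sin(th) ** 2
    arc = np.column_stack([w * widen * np.cos(th), L * np.sin(th)])
    fh = params.flank_fraction * L
    flank = np.array([[-w, 0.0], [-w, -fh], [w, -fh], [w, 0.0]])
    return arc, flank


def _resample_path(path: np.ndarray, rel_pos: np.ndarray) -> np.ndarray:
    """Points at relative arc-length positions (0..1) along a polyline."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s = np.clip(rel_pos, 0.0, 1.0) * total
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    return path[idx] + (path[idx + 1] - path[idx]) * frac[:, None]


def _rel_positions(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum / cum[-1]


def _initial_boundary(params: LimbTrajectoryParams):
    arc, flank = _limb_outline(params, 0, params.n_frames)
    # sample the arc at roughly target_edge_length chord spacing
    seg = np.linalg.norm(np.diff(arc, axis=0), axis=1)
    n_arc = max(8, int(np.ceil(seg.sum() / params.target_edge_length)))
    arc_pts = _resample_path(arc, np.linspace(0.0, 1.0, n_arc + 1))
    # flank corners only; triangulation subdivides the straight edges
    verts = np.vstack([arc_pts, flank[1:3]])
    flank_edge = (len(arc_pts) - 1, 0)  # left base -> ... -> right base
    curve = BoundaryCurve(verts, stage_label=params.start_stage, flank_edge=flank_edge)
    corners = (len(arc_pts), len(arc_pts) + 1)  # bottom-left, bottom-right
    return curve, corners


def _harmonic_displace(mesh: TriMesh, boundary_disp: np.ndarray) -> np.ndarray:
    """Interior displacement as the harmonic extension of the boundary one.

    Solves the graph-Laplace equation on mesh edges with the boundary
    displacement as Dirichlet data — the standard smooth mesh-morphing choice;
    it keeps thin boundary triangles from inverting where a pure
    distance-weighted average can flatten them.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    nb = mesh.n_boundary
    V = mesh.vertices
    n = len(V)
    disp = np.zeros_like(V)
    disp[:nb] = boundary_disp
    if n == nb:
        return disp
    # vertex adjacency from triangle edges
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for a, b, c in mesh.triangles:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    interior = np.arange(nb, n)
    idx = {v: i for i, v in enumerate(interior)}
    A = lil_matrix((len(interior), len(interior)))
    rhs = np.zeros((len(interior), 2))
    for v in interior:
        i = idx[v]
        deg = len(nbrs[v])
        A[i, i] = deg
        for w in nbrs[v]:
            if w < nb:
                rhs[i] += disp[w]
            else:
                A[i, idx[w]] = -1.0
    sol = spsolve(A.tocsr(), rhs)
    disp[interior] = sol.reshape(len(interior), 2)
    return disp


def make_limb_trajectory(params: LimbTrajectoryParams | None = None) -> DomainTrajectory:
    """Generate the synthetic hourly limb-bud trajectory.

    One frame per hour, inclusive of both endpoint stages (the default
    mE10:09 → mE12:08 range yields 48 frames). Each frame's deformed end
    configuration places its boundary vertices exactly on the next frame's
    boundary polygon — consecutive remap regions are identical, so field
    transfer at changeover conserves material to float precision.
    """
    params = params or LimbTrajectoryParams()
    n = params.n_frames
    start_hour = stage_to_hour(params.start_stage)

    boundary, corners = _initial_boundary(params)
    frames: list[StageFrame] = []
    for k in range(n):
        mesh = triangulate_domain(boundary, params.target_edge_length)
        ecto = extract_boundary_mesh(mesh, boundary)
        nb = mesh.n_boundary
        if k < n - 1:
            # split mesh boundary vertices into arc and flank portions; the
            # flank endpoints anchor the correspondence to the next outline
            orig = mesh.boundary_orig_index
            n_orig = len(boundary.vertices)
            s_fl, e_fl = boundary.flank_edge
            ms, me = orig[s_fl % n_orig], orig[e_fl % n_orig]  # mesh idx of anchors
            arc_idx = []
            i = me
            while True:
                arc_idx.append(i)
                if i == ms:
                    break
                i = (i + 1) % nb
            flank_idx = []
            i = ms
            while True:
                flank_idx.append(i)
                if i == me:
                    break
                i = (i + 1) % nb
            arc_idx = np.asarray(arc_idx)
            flank_idx = np.asarray(flank_idx)

            next_arc, next_flank = _limb_outline(params, k + 1, n)
            bpos = mesh.vertices[:nb]
            # arc runs right base -> tip -> left base, matching next_arc's order
            new_b = np.empty_like(bpos)
            new_b[arc_idx] = _resample_path(next_arc, _rel_positions(bpos[arc_idx]))
            # flank mapped piecewise, segment by segment, with the rectangle
            # corners as anchors — vertices never drift across a corner, so no
            # boundary triangle collapses onto a straight flank edge
            mc1, mc2 = orig[corners[0] % n_orig], orig[corners[1] % n_orig]
            fl = list(flank_idx)
            i1, i2 = fl.index(mc1), fl.index(mc2)
            segments = (
                (fl[: i1 + 1], np.vstack([next_arc[-1], next_flank[1]])),
                (fl[i1: i2 + 1], np.vstack([next_flank[1], next_flank[2]])),
                (fl[i2:], np.vstack([next_flank[2], next_arc[0]])),
            )
            for chain, seg in segments:
                chain = np.asarray(chain)
                new_b[chain] = _resample_path(seg, _rel_positions(bpos[chain]))
            # exact anchor hand-over
            new_b[me] = next_arc[0]
            new_b[ms] = next_arc[-1]

            disp = _harmonic_displace(mesh, new_b - bpos)
            end_positions = mesh.vertices + disp

            next_boundary = BoundaryCurve(
                new_b,
                stage_label=hour_to_stage(start_hour + k + 1),
                flank_edge=(int(ms), int(me)),
            )
            corners = (int(mc1), int(mc2))
        else:
            end_positions = mesh.vertices.copy()
            next_boundary = None

        frames.append(
            StageFrame(
                index=k, boundary=boundary, mesh=mesh, ectoderm=ecto,
                end_positions=end_positions,
            )
        )
        if next_boundary is not None:
            boundary = next_boundary
    return DomainTrajectory(frames=frames, frame_duration=1.0)


def make_static_domain(
    shape: str = "square",
    size: float | tuple[float, float] = 1.0,
    target_edge_length: float = 0.1,
    n_frames: int = 1,
) -> DomainTrajectory:
    """A non-growing domain: ``n_frames`` identical frames, identity deformation.

    ``shape`` is ``"square"`` or ``"rectangle"`` (size = side length, or a
    (width, height) pair). The full outline carries ectoderm (closed chain).
    """
    if shape not in ("square", "rectangle"):
        raise ValueError(f"unknown shape {shape!r}")
    if isinstance(size, (int, float)):
        w = h = float(size)
    else:
        w, h = map(float, size)
    if shape == "square":
        h = w
    if w <= 0 or h <= 0 or n_frames < 1:
        raise ValueError("dimensions and frame count must be positive")
    boundary = BoundaryCurve(
        np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]]), stage_label=None
    )
    mesh = triangulate_domain(boundary, target_edge_length)
    ecto = extract_boundary_mesh(mesh, boundary)
    frames = [
        StageFrame(
            index=k, boundary=boundary, mesh=mesh, ectoderm=ecto,
            end_positions=mesh.vertices.copy(),
        )
        for k in range(n_frames)
    ]
    return DomainTrajectory(frames=frames, frame_duration=1.0)


# ---------------------------------------------------------------------------
# Builtin model catalogue (toy parameterisations, labelled as such)
# ---------------------------------------------------------------------------

# The classic Brusselator u' = a - (b+1)u + u²v, v' = bu - u²v with its
# homogeneous fixed point (a, b/a). With Dv/Du = 10 the Turing threshold is
# b_c = (1 + a·sqrt(Du/Dv))² ≈ 2.67 at a = 2; b = 3.5 sits inside the striped
# regime while staying below the Hopf threshold 1 + a² = 5. On the unit square
# the critical wavelength ~ 2π/(a/sqrt(Du·Dv))^{1/2} ≈ 0.35 fits ~3 periods.
_BRUSSELATOR = """\
name: brusselator
parameters:
  a: 2.0
  b: {value: 3.5, fittable: true, bounds: [0.5, 6.0]}
  Du: 0.002
  Dv: 0.02
  sigma: 0.0
reactants:
  u:
    compartment: mesenchyme
    rhs: "a - (b + 1)*u + u^2*v"
    diffusion: "Du"
    noise: "sigma"
    initial: "a"
  v:
    compartment: mesenchyme
    rhs: "b*u - u^2*v"
    diffusion: "Dv"
    noise: "sigma"
    initial: "b/a"
"""

# Activator-inhibitor pair with saturating autocatalysis (Gierer-Meinhardt
# type): short-range activation, long-range inhibition.
_TURING_TWO_SPECIES = """\
name: turing_two_species
parameters:
  rho: 1.0
  mu_a: 1.0
  mu_h: 1.2
  kappa: 0.05
  Da: 0.001
  Dh: 0.03
  sigma: 0.0
reactants:
  activator:
    compartment: mesenchyme
    rhs: "rho*activator^2/(inhibitor*(1 + kappa*activator^2)) - mu_a*activator + 0.05"
    diffusion: "Da"
    noise: "sigma"
    initial: "1"
    clamp: true
  inhibitor:
    compartment: mesenchyme
    rhs: "rho*activator^2 - mu_h*inhibitor"
    diffusion: "Dh"
    noise: "sigma"
    initial: "1"
    clamp: true
"""

# Six-species feedforward proximodistal network: FGF (F, distal input via
# fgf4_in/fgf8_in), retinoic acid (R, proximal, degraded by Cyp26b1 (C) which
# is FGF-induced), Meis (M, RA-activated / FGF-repressed), Hoxa11 (A11,
# mid-bud) and Hoxa13 (A13, distal). A toy structural analogue of the
# published proximodistal GRN, not its parameterisation.
_PD_FEEDFORWARD = """\
name: pd_feedforward_toy
parameters:
  kF: 2.0
  dF: 1.0
  DF: 0.01
  sR: 1.0
  dR: 0.3
  kRC: 4.0
  DR: 0.02
  sC: 2.0
  dC: 1.0
  KC: 0.5
  sM: 1.0
  dM: 1.0
  KMR: 0.3
  KMF: 0.4
  sA11: 1.0
  dA11: 1.0
  K11: 0.35
  sA13: 1.0
  dA13: 1.0
  K13: 0.8
  y_prox: 0.15
variables:
  fgf_total:
    compartment: mesenchyme
    expr: "fgf4_in + fgf8_in"
patterns:
  fgf4_in:
    compartment: mesenchyme
    expr: "hillact(y/(0.8 + 0.04*t), 0.8, 12)"
  fgf8_in:
    compartment: mesenchyme
    expr: "hillact(y/(0.8 + 0.04*t), 0.7, 8)"
reactants:
  F:
    compartment: mesenchyme
    rhs: "kF*fgf_total - dF*F"
    diffusion: "DF"
    noise: "0"
    initial: "0"
    clamp: true
  R:
    compartment: mesenchyme
    rhs: "sR*exp(-y/y_prox - max(0, t - 24)/12) - dR*R - kRC*C*R"
    diffusion: "DR"
    noise: "0"
    initial: "0"
    clamp: true
  C:
    compartment: mesenchyme
    rhs: "sC*hillact(F, KC, 4) - dC*C"
    diffusion: "0"
    noise: "0"
    initial: "0"
    clamp: true
  M:
    compartment: mesenchyme
    rhs: "sM*hillact(R, KMR, 4)*hillrep(F, KMF, 4) - dM*M"
    diffusion: "0"
    noise: "0"
    initial: "0"
    clamp: true
  A11:
    compartment: mesenchyme
    rhs: "sA11*hillact(F, K11, 4)*hillrep(A13, 0.3, 6) - dA11*A11"
    diffusion: "0"
    noise: "0"
    initial: "0"
    clamp: true
  A13:
    compartment: mesenchyme
    rhs: "sA13*hillact(F, K13, 6)*hillact(step(t - 12)*t, 14, 4) - dA13*A13"
    diffusion: "0"
    noise: "0"
    initial: "0"
    clamp: true
"""

# PORD-style system: a locally self-activating output with a diffusible
# repressor read-out, producing a travelling/oscillatory patterning front.
_PORD = """\
name: pord_toy
parameters:
  alpha: 3.0
  beta: 2.5
  mu: 1.0
  nu: 1.5
  Dr: 0.015
  sigma: 0.0
reactants:
  o:
    compartment: mesenchyme
    rhs: "alpha*hillact(o, 0.5, 4)*hillrep(r, 0.6, 4) - mu*o + 0.02"
    diffusion: "0"
    noise: "sigma"
    initial: "hillact(1 - x, 0.9, 30)"
    clamp: true
  r:
    compartment: mesenchyme
    rhs: "beta*hillact(o, 0.5, 4) - nu*r"
    diffusion: "Dr"
    noise: "sigma"
    initial: "0"
    clamp: true
"""

_CATALOGUE = {
    "brusselator": _BRUSSELATOR,
    "turing_two_species": _TURING_TWO_SPECIES,
    "pd_feedforward_toy": _PD_FEEDFORWARD,
    "pord_toy": _PORD,
}


def builtin_models() -> dict[str, ModelSpec]:
    """The named catalogue of builtin toy models (each passes validation)."""
    return {name: loads_model(text) for name, text in _CATALOGUE.items()}


def builtin_model(name: str) -> ModelSpec:
    if name not in _CATALOGUE:
        raise KeyError(
            f"unknown builtin model {name!r}; available: {', '.join(sorted(_CATALOGUE))}"
        )
    spec = loads_model(_CATALOGUE[name])
    diags = validate_model(spec)
    assert not diags, f"builtin model {name} failed validation: {diags}"
    return spec


# ---------------------------------------------------------------------------
# Synthetic images
# ---------------------------------------------------------------------------


def make_synthetic_image(
    width: int, height: int, pattern: str = "uniform", value: int | None = None,
    bit_depth: int = 8,
) -> np.ndarray:
    """Deterministic grayscale test rasters for digitisation.

    Patterns: ``uniform`` (constant ``value``), ``half_split`` (left half 0,
    right half max), ``linear_gradient`` (0 at the left edge to max at the
    right edge).
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    vmax = (1 << bit_depth) - 1
    if pattern == "uniform":
        v = vmax if value is None else int(value)
        return np.full((height, width), v, dtype=dtype)
    if pattern == "half_split":
        img = np.zeros((height, width), dtype=dtype)
        img[:, width // 2:] = vmax
        return img
    if pattern == "linear_gradient":
        row = np.round(np.linspace(0, vmax, width)).astype(dtype)
        return np.tile(row, (height, 1))
    raise ValueError(f"unknown pattern {pattern!r}")
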