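"""Declarative model specifications for GRN reaction–diffusion systems.

A model describes a system of coupled (stochastic) PDEs

    du/dt = f(u, x, t) + D ∇²u + η(u, t)

over three compartments: the 2D mesenchyme (triangular elements), the 1D
ectoderm boundary (linear elements) and a non-spatial global compartment.
Entities are:

* **parameters** — named numerical constants, optionally fittable with bounds;
* **variables** — named expressions evaluated each step, never time-integrated,
  never diffusing;
* **reactants** — time-integrated species with a reaction right-hand side ``f``
  (concentration/time), a diffusivity ``D`` (length²/time), a noise amplitude
  ``η`` (concentration/√time) and an initial condition, all free expressions;
* **pre-defined patterns** — feedforward spatiotemporal inputs, fixed with
  respect to the model (e.g. digitised FGF expression domains);
* **couplings** — diffusive exchange between a mesenchyme/ectoderm reactant
  pair, the discrete analogue of a dynamic boundary condition.

Expressions may reference global entities and entities of their own
compartment, plus the builtin symbols ``t``, ``x``, ``y`` (spatial compartments
only). The model file format is documented YAML; see ``examples/`` for a
commented example.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .expressions import Expression, ExpressionSyntaxError, parse_expression

__all__ = [
    "MESENCHYME",
    "ECTODERM",
    "GLOBAL",
    "ParameterDef",
    "VariableDef",
    "ReactantDef",
    "PredefinedPatternDef",
    "CouplingDef",
    "InterventionSpec",
    "ModelSpec",
    "Diagnostic",
    "ModelSchemaError",
    "validate_model",
    "load_model",
    "loads_model",
    "save_model",
    "dumps_model",
]

MESENCHYME = "mesenchyme"
ECTODERM = "ectoderm"
GLOBAL = "global"
_COMPARTMENTS = (MESENCHYME, ECTODERM, GLOBAL)
_SPATIAL = (MESENCHYME, ECTODERM)


class ModelSchemaError(ValueError):
    """A model file violates the documented schema; names the offending field."""


def _expr(value, where: str) -> Expression:
    if isinstance(value, Expression):
        return value
    try:
        return parse_expression(str(value))
    except ExpressionSyntaxError as e:
        raise ModelSchemaError(f"{where}: {e}") from e


@dataclass
class ParameterDef:
    name: str
    value: float
    fittable: bool = False
    bounds: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.bounds is not None:
            lo, hi = self.bounds
            if not (lo <= self.value <= hi):
                raise ModelSchemaError(
                    f"parameter {self.name!r}: value {self.value} outside bounds [{lo}, {hi}]"
                )


@dataclass
class VariableDef:
    name: str
    compartment: str
    expr: Expression


@dataclass
class ReactantDef:
    """A time-integrated species in a spatial compartment."""

    name: str
    compartment: str  # mesenchyme or ectoderm
    rhs: Expression
    diffusion: Expression
    noise: Expression
    initial: Expression
    clamp_nonnegative: bool = False


@dataclass
class PredefinedPatternDef:
    """Feedforward input: closed-form expr of (x, y, t) or per-frame arrays."""

    name: str
    compartment: str
    expr: Optional[Expression] = None
    frames: Optional[list[np.ndarray]] = None  # one per-element array per stage frame

    def __post_init__(self):
        if (self.expr is None) == (self.frames is None):
            raise ModelSchemaError(
                f"pattern {self.name!r}: exactly one of 'expr' or 'frames' required"
            )


@dataclass
class CouplingDef:
    mesenchyme_reactant: str
    ectoderm_reactant: str
    exchange_rate: Expression


@dataclass
class InterventionSpec:
    """Virtual experiment descriptor.

    ``bead``: a point source on the single element containing ``position``
    during ``window = (t_on, t_off)``, adding ``rate`` (concentration/time) to
    the target reactant's right-hand side; the bead tracks its material point
    through deformation and remeshing.

    ``expression_override``: temporarily replaces the rhs of a reactant or the
    expression of a variable during the window.
    """

    kind: str  # "bead" | "expression_override"
    target: str
    window: tuple[float, float]
    position: Optional[tuple[float, float]] = None  # bead
    rate: float = 0.0  # bead
    expr: Optional[Expression] = None  # expression_override

    def __post_init__(self):
        if self.kind not in ("bead", "expression_override"):
            raise ModelSchemaError(f"unknown intervention kind {self.kind!r}")
        t_on, t_off = self.window
        if not (t_off > t_on):
            raise ModelSchemaError(
                f"intervention on {self.target!r}: window must satisfy t_off > t_on"
            )
        if self.kind == "bead" and self.position is None:
            raise ModelSchemaError(f"bead on {self.target!r}: position required")
        if self.kind == "expression_override" and self.expr is None:
            raise ModelSchemaError(
                f"override on {self.target!r}: replacement expression required"
            )


@dataclass
class ModelSpec:
    name: str
    parameters: list[ParameterDef] = field(default_factory=list)
    variables: list[VariableDef] = field(default_factory=list)
    reactants: list[ReactantDef] = field(default_factory=list)
    patterns: list[PredefinedPatternDef] = field(default_factory=list)
    couplings: list[CouplingDef] = field(default_factory=list)
    interventions: list[InterventionSpec] = field(default_factory=list)

    def parameter_values(self) -> dict[str, float]:
        return {p.name: p.value for p in self.parameters}

    def reactant(self, name: str) -> ReactantDef:
        for r in self.reactants:
            if r.name == name:
                return r
        raise KeyError(name)

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    entity: str
    message: str

    def __str__(self) -> str:
        return f"{self.entity}: {self.message}"


def _visible_symbols(spec: ModelSpec, compartment: str) -> set[str]:
    """Names visible from a compartment: global entities + own-compartment ones."""
    vis = {p.name for p in spec.parameters}
    vis |= {v.name for v in spec.variables if v.compartment == GLOBAL}
    if compartment in _SPATIAL:
        vis |= {v.name for v in spec.variables if v.compartment == compartment}
        vis |= {r.name for r in spec.reactants if r.compartment == compartment}
        vis |= {p.name for p in spec.patterns if p.compartment == compartment}
    return vis


def validate_model(spec: ModelSpec) -> list[Diagnostic]:
    """Check a model for inconsistencies; an empty list means valid.

    Checks name uniqueness, symbol resolution, compartment visibility,
    variable-cycle freedom, coupling endpoints, pattern/intervention sanity.
    Diagnostics are returned, never raised.
    """
    diags: list[Diagnostic] = []

    def check_compartment(entity: str, comp: str, allowed=_COMPARTMENTS):
        if comp not in allowed:
            diags.append(Diagnostic(entity, f"invalid compartment {comp!r}"))
            return False
        return True

    # --- name uniqueness (and reserved symbols)
    seen: dict[str, str] = {}
    for kind, items in (
        ("parameter", spec.parameters),
        ("variable", spec.variables),
        ("reactant", spec.reactants),
        ("pattern", spec.patterns),
    ):
        for item in items:
            if item.name in ("t", "x", "y"):
                diags.append(
                    Diagnostic(item.name, f"{kind} name shadows the builtin symbol {item.name!r}")
                )
            if item.name in seen:
                diags.append(
                    Diagnostic(item.name, f"{kind} name already used by a {seen[item.name]}")
                )
            else:
                seen[item.name] = kind

    # --- compartments
    for v in spec.variables:
        check_compartment(v.name, v.compartment)
    for r in spec.reactants:
        check_compartment(r.name, r.compartment, _SPATIAL)
    for p in spec.patterns:
        check_compartment(p.name, p.compartment)

    # --- symbol resolution and visibility
    def check_expr(entity: str, what: str, expr: Expression, visible: set[str], spatial: bool):
        for sym in sorted(expr.free_symbols - visible):
            owner = seen.get(sym)
            if owner is None:
                diags.append(Diagnostic(entity, f"{what} references undefined symbol {sym!r}"))
            else:
                diags.append(
                    Diagnostic(
                        entity,
                        f"{what} references {sym!r}, a {owner} not visible from this compartment",
                    )
                )
        if not spatial and expr.used_symbols & {"x", "y"}:
            diags.append(
                Diagnostic(entity, f"{what} uses spatial coordinates in the global compartment")
            )

    for v in spec.variables:
        if v.compartment in _COMPARTMENTS:
            check_expr(
                v.name, "expr", v.expr, _visible_symbols(spec, v.compartment),
                v.compartment in _SPATIAL,
            )
    param_names = {p.name for p in spec.parameters}
    for r in spec.reactants:
        if r.compartment not in _SPATIAL:
            continue
        vis = _visible_symbols(spec, r.compartment)
        check_expr(r.name, "rhs", r.rhs, vis, True)
        check_expr(r.name, "diffusion", r.diffusion, vis, True)
        check_expr(r.name, "noise", r.noise, vis, True)
        # initial conditions may only use parameters, patterns, t, x, y:
        # reactants are undefined before initialisation and variables may
        # reference reactants.
        init_vis = param_names | {
            p.name for p in spec.patterns if p.compartment == r.compartment
        }
        for sym in sorted(r.initial.free_symbols - init_vis):
            diags.append(
                Diagnostic(
                    r.name,
                    f"initial may only reference parameters and patterns, not {sym!r}",
                )
            )
    for p in spec.patterns:
        if p.expr is not None:
            # patterns are feedforward: parameters and (t, x, y) only
            for sym in sorted(p.expr.free_symbols - param_names):
                diags.append(
                    Diagnostic(
                        p.name, f"pattern expression may only reference parameters, not {sym!r}"
                    )
                )

    # --- variable cycles (references among variables only)
    var_names = {v.name for v in spec.variables}
    deps = {v.name: (v.expr.free_symbols & var_names) for v in spec.variables}
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    def visit(name: str, stack: list[str]) -> bool:
        if state.get(name) == 1:
            return True
        if state.get(name) == 0:
            cyc = stack[stack.index(name):] + [name]
            diags.append(Diagnostic(name, "variable cycle: " + " -> ".join(cyc)))
            return False
        state[name] = 0
        ok = all(visit(d, stack + [name]) for d in sorted(deps[name]))
        state[name] = 1
        return ok

    for name in sorted(var_names):
        if name not in state:
            visit(name, [])

    # --- couplings
    by_name = {r.name: r for r in spec.reactants}
    for c in spec.couplings:
        m = by_name.get(c.mesenchyme_reactant)
        e = by_name.get(c.ectoderm_reactant)
        if m is None or m.compartment != MESENCHYME:
            diags.append(
                Diagnostic(
                    c.mesenchyme_reactant,
                    "coupling endpoint is not a mesenchyme reactant",
                )
            )
        if e is None or e.compartment != ECTODERM:
            diags.append(
                Diagnostic(
                    c.ectoderm_reactant, "coupling endpoint is not an ectoderm reactant"
                )
            )
        bad = c.exchange_rate.free_symbols - param_names - {
            v.name for v in spec.variables if v.compartment == GLOBAL
        }
        for sym in sorted(bad):
            diags.append(
                Diagnostic(
                    f"coupling {c.mesenchyme_reactant}~{c.ectoderm_reactant}",
                    f"exchange rate may only reference global entities, not {sym!r}",
                )
            )
        if c.exchange_rate.used_symbols & {"x", "y"}:
            diags.append(
                Diagnostic(
                    f"coupling {c.mesenchyme_reactant}~{c.ectoderm_reactant}",
                    "exchange rate uses spatial coordinates",
                )
            )

    # --- interventions
    targets = var_names | set(by_name)
    for iv in spec.interventions:
        if iv.kind == "bead":
            if iv.target not in by_name:
                diags.append(
                    Diagnostic(iv.target, "bead target is not a reactant of this model")
                )
        elif iv.target not in targets:
            diags.append(
                Diagnostic(iv.target, "override target is not a reactant or variable")
            )

    return diags


# ---------------------------------------------------------------------------
# Serialization (documented YAML schema)
# ---------------------------------------------------------------------------


def _parse_parameter(name: str, raw) -> ParameterDef:
    if isinstance(raw, (int, float)):
        return ParameterDef(name=name, value=float(raw))
    if isinstance(raw, dict):
        try:
            value = float(raw["value"])
        except KeyError:
            raise ModelSchemaError(f"parameters.{name}: missing 'value'")
        bounds = raw.get("bounds")
        if bounds is not None:
            bounds = (float(bounds[0]), float(bounds[1]))
        return ParameterDef(
            name=name, value=value, fittable=bool(raw.get("fittable", False)), bounds=bounds
        )
    raise ModelSchemaError(f"parameters.{name}: expected number or mapping")


def _parse_reactant(name: str, raw: dict) -> ReactantDef:
    if not isinstance(raw, dict):
        raise ModelSchemaError(f"reactants.{name}: expected mapping")
    comp = raw.get("compartment", MESENCHYME)
    if "rhs" not in raw:
        raise ModelSchemaError(f"reactants.{name}: missing 'rhs'")
    return ReactantDef(
        name=name,
        compartment=comp,
        rhs=_expr(raw["rhs"], f"reactants.{name}.rhs"),
        diffusion=_expr(raw.get("diffusion", 0), f"reactants.{name}.diffusion"),
        noise=_expr(raw.get("noise", 0), f"reactants.{name}.noise"),
        initial=_expr(raw.get("initial", 0), f"reactants.{name}.initial"),
        clamp_nonnegative=bool(raw.get("clamp", False)),
    )


def loads_model(text: str) -> ModelSpec:
    """Parse a model from its YAML text form."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ModelSchemaError(f"not valid YAML: {e}") from e
    if not isinstance(doc, dict):
        raise ModelSchemaError("model file must be a mapping at top level")
    if "name" not in doc:
        raise ModelSchemaError("missing required 'name' block")
    if "reactants" not in doc or not doc["reactants"]:
        raise ModelSchemaError("missing required 'reactants' block")

    parameters = [
        _parse_parameter(k, v) for k, v in (doc.get("parameters") or {}).items()
    ]
    variables = []
    for k, v in (doc.get("variables") or {}).items():
        if not isinstance(v, dict) or "expr" not in v:
            raise ModelSchemaError(f"variables.{k}: expected mapping with 'expr'")
        variables.append(
            VariableDef(
                name=k,
                compartment=v.get("compartment", GLOBAL),
                expr=_expr(v["expr"], f"variables.{k}.expr"),
            )
        )
    reactants = [_parse_reactant(k, v) for k, v in doc["reactants"].items()]
    patterns = []
    for k, v in (doc.get("patterns") or {}).items():
        if not isinstance(v, dict):
            raise ModelSchemaError(f"patterns.{k}: expected mapping")
        frames = v.get("frames")
        if frames is not None:
            frames = [np.asarray(f, dtype=float) for f in frames]
        patterns.append(
            PredefinedPatternDef(
                name=k,
                compartment=v.get("compartment", MESENCHYME),
                expr=_expr(v["expr"], f"patterns.{k}.expr") if "expr" in v else None,
                frames=frames,
            )
        )
    couplings = []
    for i, c in enumerate(doc.get("couplings") or []):
        try:
            couplings.append(
                CouplingDef(
                    mesenchyme_reactant=c["mesenchyme"],
                    ectoderm_reactant=c["ectoderm"],
                    exchange_rate=_expr(c["rate"], f"couplings[{i}].rate"),
                )
            )
        except KeyError as e:
            raise ModelSchemaError(f"couplings[{i}]: missing {e.args[0]!r}")
    interventions = []
    for i, iv in enumerate(doc.get("interventions") or []):
        try:
            kind = iv["kind"]
            window = (float(iv["window"][0]), float(iv["window"][1]))
        except KeyError as e:
            raise ModelSchemaError(f"interventions[{i}]: missing {e.args[0]!r}")
        pos = iv.get("position")
        interventions.append(
            InterventionSpec(
                kind=kind,
                target=iv.get("target", ""),
                window=window,
                position=(float(pos[0]), float(pos[1])) if pos is not None else None,
                rate=float(iv.get("rate", 0.0)),
                expr=_expr(iv["expr"], f"interventions[{i}].expr") if "expr" in iv else None,
            )
        )
    return ModelSpec(
        name=str(doc["name"]),
        parameters=parameters,
        variables=variables,
        reactants=reactants,
        patterns=patterns,
        couplings=couplings,
        interventions=interventions,
    )


def dumps_model(spec: ModelSpec) -> str:
    """Render a model to its YAML text form (expressions re-rendered)."""
    doc: dict = {"name": spec.name}
    if spec.parameters:
        params = {}
        for p in spec.parameters:
            if p.fittable or p.bounds is not None:
                entry: dict = {"value": p.value}
                if p.fittable:
                    entry["fittable"] = True
                if p.bounds is not None:
                    entry["bounds"] = list(p.bounds)
                params[p.name] = entry
            else:
                params[p.name] = p.value
        doc["parameters"] = params
    if spec.variables:
        doc["variables"] = {
            v.name: {"compartment": v.compartment, "expr": v.expr.render()}
            for v in spec.variables
        }
    doc["reactants"] = {
        r.name: {
            "compartment": r.compartment,
            "rhs": r.rhs.render(),
            "diffusion": r.diffusion.render(),
            "noise": r.noise.render(),
            "initial": r.initial.render(),
            "clamp": r.clamp_nonnegative,
        }
        for r in spec.reactants
    }
    if spec.patterns:
        pats = {}
        for p in spec.patterns:
            entry = {"compartment": p.compartment}
            if p.expr is not None:
                entry["expr"] = p.expr.render()
            else:
                entry["frames"] = [f.tolist() for f in p.frames]
            pats[p.name] = entry
        doc["patterns"] = pats
    if spec.couplings:
        doc["couplings"] = [
            {
                "mesenchyme": c.mesenchyme_reactant,
                "ectoderm": c.ectoderm_reactant,
                "rate": c.exchange_rate.render(),
            }
            for c in spec.couplings
        ]
    if spec.interventions:
        ivs = []
        for iv in spec.interventions:
            entry = {"kind": iv.kind, "target": iv.target, "window": list(iv.window)}
            if iv.position is not None:
                entry["position"] = list(iv.position)
            if iv.kind == "bead":
                entry["rate"] = iv.rate
            if iv.expr is not None:
                entry["expr"] = iv.expr.render()
            ivs.append(entry)
        doc["interventions"] = ivs
    return yaml.safe_dump(doc, sort_keys=False)


def load_model(path) -> ModelSpec:
    return loads_model(Path(path).read_text())


def save_model(spec: ModelSpec, path) -> None:
    Path(path).write_text(dumps_model(spec))
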