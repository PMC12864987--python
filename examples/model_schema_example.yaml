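# Commented example of the limbrd model file format (YAML).
#
# A model is a system of coupled stochastic reaction-diffusion PDEs
#     du/dt = f(u, x, t) + D laplacian(u) + eta(u, t)
# over three compartments: "mesenchyme" (the 2D limb interior, triangular
# elements), "ectoderm" (the 1D limb-arc boundary, linear elements) and
# "global" (non-spatial). All right-hand sides are free mathematical
# expressions over the model's own entities plus the builtin symbols
#   t  - simulation time (hours)
#   x, y - element coordinates (domain length unit; y increases distally)
# and the builtin functions
#   sin cos exp log sqrt abs  min(a,b) max(a,b)  step(z)
#   hillact(u, K, n) = u^n / (K^n + u^n)     Hill-type activation
#   hillrep(u, K, n) = K^n / (K^n + u^n)     Hill-type repression
# step(0) is 1 by convention. Operators: + - * / ^ (right-associative power),
# parentheses, unary minus. Identifiers are case-sensitive
# [A-Za-z_][A-Za-z0-9_]*; t, x, y may not be redefined.

name: annotated_example

# --- parameters: named constants (dimensionless unless noted). A bare number
# is shorthand; the mapping form declares fittability and bounds.
parameters:
  k_deg: 1.0                                   # degradation rate, 1/h
  K_half: {value: 0.5, fittable: true, bounds: [0.05, 5.0]}
  D_lig: 0.01                                  # diffusivity, length^2/h
  k_ex: 0.3                                    # compartment exchange, 1/h

# --- variables: named expressions, re-evaluated every step; never
# time-integrated, never diffusing. Compartment defaults to "global".
variables:
  drive:
    compartment: global
    expr: "2*k_deg"
  local_input:                                 # spatial variables may use x, y
    compartment: mesenchyme
    expr: "fgf_in * hillrep(lig, K_half, 4)"

# --- reactants: time-integrated species. "compartment" is mesenchyme or
# ectoderm. rhs has units concentration/h, diffusion length^2/h, noise
# concentration/sqrt(h), initial concentration. "clamp: true" floors the
# species at 0 after each step.
reactants:
  lig:
    compartment: mesenchyme
    rhs: "drive*local_input - k_deg*lig"
    diffusion: "D_lig"
    noise: "0.01"
    initial: "0"
    clamp: true
  lig_ect:
    compartment: ectoderm
    rhs: "-k_deg*lig_ect"
    diffusion: "0.002"
    noise: "0"
    initial: "0"
    clamp: true

# --- patterns: pre-defined feedforward inputs, fixed with respect to the
# model. Either a closed-form expression of (x, y, t) and parameters, or
# "frames": one per-element array per stage frame of the trajectory.
patterns:
  fgf_in:
    compartment: mesenchyme
    expr: "hillact(y, 0.7, 8)"                 # distal input domain

# --- couplings: diffusive exchange between a mesenchyme/ectoderm reactant
# pair through each boundary element's owner triangle (rate in 1/h; may
# reference global entities and t only).
couplings:
  - {mesenchyme: lig, ectoderm: lig_ect, rate: "k_ex"}

# --- interventions: virtual experiments.
#   bead: point source on the element containing "position" during "window",
#         adding "rate" (concentration/h) to the target reactant.
#   expression_override: temporarily replaces the target's rhs (reactant) or
#         expression (variable) during the window.
interventions:
  - {kind: bead, target: lig, position: [0.0, 0.6], window: [2.0, 5.0], rate: 4.0}
  - {kind: expression_override, target: lig, window: [10.0, 12.0], expr: "0"}
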