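"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pytest

from limbrd import BoundaryCurve, loads_model, triangulate_domain
from limbrd.fixtures import LimbTrajectoryParams, make_limb_trajectory, make_static_domain


@pytest.fixture(scope="session")
def unit_square_mesh():
    boundary = BoundaryCurve(np.array([[0.0, 0.0], [1, 0], [1, 1], [0, 1]]))
    return triangulate_domain(boundary, 0.1)


@pytest.fixture(scope="session")
def square_trajectory():
    """Static unit square, 4 identical hourly frames."""
    return make_static_domain("square", 1.0, 0.1, n_frames=4)


@pytest.fixture(scope="session")
def short_limb_trajectory():
    """A 12-frame slice of the synthetic limb trajectory (mE10:09-mE10:20)."""
    return make_limb_trajectory(
        LimbTrajectoryParams(start_stage="mE10:09", end_stage="mE10:20",
                             target_edge_length=0.14)
    )


@pytest.fixture()
def decay_model():
    return loads_model(
        """
name: decay
parameters:
  k: {value: 0.7, fittable: true, bounds: [0.05, 3.0]}
reactants:
  u: {compartment: mesenchyme, rhs: "-k*u", initial: "1"}
"""
    )


@pytest.fixture()
def diffusion_model():
    return loads_model(
        """
name: diffusion_only
parameters: {D: 0.02}
reactants:
  u:
    compartment: mesenchyme
    rhs: "0"
    diffusion: "D"
    initial: "1 + x + hillact(y, 0.5, 2)"
"""
    )
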