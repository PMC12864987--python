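"""Integration scheme: explicit Euler-Maruyama, finite-volume diffusion,
growth dilution, coupling, interventions and full simulations."""

import copy

import numpy as np
import pytest

from limbrd import (
    FieldState,
    InterventionSpec,
    SimulationConfig,
    SimulationError,
    StabilityError,
    apply_growth_dilution,
    diffusion_rates,
    loads_model,
    place_bead,
    simulate,
)
from limbrd.fixtures import make_static_domain


def total_amount(movie, species="u"):
    out = []
    for s in movie.snapshots:
        frame = movie.trajectory.frames[s.frame_index]
        A = frame.mesh.triangle_areas(s.positions)
        out.append(float((s.state.mesenchyme[species] * A).sum()))
    return np.asarray(out)


class TestDiffusionOperator:
    def test_uniform_field_has_zero_rates(self, unit_square_mesh):
        m = unit_square_mesh
        el, cd = m.edge_geometry()
        rates = diffusion_rates(m.areas, m.adj_tris, el, cd,
                                np.full(len(m.triangles), 3.0),
                                np.full(len(m.triangles), 0.1))
        np.testing.assert_array_equal(rates, 0.0)

    def test_pairwise_conservation(self, unit_square_mesh):
        m = unit_square_mesh
        el, cd = m.edge_geometry()
        rng = np.random.default_rng(0)
        u = rng.random(len(m.triangles))
        D = rng.random(len(m.triangles))
        rates = diffusion_rates(m.areas, m.adj_tris, el, cd, u, D)
        assert abs(float((rates * m.areas).sum())) < 1e-12 * np.abs(u).sum()

    def test_slowest_mode_matches_heat_equation(self):
        """Second-slowest eigenvalue of the operator vs the analytic D*pi^2."""
        mesh = make_static_domain("square", 1.0, 1 / 20).frames[0].mesh
        D = 0.3
        M = len(mesh.triangles)
        A = mesh.areas
        el, cd = mesh.edge_geometry()
        L = np.zeros((M, M))
        for (i, j), l, d in zip(mesh.adj_tris, el, cd):
            w = D * l / d
            L[i, i] -= w / A[i]
            L[i, j] += w / A[i]
            L[j, j] -= w / A[j]
            L[j, i] += w / A[j]
        # similarity transform by sqrt(A) makes the operator symmetric
        S = np.diag(np.sqrt(A)) @ L @ np.diag(1 / np.sqrt(A))
        ev = np.sort(np.linalg.eigvalsh(0.5 * (S + S.T)))[::-1]
        assert abs(ev[0]) < 1e-9  # conservation mode
        assert abs(-ev[1] / (D * np.pi**2) - 1) < 0.05


class TestIntegration:
    def test_explicit_euler_decay_is_exact_per_step(self, square_trajectory,
                                                    decay_model):
        cfg = SimulationConfig(dt=0.01, output_every=1, t_end=0.05)
        movie = simulate(decay_model, square_trajectory, cfg)
        expected = movie.snapshots[0].state.mesenchyme["u"].copy()
        for snap in movie.snapshots[1:]:
            expected = expected + 0.01 * (-0.7 * expected)  # one explicit step
            np.testing.assert_array_equal(snap.state.mesenchyme["u"], expected)

    def test_decay_matches_closed_form_with_first_order_convergence(
        self, square_trajectory, decay_model
    ):
        errs = []
        for dt in (0.02, 0.01):
            cfg = SimulationConfig(dt=dt, output_every=int(1 / dt), t_end=1.0)
            movie = simulate(decay_model, square_trajectory, cfg)
            u = movie.snapshots[-1].state.mesenchyme["u"][0]
            errs.append(abs(u - np.exp(-0.7)))
        assert errs[0] / errs[1] == pytest.approx(2.0, abs=0.2)

    def test_same_seed_bit_identical(self, square_trajectory):
        spec = loads_model(
            "name: noisy\nparameters: {s: 0.2}\n"
            "reactants:\n  u: {compartment: mesenchyme, rhs: '0', noise: 's', initial: '1'}\n"
        )
        cfg = SimulationConfig(dt=0.01, seed=42, output_every=20, t_end=0.5)
        a = simulate(spec, square_trajectory, cfg)
        b = simulate(spec, square_trajectory, cfg)
        for sa, sb in zip(a.snapshots, b.snapshots):
            np.testing.assert_array_equal(
                sa.state.mesenchyme["u"], sb.state.mesenchyme["u"]
            )

    def test_zero_noise_is_seed_independent(self, square_trajectory, decay_model):
        runs = [
            simulate(decay_model, square_trajectory,
                     SimulationConfig(dt=0.01, seed=s, output_every=50, t_end=0.5))
            for s in (1, 999)
        ]
        np.testing.assert_array_equal(
            runs[0].snapshots[-1].state.mesenchyme["u"],
            runs[1].snapshots[-1].state.mesenchyme["u"],
        )

    def test_wiener_variance_law(self):
        """With f = D = 0, Var[u(t)] across replicates approaches sigma^2 * t."""
        traj = make_static_domain("square", 1.0, 0.045, n_frames=1)
        spec = loads_model(
            "name: wiener\nparameters: {s: 0.5}\n"
            "reactants:\n  u: {compartment: mesenchyme, rhs: '0', noise: 's', initial: '0'}\n"
        )
        vals = []
        for seed in (0, 1):
            cfg = SimulationConfig(dt=0.01, seed=seed, output_every=100, t_end=1.0)
            movie = simulate(spec, traj, cfg)
            vals.append(movie.snapshots[-1].state.mesenchyme["u"])
        v = np.concatenate(vals)  # each element is an independent replicate
        assert v.size >= 1000
        assert abs(v.var() / 0.25 - 1) < 0.10

    def test_sqrt_area_noise_scaling(self, short_limb_trajectory):
        """With the SPDE flag on, each element's noise is divided by the
        square root of its area (same draws, so the runs differ exactly by
        that factor when f = D = 0)."""
        spec = loads_model(
            "name: n\nparameters: {s: 0.3}\n"
            "reactants:\n  u: {compartment: mesenchyme, rhs: '0', noise: 's', initial: '0'}\n"
        )
        base = SimulationConfig(dt=0.05, seed=4, output_every=4, t_end=0.2)
        scaled = SimulationConfig(dt=0.05, seed=4, output_every=4, t_end=0.2,
                                  noise_sqrt_area_scaling=True)
        a = simulate(spec, short_limb_trajectory, base)
        b = simulate(spec, short_limb_trajectory, scaled)
        for sa, sb in zip(a.snapshots[1:], b.snapshots[1:]):
            frame = short_limb_trajectory.frames[sa.frame_index]
            # compare increments in a single frame with slowly varying areas:
            # ratio of states stays close to 1/sqrt(A) after short times
            ratio = sb.state.mesenchyme["u"] / sa.state.mesenchyme["u"]
            A = frame.mesh.triangle_areas(sa.positions)
            np.testing.assert_allclose(ratio, 1 / np.sqrt(A), rtol=0.05)

    def test_nonfinite_state_aborts_with_context(self, square_trajectory):
        spec = loads_model(
            "name: blowup\nreactants:\n"
            "  u: {compartment: mesenchyme, rhs: 'u*u', initial: '50'}\n"
        )
        with pytest.raises(SimulationError, match="u"):
            simulate(spec, square_trajectory,
                     SimulationConfig(dt=0.5, output_every=1, t_end=4.0))

    def test_stability_check_errors_when_strict(self, square_trajectory,
                                                diffusion_model):
        cfg = SimulationConfig(dt=0.25, output_every=1, t_end=1.0,
                               stability_check=True)
        with pytest.raises(StabilityError):
            simulate(diffusion_model, square_trajectory, cfg)

    def test_snapshot_count_contract(self, square_trajectory, decay_model):
        cfg = SimulationConfig(dt=0.01, output_every=30, t_end=2.0)
        movie = simulate(decay_model, square_trajectory, cfg)
        assert len(movie.snapshots) == int(np.floor(200 / 30)) + 1
        assert (np.diff(movie.times) > 0).all()


class TestGrowthAndConservation:
    def test_dilution_keeps_per_element_amount(self):
        state = FieldState(time=0.0, mesenchyme={"u": np.array([1.0, 2.0, 3.0])})
        ratio = np.array([0.5, 1.0, 2.0])  # A_before / A_after
        apply_growth_dilution(state, ratio)
        np.testing.assert_allclose(state.mesenchyme["u"], [0.5, 2.0, 6.0])

    def test_pure_diffusion_conserves_on_static_square(self, square_trajectory,
                                                       diffusion_model):
        cfg = SimulationConfig(dt=0.005, output_every=1, t_end=1.0)
        amounts = total_amount(simulate(diffusion_model, square_trajectory, cfg))
        drift = np.abs(np.diff(amounts)) / amounts[0]
        assert drift.max() < 1e-10

    def test_pure_diffusion_conserves_across_remesh(self, short_limb_trajectory,
                                                    diffusion_model):
        cfg = SimulationConfig(dt=0.01, output_every=25, t_end=6.0)
        amounts = total_amount(simulate(diffusion_model, short_limb_trajectory, cfg))
        assert np.abs(amounts - amounts[0]).max() < 1e-8 * amounts[0]

    def test_coupling_conserves_and_equilibrates(self):
        traj = make_static_domain("square", 1.0, 0.2, n_frames=3)
        spec = loads_model(
            """
name: exchange
parameters: {kex: 2.0}
reactants:
  um: {compartment: mesenchyme, rhs: "0", initial: "1"}
  ue: {compartment: ectoderm, rhs: "0", initial: "0"}
couplings:
  - {mesenchyme: um, ectoderm: ue, rate: "kex"}
"""
        )
        cfg = SimulationConfig(dt=0.002, output_every=50, t_end=3.0)
        movie = simulate(spec, traj, cfg)
        frame = traj.frames[0]
        A = frame.mesh.areas
        L = frame.ectoderm.lengths(frame.mesh.vertices)
        combined = [
            float((s.state.mesenchyme["um"] * A).sum()
                  + (s.state.ectoderm["ue"] * L).sum())
            for s in movie.snapshots
        ]
        assert np.abs(np.diff(combined)).max() < 1e-10 * combined[0]
        # concentrations approach each other monotonically on owner triangles
        owners = frame.ectoderm.owner_triangle
        gaps = [
            np.abs(s.state.mesenchyme["um"][owners] - s.state.ectoderm["ue"]).mean()
            for s in movie.snapshots
        ]
        assert all(b <= a + 1e-12 for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 0.05 * gaps[0]


BEAD_MODEL = """
name: bead_toy
parameters: {k: 1.0}
reactants:
  R:
    compartment: mesenchyme
    rhs: "-k*R"
    diffusion: "0.005"
    initial: "0"
    clamp: true
"""


class TestInterventions:
    def make_spec(self, rate, window=(0.5, 1.5), pos=(0.5, 0.5)):
        spec = loads_model(BEAD_MODEL)
        spec.interventions.append(
            InterventionSpec(kind="bead", target="R", window=window,
                             position=pos, rate=rate)
        )
        return spec

    def test_zero_rate_bead_changes_nothing(self, square_trajectory):
        cfg = SimulationConfig(dt=0.01, output_every=25, t_end=2.0)
        base = simulate(loads_model(BEAD_MODEL), square_trajectory, cfg)
        with_bead = simulate(self.make_spec(0.0), square_trajectory, cfg)
        for a, b in zip(base.snapshots, with_bead.snapshots):
            np.testing.assert_array_equal(a.state.mesenchyme["R"],
                                          b.state.mesenchyme["R"])

    def test_bead_elevates_target_locally_during_window_only(self,
                                                             square_trajectory):
        cfg = SimulationConfig(dt=0.01, output_every=10, t_end=3.0)
        movie = simulate(self.make_spec(5.0), square_trajectory, cfg)
        mesh = square_trajectory.frames[0].mesh
        cent = mesh.centroids()
        near = np.linalg.norm(cent - [0.5, 0.5], axis=1) < 0.15
        far = np.linalg.norm(cent - [0.5, 0.5], axis=1) > 0.4

        before = movie.snapshot_at(0.4).state.mesenchyme["R"]
        during = movie.snapshot_at(1.5).state.mesenchyme["R"]
        after = movie.snapshot_at(3.0).state.mesenchyme["R"]
        assert before.max() == 0.0
        assert during[near].max() > 10 * max(during[far].max(), 1e-12)
        assert after.max() < 0.3 * during.max()  # decays once the window closes

    def test_bead_outside_domain_rejected(self, square_trajectory):
        spec = self.make_spec(1.0, pos=(5.0, 5.0))
        with pytest.raises(SimulationError, match="outside"):
            simulate(spec, square_trajectory,
                     SimulationConfig(dt=0.01, output_every=10, t_end=2.0))
        with pytest.raises(SimulationError):
            place_bead(spec.interventions[0], square_trajectory)

    def test_place_bead_resolves_containing_element(self, square_trajectory):
        spec = self.make_spec(1.0, pos=(0.31, 0.62))
        ti = place_bead(spec.interventions[0], square_trajectory)
        mesh = square_trajectory.frames[0].mesh
        tri = mesh.vertices[mesh.triangles[ti]]
        # barycentric containment
        from matplotlib.path import Path

        assert Path(tri).contains_point((0.31, 0.62), radius=1e-9)

    def test_expression_override_window(self, square_trajectory):
        spec = loads_model(BEAD_MODEL)
        from limbrd import parse_expression

        spec.interventions.append(
            InterventionSpec(kind="expression_override", target="R",
                             window=(0.0, 1.0), expr=parse_expression("1 - k*R"))
        )
        cfg = SimulationConfig(dt=0.01, output_every=50, t_end=2.0)
        movie = simulate(spec, square_trajectory, cfg)
        during = movie.snapshot_at(1.0).state.mesenchyme["R"]
        after = movie.snapshot_at(2.0).state.mesenchyme["R"]
        assert during.min() > 0.5  # driven towards 1 while overridden
        assert after.max() < during.min()  # pure decay resumes
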