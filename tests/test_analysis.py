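"""Digitisation, pattern comparison and parameter fitting."""

import numpy as np
import pytest

from limbrd import (
    AlignmentTransform,
    DigitisedPattern,
    FitTarget,
    ObjectiveSpec,
    SimulationConfig,
    digitise_image,
    fit_parameters,
    loads_model,
    objective_value,
    pattern_difference,
    simulate,
)
from limbrd.analysis import DigitisationError
from limbrd.fixtures import make_static_domain, make_synthetic_image


@pytest.fixture(scope="module")
def mesh():
    return make_static_domain("square", 1.0, 0.1).frames[0].mesh


class TestDigitisation:
    def test_uniform_image_constant_everywhere(self, mesh):
        img = make_synthetic_image(64, 64, "uniform", value=200)
        tf = AlignmentTransform.fit_bounds(img.shape, mesh)
        pat = digitise_image(img, tf, mesh)
        np.testing.assert_allclose(pat.values, 200 / 255, atol=1e-12)

    def test_uniform_image_constant_under_rotation(self, mesh):
        img = make_synthetic_image(96, 96, "uniform", value=128)
        c, s = np.cos(0.7), np.sin(0.7)
        # rotated frame placed so the mesh stays inside the image footprint
        m = np.array([[c / 40, -s / 40, -0.8], [s / 40, c / 40, -0.8]])
        pat = digitise_image(img, AlignmentTransform(m), mesh)
        np.testing.assert_allclose(pat.values, 128 / 255, atol=1e-12)

    def test_half_split_separates_sides(self, mesh):
        img = make_synthetic_image(128, 128, "half_split")
        tf = AlignmentTransform.fit_bounds(img.shape, mesh)
        pat = digitise_image(img, tf, mesh)
        cent = mesh.centroids()
        left = cent[:, 0] < 0.4
        right = cent[:, 0] > 0.6
        assert pat.values[left].max() == 0.0
        assert pat.values[right].min() == 1.0

    def test_gradient_matches_supersampling_oracle(self, mesh):
        img = make_synthetic_image(256, 256, "linear_gradient")
        tf = AlignmentTransform.fit_bounds(img.shape, mesh)
        pat = digitise_image(img, tf, mesh)

        rng = np.random.default_rng(3)
        vals = img.astype(float) / 255.0
        h, w = img.shape
        inv = np.linalg.inv(tf.matrix[:, :2])
        for ei in range(0, len(mesh.triangles), 11):
            a, b, c = mesh.vertices[mesh.triangles[ei]]
            r1 = np.sqrt(rng.random(20000))
            r2 = rng.random(20000)
            pts = (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (
                r1 * r2)[:, None] * c
            pix = (pts - tf.matrix[:, 2]) @ inv.T
            cc = np.clip(np.floor(pix[:, 0]).astype(int), 0, w - 1)
            rr = np.clip(np.floor(pix[:, 1]).astype(int), 0, h - 1)
            oracle = vals[rr, cc].mean()
            assert abs(pat.values[ei] - oracle) < 2e-3

    def test_inverted_intensity(self, mesh):
        img = make_synthetic_image(64, 64, "uniform", value=55)
        tf = AlignmentTransform.fit_bounds(img.shape, mesh, invert_intensity=True)
        pat = digitise_image(img, tf, mesh)
        np.testing.assert_allclose(pat.values, (255 - 55) / 255, atol=1e-12)

    def test_multichannel_rejected(self, mesh):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        tf = AlignmentTransform(np.array([[1.0, 0, 0], [0, 1, 0]]))
        with pytest.raises(DigitisationError, match="single-channel"):
            digitise_image(img, tf, mesh)

    def test_zero_coverage_rejected(self, mesh):
        img = make_synthetic_image(16, 16, "uniform", value=10)
        tf = AlignmentTransform(np.array([[0.001, 0, 50.0], [0, 0.001, 50.0]]))
        with pytest.raises(DigitisationError, match="outside"):
            digitise_image(img, tf, mesh)

    def test_16bit_scaling(self, mesh):
        img = make_synthetic_image(64, 64, "uniform", value=1000, bit_depth=16)
        tf = AlignmentTransform.fit_bounds(img.shape, mesh)
        pat = digitise_image(img, tf, mesh)
        np.testing.assert_allclose(pat.values, 1000 / 65535, atol=1e-12)


class TestPatternDifference:
    def test_identical_fields_zero(self, mesh):
        u = np.random.default_rng(0).random(len(mesh.triangles))
        diff, rms = pattern_difference(u, u, mesh)
        assert rms == 0.0 and np.all(diff == 0)

    def test_unit_offset_rms_one(self, mesh):
        M = len(mesh.triangles)
        diff, rms = pattern_difference(np.ones(M), np.zeros(M), mesh)
        assert rms == pytest.approx(1.0)
        np.testing.assert_array_equal(diff, 1.0)

    def test_antisymmetry(self, mesh):
        rng = np.random.default_rng(1)
        a, b = rng.random(len(mesh.triangles)), rng.random(len(mesh.triangles))
        d_ab, rms_ab = pattern_difference(a, b, mesh)
        d_ba, rms_ba = pattern_difference(b, a, mesh)
        np.testing.assert_allclose(d_ab, -d_ba)
        assert rms_ab == rms_ba

    def test_mismatched_lengths_rejected(self, mesh):
        with pytest.raises(ValueError, match="match"):
            pattern_difference(np.ones(3), np.ones(3), mesh)


FIT_MODEL = """
name: decayfit
parameters:
  k: {value: 0.7, fittable: true, bounds: [0.05, 3.0]}
reactants:
  u: {compartment: mesenchyme, rhs: "-k*u", initial: "1 + x"}
"""


@pytest.fixture(scope="module")
def fit_setup():
    traj = make_static_domain("square", 1.0, 0.12, n_frames=1)
    spec = loads_model(FIT_MODEL)
    cfg = SimulationConfig(dt=0.02, output_every=50, t_end=1.0)
    ref = simulate(spec, traj, cfg)
    target = FitTarget(reactant="u",
                       values=ref.snapshots[-1].state.mesenchyme["u"], time=1.0)
    obj = ObjectiveSpec(model=spec, trajectory=traj, config=cfg,
                        fittable={"k": (0.05, 3.0)}, targets=[target])
    return obj


class TestObjectiveAndFit:
    def test_self_consistency_zero_objective(self, fit_setup):
        assert objective_value({"k": 0.7}, fit_setup) < 1e-12

    def test_objective_nonnegative_and_grows_off_truth(self, fit_setup):
        assert objective_value({"k": 1.4}, fit_setup) > 0

    def test_two_element_hand_computation(self):
        """Objective equals direct arithmetic on a tiny hand-checkable case."""
        traj = make_static_domain("square", 1.0, 0.8, n_frames=1)
        mesh = traj.frames[0].mesh
        spec = loads_model(FIT_MODEL.replace('"1 + x"', '"1"'))
        cfg = SimulationConfig(dt=0.5, output_every=1, t_end=0.5)
        ref = np.zeros(len(mesh.triangles))
        obj = ObjectiveSpec(model=spec, trajectory=traj, config=cfg,
                            fittable={"k": (0.05, 3.0)},
                            targets=[FitTarget("u", ref, time=0.5, weight=2.0)])
        # one Euler step: u = 1 - k*dt = 1 - 0.7*0.5 = 0.65 on every element;
        # area-weighted mean squared difference vs 0 is 0.65^2; weight 2
        assert objective_value({"k": 0.7}, obj) == pytest.approx(2 * 0.65**2,
                                                                 rel=1e-12)

    def test_objective_invariant_under_target_reordering(self, fit_setup):
        obj = fit_setup
        t = obj.targets[0]
        half_a = FitTarget(t.reactant, t.field(), t.time, weight=0.5)
        obj2 = ObjectiveSpec(model=obj.model, trajectory=obj.trajectory,
                             config=obj.config, fittable=obj.fittable,
                             targets=[half_a, half_a])
        obj3 = ObjectiveSpec(model=obj.model, trajectory=obj.trajectory,
                             config=obj.config, fittable=obj.fittable,
                             targets=[half_a, half_a][::-1])
        assert objective_value({"k": 1.1}, obj2) == objective_value({"k": 1.1}, obj3)

    def test_out_of_bounds_params_rejected(self, fit_setup):
        with pytest.raises(ValueError, match="bounds"):
            objective_value({"k": 99.0}, fit_setup)

    def test_recovers_decay_constant_within_one_percent(self, fit_setup):
        res = fit_parameters(fit_setup, {"k": 0.2}, budget=60, seed=1)
        assert abs(res.parameters["k"] - 0.7) < 0.01 * 0.7
        assert res.objective <= objective_value({"k": 0.2}, fit_setup)

    def test_start_at_truth_converges_immediately(self, fit_setup):
        res = fit_parameters(fit_setup, {"k": 0.7}, budget=50, seed=0)
        assert res.converged and res.n_evaluations == 1
        assert res.objective < 1e-12

    def test_trace_respects_bounds_and_reproducibility(self, fit_setup):
        a = fit_parameters(fit_setup, {"k": 0.3}, budget=25, seed=5, n_restarts=1)
        b = fit_parameters(fit_setup, {"k": 0.3}, budget=25, seed=5, n_restarts=1)
        assert all(0.05 <= p["k"] <= 3.0 for p, _ in a.trace)
        assert [(p["k"], f) for p, f in a.trace] == [(p["k"], f) for p, f in b.trace]

    def test_values_must_lie_in_unit_interval(self):
        with pytest.raises(DigitisationError):
            DigitisedPattern(values=np.array([0.2, 1.4]))
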