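"""Solver verification: Prony arithmetic, analytic oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import facefem.fem_core as fc
from facefem.mesh import LANDMARKS
from facefem.phantom import build_block_mesh, synthesize_truth


class TestShearRelaxation:
    def test_no_relaxation_at_time_zero(self):
        assert fc.shear_relaxation(0.0) == 1.0
        assert fc.shear_relaxation(0.0, scale=1.5) == 1.0

    def test_total_relaxation_is_62_5_percent(self):
        g_inf = fc.shear_relaxation(1e6, scale=1.0)
        assert g_inf == pytest.approx(0.375, abs=1e-9)
        assert fc.relaxation_percent(1.0) == pytest.approx(62.5)

    def test_scaled_relaxation_minimum_30_5_percent(self):
        assert fc.shear_relaxation(1e6, scale=0.488) == pytest.approx(0.695, abs=1e-4)
        assert fc.relaxation_percent(0.488) == pytest.approx(30.5, abs=0.01)

    def test_scale_recovered_from_relaxation_percent(self):
        assert fc.scale_for_relaxation(30.5) == pytest.approx(0.488, abs=1e-4)
        assert fc.scale_for_relaxation(62.5) == pytest.approx(1.0)

    def test_finite_time_value_matches_formula(self):
        expect = 1 - 0.325 * (1 - np.exp(-1.0)) - 0.3 * (1 - np.exp(-1.0 / 6.0))
        assert fc.shear_relaxation(1.0) == pytest.approx(expect, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            fc.shear_relaxation(-0.1)

    def test_excessive_scale_rejected(self):
        with pytest.raises(ValueError):
            fc.shear_relaxation(1.0, scale=1.7)  # 1.7 * 0.625 > 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        g1=st.floats(0.05, 0.5),
        g2=st.floats(0.05, 0.4),
        t1=st.floats(0.1, 10.0),
        t2=st.floats(0.1, 50.0),
        scale=st.floats(0.1, 1.4),
    )
    def test_monotone_non_increasing_with_long_time_limit(self, g1, g2, t1, t2, scale):
        if (g1 + g2) * scale >= 1.0:
            scale = 0.99 / (g1 + g2)
        prony = fc.PronySeries(g=(g1, g2), tau=(t1, t2))
        times = np.linspace(0, 200, 300)
        vals = fc.shear_relaxation(times, prony, scale)
        assert np.all(np.diff(vals) <= 1e-12)
        assert vals[-1] >= 1.0 - scale * (g1 + g2) - 1e-9


class TestInputVector:
    def test_bounds_table_matches_literature_ranges(self):
        b = fc.table2_bounds(5.0)
        assert b["E_bone"] == (5000.0, 15000.0)
        assert b["nu_soft"] == (0.45, 0.499)
        assert b["G_scale"] == (0.488, 1.512)
        assert b["x_adv"] == (3.0, 7.0)

    def test_validation_rejects_inadmissible_inputs(self):
        with pytest.raises(ValueError):
            fc.InputVector(nu_soft=0.5).validate()
        with pytest.raises(ValueError):
            fc.InputVector(E_soft=-1.0).validate()
        with pytest.raises(ValueError):
            fc.InputVector(G_scale=1.7).validate()


@pytest.fixture(scope="module")
def soft_block():
    mesh = build_block_mesh((20.0, 20.0, 20.0), 5.0, "soft_tissue")
    bc = fc.BoundarySpec(
        fixed=(("x_min", (0,)), ("y_min", (1,)), ("z_min", (2,))),
        prescribed_set="y_max",
        direction=(0.0, 1.0, 0.0),
        prescribed_axes=(1,),
        ramp=1.0,
        hold=59.0,
    )
    return mesh, bc


class TestSolverOracles:
    def test_uniaxial_block_matches_closed_form(self, soft_block):
        """Homogeneous uniaxial extension with free lateral faces."""
        mesh, bc = soft_block
        nu, d, L = 0.45, 1.0, 20.0
        inp = fc.InputVector(E_soft=0.5, nu_soft=nu, x_adv=d)
        u = fc.ViscoelasticSolver(mesh, bc).solve_elastic(inp).final()
        exact = np.column_stack(
            [-nu * d * mesh.nodes[:, 0] / L,
             d * mesh.nodes[:, 1] / L,
             -nu * d * mesh.nodes[:, 2] / L]
        )
        assert np.abs(u - exact).max() / d < 0.005

    def test_long_time_equals_relaxed_elastic_solve(self, soft_block):
        """End-of-hold viscoelastic field == elastic field at G_inf."""
        mesh, bc = soft_block
        inp = fc.InputVector(E_soft=0.5, nu_soft=0.47, G_scale=1.2, x_adv=1.0)
        s = fc.ViscoelasticSolver(mesh, bc)
        uv = s.solve(inp).final()
        g_inf = 1.0 - inp.G_scale * fc.default_prony().total
        ue = s.solve_elastic(inp, soft_shear_factor=g_inf).final()
        assert np.abs(uv - ue).max() / np.abs(ue).max() < 0.01

    def test_instantaneous_response_is_unrelaxed(self, soft_block):
        """End of a very short ramp == elastic solve with unrelaxed modulus."""
        mesh, bc = soft_block
        import dataclasses

        fast = dataclasses.replace(bc, ramp=1e-4, hold=0.0)
        inp = fc.InputVector(E_soft=0.5, nu_soft=0.47, G_scale=1.4, x_adv=1.0)
        s = fc.ViscoelasticSolver(mesh, fast)
        uv = s.solve(inp, time_grid=np.array([0.0, 1e-4])).final()
        ue = s.solve_elastic(inp, soft_shear_factor=1.0).final()
        assert np.abs(uv - ue).max() / np.abs(ue).max() < 0.01


class TestPhantomSolves:
    def test_zero_advancement_gives_zero_field(self, phantom_coarse, solver_coarse):
        _, landmarks = phantom_coarse
        inp = fc.midrange_inputs().replace(x_adv=0.0)
        field = solver_coarse.solve(inp)
        assert np.abs(field.final()).max() == 0.0
        assert np.allclose(fc.extract_landmarks(field, landmarks), 0.0)

    def test_joint_modulus_scaling_leaves_displacements_unchanged(
        self, phantom_coarse, solver_coarse
    ):
        """Prescribed-displacement loading is invariant to a global
        stiffness rescale."""
        _, landmarks = phantom_coarse
        inp = fc.midrange_inputs()
        d1 = fc.extract_landmarks(solver_coarse.solve(inp), landmarks)
        scaled = inp.replace(
            E_bone=2 * inp.E_bone, E_cart=2 * inp.E_cart, E_soft=2 * inp.E_soft
        )
        d2 = fc.extract_landmarks(solver_coarse.solve(scaled), landmarks)
        assert np.allclose(d1, d2, rtol=1e-8, atol=1e-10)

    def test_landmarks_monotone_in_advancement(self, phantom_coarse, solver_coarse):
        _, landmarks = phantom_coarse
        inp = fc.midrange_inputs()
        prev = None
        for adv in (2.0, 4.0, 6.0):
            d = fc.extract_landmarks(solver_coarse.solve(inp.replace(x_adv=adv)),
                                     landmarks)
            if prev is not None:
                assert np.all(d >= prev - 1e-9)
            prev = d

    def test_relaxation_scale_effect_has_constant_sign_at_upper_lip(
        self, phantom_coarse, solver_coarse
    ):
        _, landmarks = phantom_coarse
        inp = fc.midrange_inputs()
        ul = [
            fc.extract_landmarks(solver_coarse.solve(inp.replace(G_scale=g)),
                                 landmarks)[1]
            for g in (0.488, 1.0, 1.512)
        ]
        diffs = np.diff(ul)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_upper_lip_within_rigid_attachment_bracket(
        self, phantom_default, landmark_solution_default, midrange
    ):
        """UL tracks the mobile segment: between half and 110 % of the
        prescribed advancement at midrange inputs."""
        ul = landmark_solution_default[LANDMARKS.index("UL")]
        assert 0.5 * midrange.x_adv <= ul <= 1.1 * midrange.x_adv

    def test_mesh_refinement_changes_landmarks_below_5_percent(self):
        """Halving the target edge length is a <5 % perturbation."""
        from facefem.phantom import GeometryParams, build_phantom, refine

        p = GeometryParams()
        inp = fc.midrange_inputs()
        out = []
        for params in (p, refine(p, 2.0)):
            mesh, lm = build_phantom(params)
            out.append(
                fc.extract_landmarks(
                    fc.ViscoelasticSolver(mesh).solve(inp, store="last"), lm
                )
            )
        rel = np.abs(out[1] - out[0]) / np.abs(out[1])
        assert np.all(rel < 0.05), rel


class TestExtraction:
    def test_zero_and_rigid_translation_fields(self, phantom_coarse):
        mesh, landmarks = phantom_coarse
        zero = np.zeros((mesh.n_nodes, 3))
        assert np.allclose(fc.extract_landmarks(zero, landmarks), 0.0)
        rigid = np.tile([0.0, 2.5, 0.0], (mesh.n_nodes, 1))
        assert np.allclose(fc.extract_landmarks(rigid, landmarks), 2.5)

    def test_invalid_landmark_index_raises(self, phantom_coarse):
        from facefem.mesh import LandmarkSet

        mesh, _ = phantom_coarse
        bad = LandmarkSet(
            indices={"N": mesh.n_nodes + 1, "UL": 0, "LL": 1, "RC": 2, "LC": 3}
        )
        with pytest.raises(IndexError):
            fc.extract_landmarks(np.zeros((mesh.n_nodes, 3)), bad)

    def test_time_grid_validation(self, phantom_coarse, solver_coarse):
        inp = fc.midrange_inputs()
        with pytest.raises(fc.FEMError):
            solver_coarse.solve(inp, time_grid=np.array([0.0, 2.0, 1.0]))
        with pytest.raises(fc.FEMError):
            solver_coarse.solve(inp, time_grid=np.array([0.5, 1.0]))


class TestSyntheticTruth:
    def test_zero_noise_is_exact_forward_solve(self, phantom_coarse, solver_coarse):
        mesh, landmarks = phantom_coarse
        inp = fc.midrange_inputs()
        truth = synthesize_truth(mesh, landmarks, inp, noise_sd=0.0, seed=5,
                                 solver=solver_coarse)
        direct = fc.extract_landmarks(
            solver_coarse.solve(inp), landmarks
        )
        assert np.array_equal(truth, direct)

    def test_noise_level_calibrated(self, phantom_coarse, solver_coarse):
        """Sample SD of the added noise is close to the requested 0.2 mm."""
        mesh, landmarks = phantom_coarse
        inp = fc.midrange_inputs()
        base = synthesize_truth(mesh, landmarks, inp, noise_sd=0.0,
                                solver=solver_coarse)
        rng_draws = np.array([
            synthesize_truth(mesh, landmarks, inp, noise_sd=0.2, seed=k,
                             solver=solver_coarse) - base
            for k in range(100)
        ])
        sds = rng_draws.std(axis=0, ddof=1)
        assert np.all(sds > 0.15) and np.all(sds < 0.25)

    def test_reproducible_given_seed(self, phantom_coarse, solver_coarse):
        mesh, landmarks = phantom_coarse
        inp = fc.midrange_inputs()
        a = synthesize_truth(mesh, landmarks, inp, noise_sd=0.3, seed=11,
                             solver=solver_coarse)
        b = synthesize_truth(mesh, landmarks, inp, noise_sd=0.3, seed=11,
                             solver=solver_coarse)
        assert np.array_equal(a, b)
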