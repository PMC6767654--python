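import numpy as np
import pytest

import glymphuq as g
from glymphuq import fem
from glymphuq.solver import _MidpointStepper, assemble_operators


def diffusion_problem(mesh, D=1.2e-10, **kw):
    coeffs = g.CoefficientSample(D, None, 0.0, seed=0, model="test")
    return g.TransportProblem(mesh, coeffs, **kw)


class TestAssembly:
    def test_lumped_mass_sums_to_volume(self, unit_cube):
        M = fem.lumped_mass(unit_cube.vertices, unit_cube.cells)
        assert M.sum() == pytest.approx(1.0, rel=1e-12)
        assert M.min() > 0

    def test_pure_diffusion_operator_is_symmetric(self, unit_cube):
        ops = assemble_operators(diffusion_problem(unit_cube, D=1.0))
        K = ops.transport
        assert abs(K - K.T).max() < 1e-14 * abs(K).max()
        # positive semi-definite: constants are in the kernel of stiffness
        assert np.abs(ops.diffusion @ np.ones(unit_cube.n_vertices)).max() < 1e-12

    def test_convection_row_sums_vanish_for_divergence_free_p1_field(self, unit_cube):
        # v = (y - z, z - x, x - y) is linear and solenoidal: interpolation exact
        x = unit_cube.vertices
        v = np.column_stack([x[:, 1] - x[:, 2], x[:, 2] - x[:, 0], x[:, 0] - x[:, 1]])
        C = fem.convection_matrix(unit_cube.vertices, unit_cube.cells, v)
        rows = np.asarray(C.sum(axis=1)).ravel()
        interior = np.setdiff1d(np.arange(unit_cube.n_vertices),
                                np.unique(unit_cube.facets))
        assert np.abs(rows[interior]).max() < 1e-14
        # columns sum to zero by partition of unity (basis of flux accounting)
        assert np.abs(np.asarray(C.sum(axis=0))).max() < 1e-14

    def test_interpolated_field_divergence_is_reported(self, brain_mesh):
        rng = np.random.default_rng(0)
        v = 1e-7 * rng.standard_normal((brain_mesh.n_vertices, 3))
        coeffs = g.CoefficientSample(1.2e-10, v, 0.0, seed=0, model="t")
        ops = assemble_operators(g.TransportProblem(brain_mesh, coeffs))
        assert ops.convection_row_sum_max > 0  # nonzero and reported, not hidden

    def test_degenerate_cell_rejected(self, unit_cube):
        bad = g.LabeledMesh(unit_cube.vertices.copy(), unit_cube.cells.copy(),
                            unit_cube.cell_label, unit_cube.facets, unit_cube.facet_label)
        bad.vertices[bad.cells[0, 1]] = bad.vertices[bad.cells[0, 0]]
        with pytest.raises(ValueError):
            assemble_operators(diffusion_problem(bad))


class TestStep:
    def test_zero_boundary_zero_state_stays_zero(self, unit_cube):
        ops = assemble_operators(diffusion_problem(unit_cube, D=1.0))
        stepper = _MidpointStepper(ops, 0.1)
        c = stepper.step(np.zeros(unit_cube.n_vertices), np.zeros(len(ops.dirichlet_nodes)))
        assert np.all(c == 0.0)

    def test_reaction_decay_matches_midpoint_exponential(self):
        # uniform state, negligible diffusion, boundary held at the decayed
        # value: interior follows the one-step midpoint approximation of
        # exp(-r dt)
        mesh = g.build_box_mesh((1, 1, 1), (6, 6, 6))
        r, dt, c0 = 1e-4, 900.0, 2.0
        coeffs = g.CoefficientSample(1e-16, None, r, seed=0, model="t")
        ops = assemble_operators(g.TransportProblem(mesh, coeffs))
        stepper = _MidpointStepper(ops, dt)
        factor = (1 - r * dt / 2) / (1 + r * dt / 2)
        c = stepper.step(np.full(mesh.n_vertices, c0),
                         np.full(len(ops.dirichlet_nodes), c0 * factor))
        assert c == pytest.approx(c0 * factor, rel=1e-10)
        assert factor == pytest.approx(np.exp(-r * dt), rel=(r * dt) ** 2)

    def test_spatial_convergence_is_second_order(self):
        # decaying eigenmode of the heat equation on the unit box with
        # homogeneous Dirichlet data: L2 error drops ~4x per mesh halving
        D, T, dt = 1.0, 4e-3, 1e-4
        errs = []
        for n in (4, 8, 16):
            mesh = g.build_box_mesh((1, 1, 1), (n, n, n))
            ops = assemble_operators(diffusion_problem(mesh, D=D))
            stepper = _MidpointStepper(ops, dt)
            x = mesh.vertices
            c = np.sin(np.pi * x[:, 0]) * np.sin(np.pi * x[:, 1]) * np.sin(np.pi * x[:, 2])
            zero = np.zeros(len(ops.dirichlet_nodes))
            for _ in range(int(T / dt)):
                c = stepper.step(c, zero)
            exact = np.exp(-3 * np.pi ** 2 * D * T) * np.sin(np.pi * x[:, 0]) \
                * np.sin(np.pi * x[:, 1]) * np.sin(np.pi * x[:, 2])
            errs.append(np.sqrt(ops.lumped_mass @ (c - exact) ** 2))
        rate1 = np.log2(errs[0] / errs[1])
        rate2 = np.log2(errs[1] / errs[2])
        assert rate1 > 1.6 and rate2 > 1.6


class TestSolveTransport:
    def test_budget_is_conserved_to_machine_precision(self, baseline_series):
        assert baseline_series.budget_residuals.max() < 1e-10

    def test_budget_identity_holds_at_every_step(self, baseline_series, brain_mesh):
        s = baseline_series
        total = s.parenchymal_trace + s.c_csf_trace * 1.4e-4 + s.drained_trace
        assert np.abs(total - 5e-4).max() < 1e-6 * 5e-4

    def test_temporal_convergence_is_first_order(self, brain_mesh):
        # c_CSF(6 h) differences between successive dt halvings shrink ~2x
        vals = {}
        for dt in (3600.0, 1800.0, 900.0):
            prob = diffusion_problem(brain_mesh, dt=dt, t_end=6 * 3600.0)
            vals[dt] = g.solve_transport(prob).c_csf_trace[-1]
        e1 = abs(vals[3600.0] - vals[1800.0])
        e2 = abs(vals[1800.0] - vals[900.0])
        assert 1.4 < e1 / e2 < 3.0

    def test_deterministic_reproducibility(self, brain_mesh, baseline_series):
        again = g.solve_transport(diffusion_problem(brain_mesh))
        assert np.array_equal(again.nodal_c, baseline_series.nodal_c)
        assert np.array_equal(again.c_csf_trace, baseline_series.c_csf_trace)

    def test_diffusion_respects_bounds(self, baseline_series):
        # with v = 0, r = 0 and lumping, values stay in [0, max g] up to eps
        max_g = baseline_series.c_csf_trace.max()
        assert baseline_series.nodal_c.min() > -1e-3 * max_g
        assert baseline_series.nodal_c.max() < max_g * (1 + 1e-10)

    def test_initial_condition_is_zero(self, baseline_series):
        assert np.all(baseline_series.nodal_c[0] == 0.0)

    def test_sas_concentration_decreases_as_tracer_enters(self, baseline_series):
        c = baseline_series.c_csf_trace
        assert c[0] == pytest.approx(3.5714, abs=2e-3)
        assert np.all(np.diff(c) <= 1e-12)

    def test_output_time_validation(self, brain_mesh):
        with pytest.raises(ValueError):
            g.TransportProblem(brain_mesh,
                               g.CoefficientSample(1e-10, None, 0.0, seed=0),
                               dt=900.0, output_times=np.array([1000.0]))

    def test_drainage_accumulates_and_drains_the_budget(self, brain_mesh):
        coeffs = g.CoefficientSample(1.2e-10, None, 1e-5, seed=0, model="t")
        s = g.solve_transport(g.TransportProblem(brain_mesh, coeffs, t_end=6 * 3600.0))
        assert np.all(np.diff(s.drained_trace) >= 0)
        assert s.drained_trace[-1] > 0
        assert s.budget_residuals.max() < 1e-10


class TestPeclet:
    def test_printed_estimate_exceeds_1000(self):
        pe = g.estimate_peclet(0.084, 1.7e-7, 1.2e-10)
        assert pe == pytest.approx(1071.0, rel=1e-3)
        assert pe >= 1e3

    def test_degenerate_cases(self):
        assert g.estimate_peclet(0.084, 0.0, 1.2e-10) == 0.0
        assert g.estimate_peclet(0.168, 1.7e-7, 1.2e-10) == pytest.approx(
            2 * g.estimate_peclet(0.084, 1.7e-7, 1.2e-10))
        with pytest.raises(ValueError):
            g.estimate_peclet(0.084, 1.7e-7, 0.0)


class TestDirectionalOutflow:
    def test_net_outflow_is_positive(self, brain_mesh):
        # the directional field drains a small net volume out of the domain
        out = g.directional_surface_outflow(brain_mesh)
        assert out > 0
        # and scales linearly with the field magnitude
        assert g.directional_surface_outflow(brain_mesh, v_f=4e-6) == pytest.approx(
            2 * out, rel=1e-12)
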