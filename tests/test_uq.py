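import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glymphuq as g
from glymphuq.uq import qoi_table, sample_seeds


class TestEstimators:
    def test_constant_samples(self):
        mean, se = g.estimate_expectation(np.full(50, 7.0))
        assert (mean, se) == (7.0, 0.0)
        assert g.prediction_interval(np.full(50, 7.0)) == (7.0, 7.0)

    def test_gaussian_mean_within_four_standard_errors(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        mean, se = g.estimate_expectation(x)
        assert abs(mean) < 4 / np.sqrt(10_000)
        assert se == pytest.approx(1 / np.sqrt(10_000), rel=0.05)

    def test_standard_error_halves_when_n_quadruples(self):
        rng = np.random.default_rng(2)
        _, se1 = g.estimate_expectation(rng.standard_normal(4_000))
        _, se2 = g.estimate_expectation(rng.standard_normal(16_000))
        assert se1 / se2 == pytest.approx(2.0, rel=0.1)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            g.estimate_expectation([1.0])


class TestPredictionInterval:
    def test_order_statistics_on_a_uniform_grid(self):
        # linear-interpolation quantile oracle computed by hand for 1..N
        x = np.arange(1.0, 101.0)
        lo, hi = g.prediction_interval(x)
        tail = (1 - 0.9973) / 2
        assert lo == pytest.approx(1 + tail * 99, rel=1e-12)
        assert hi == pytest.approx(100 - tail * 99, rel=1e-12)

    def test_gaussian_interval_is_plus_minus_three_sigma(self):
        x = np.random.default_rng(3).standard_normal(100_000)
        lo, hi = g.prediction_interval(x)
        assert lo == pytest.approx(-3.0, abs=0.15)
        assert hi == pytest.approx(3.0, abs=0.15)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200))
    def test_interval_brackets_the_mean(self, xs):
        lo, hi = g.prediction_interval(xs)
        assert lo <= np.mean(xs) <= hi


class TestErrorCriterion:
    def test_sample_size_arithmetic(self):
        # V=1, Q=10: 3 sqrt(V/N) crosses 0.01 Q between N = 100 and N = 3200
        big = np.tile([9.0, 11.0], 1600)    # mean 10, variance ~1, N = 3200
        small = np.tile([9.0, 11.0], 50)    # N = 100
        assert g.check_error_criterion(big) is True
        assert g.check_error_criterion(small) is False

    def test_degenerate_cases(self):
        assert g.check_error_criterion(np.full(10, 5.0)) is True  # zero variance
        with pytest.raises(ValueError):
            g.check_error_criterion(np.array([-1.0, 1.0]))  # zero mean


class TestPdfCdf:
    def test_censoring_caps_the_cdf(self):
        est = g.estimate_pdf_cdf(np.linspace(0, 1, 96), n_censored=4)
        assert est["cdf_y"][-1] == pytest.approx(0.96)
        assert est["uncensored_fraction"] == pytest.approx(0.96)

    def test_density_integrates_to_uncensored_fraction(self):
        x = np.random.default_rng(4).standard_normal(2000)
        est = g.estimate_pdf_cdf(x, n_censored=500)
        mass = np.trapezoid(est["density"], est["grid"])
        assert mass == pytest.approx(0.8, abs=0.05)

    def test_kde_mode_near_the_true_mean(self):
        x = 5.0 + np.random.default_rng(5).standard_normal(4000)
        est = g.estimate_pdf_cdf(x)
        mode = est["grid"][np.argmax(est["density"])]
        bw = x.std() * len(x) ** (-1 / 5)  # Scott bandwidth
        assert abs(mode - 5.0) < 3 * bw

    def test_all_censored_raises(self):
        with pytest.raises(ValueError):
            g.estimate_pdf_cdf([], n_censored=10)


@pytest.fixture(scope="module")
def mesh():
    return g.build_synthetic_brain(target_edge_length=0.015, ventricle_radius=0.02)


class TestCoefficientStructure:
    """Each model produces exactly its tabulated stochastic pattern."""

    def test_d1_random_scalar_no_flow(self, mesh):
        s = g.sample_coefficients("D1", mesh, 1)
        assert np.isscalar(s.diffusivity) and s.velocity is None and s.drainage_r == 0.0

    def test_d2_random_field_no_flow(self, mesh):
        s = g.sample_coefficients("D2", mesh, 1)
        assert np.asarray(s.diffusivity).shape == (mesh.n_vertices,)
        assert s.velocity is None and s.drainage_r == 0.0

    def test_v1_constant_diffusivity_and_flow(self, mesh):
        lam = 1020e-6
        matern = g.MaternSpec.for_mesh(mesh, lam, 0.0023, strict=False)
        vel = g.VelocitySpec(model="V1", eta=1.0)
        s = g.sample_coefficients("V1", mesh, 1, velocity=vel, matern=matern)
        assert s.diffusivity == 1.2e-10
        assert s.velocity.shape == (mesh.n_vertices, 3) and s.drainage_r == 0.0

    def test_v3_inflow_with_drainage(self, mesh):
        s = g.sample_coefficients("V3", mesh, 1)
        assert s.diffusivity == 1.2e-10
        assert s.velocity is not None and s.drainage_r == 1e-5

    def test_unknown_model_rejected(self, mesh):
        with pytest.raises(ValueError):
            g.sample_coefficients("D3", mesh, 1)


@pytest.fixture(scope="module")
def short_spec(brain_mesh):
    return dict(mesh=brain_mesh, N=4, t_end=4 * 3600.0,
                checkpoint_hours=(1.0, 3.0))


class TestMonteCarloDriver:

    def test_runs_are_bit_reproducible(self, short_spec):
        t1 = qoi_table(g.run_monte_carlo(g.ModelSpec(model="D1", base_seed=7,
                                                     **short_spec))[0])
        t2 = qoi_table(g.run_monte_carlo(g.ModelSpec(model="D1", base_seed=7,
                                                     **short_spec))[0])
        assert t1.equals(t2)

    def test_degenerate_diffusion_gives_zero_width_intervals(self, short_spec):
        # vanishing gamma scale: all realizations share the same coefficients
        diff = g.DiffusionSpec(model="D1", gamma_scale=1e-30)
        _, summary = g.run_monte_carlo(g.ModelSpec(model="D1", base_seed=1,
                                                   diffusion=diff, **short_spec))
        for name, s in summary.stats.items():
            lo, hi = s.interval
            assert hi - lo <= 1e-9 * max(abs(s.mean), 1e-30)

    def test_summary_metadata_records_model_structure(self, short_spec):
        _, summary = g.run_monte_carlo(g.ModelSpec(model="D1", base_seed=1,
                                                   **short_spec))
        struct = summary.metadata["coefficient_structure"]
        assert struct == {"D": "random variable", "v": 0, "r": 0}
        assert summary.N == 4

    def test_per_sample_seeds_are_deterministic(self):
        a = sample_seeds(123, 8)
        b = sample_seeds(123, 8)
        c = sample_seeds(124, 8)
        assert np.array_equal(a, b) and not np.array_equal(a, c)
        assert len(np.unique(a)) == 8


class TestYamlConfig:
    def test_config_round_trip_controls_the_run(self, tmp_path, brain_mesh):
        from glymphuq.config import load_model_config, model_spec_from_config

        cfg = tmp_path / "run.yaml"
        cfg.write_text(
            "model: D1\n"
            "n_samples: 3\n"
            "base_seed: 5\n"
            "t_end: 7200\n"
            "diffusion: {D_Gad: 2.4e-10}\n"
            "boundary: {n0: 1.0e-3}\n"
            "geometry: {edge: 0.015, ventricle_radius: 0.02}\n")
        spec = load_model_config(cfg)
        assert spec.model == "D1" and spec.N == 3 and spec.t_end == 7200
        assert spec.diffusion.D_Gad == 2.4e-10
        assert spec.boundary.n0 == 1e-3
        assert spec.mesh.metadata["target_edge_length"] == 0.015

    def test_unknown_keys_rejected(self, brain_mesh):
        from glymphuq.config import model_spec_from_config

        with pytest.raises(ValueError, match="unknown"):
            model_spec_from_config({"model": "D1", "typo_key": 1}, mesh=brain_mesh)
        with pytest.raises(ValueError, match="boundary"):
            model_spec_from_config({"model": "D1", "boundary": {"bad": 1}},
                                   mesh=brain_mesh)
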