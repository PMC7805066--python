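"""LQ-Poisson TCP model, alpha discretisation and uncertainty expectations."""

import numpy as np
import pytest
from scipy import ndimage

from tcplan.grids import VoxelGrid
from tcplan.radiobiology import (
    AlphaDistribution,
    EUDParams,
    ExpectationEngine,
    RadiobioParams,
    discretize_alpha,
    expected_dose,
    expected_eud,
    expected_tcp,
    geud,
    plan_tcp,
    population_tcp,
    voxel_tcp,
)
from tcplan.uncertainty import ZERO_ERROR

from conftest import make_small_instance


class TestAlphaDiscretisation:
    def test_degenerate_sd_is_point_mass(self):
        ad = discretize_alpha(0.15, 0.0, 1)
        assert ad.alphas.tolist() == [0.15]
        assert ad.weights.tolist() == [1.0]

    def test_moment_recovery_large_p(self):
        ad = discretize_alpha(0.15, 0.04, 10001)
        assert ad.alphas.mean() == pytest.approx(0.15, rel=1e-3)
        assert ad.alphas.std() == pytest.approx(0.04, rel=1e-2)

    @pytest.mark.parametrize("p", [1, 2, 5, 11, 100])
    def test_weights_sum_to_one(self, p):
        assert discretize_alpha(p=p).weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_samples_positive(self):
        assert np.all(discretize_alpha(0.15, 0.1, 101).alphas > 0)


class TestVoxelTCP:
    def test_zero_density_gives_unity(self, params):
        assert voxel_tcp(0.0, 10.0, 0.15, 2.0, params) == 1.0

    def test_worked_exponent_case(self, params):
        """1e4 cells at 2 Gy x 39: survival exponent -18.35, TCP ~ 0.99989."""
        # independent high-precision evaluation of the closed form
        import mpmath

        mpmath.mp.dps = 40
        expo = (
            -mpmath.mpf("0.15") * 39 * 2
            - mpmath.mpf("0.15") * 39 * 4 / mpmath.mpf("3.1")
            + mpmath.log(2) * mpmath.mpf("54.6") / 42
        )
        oracle = float(mpmath.exp(-mpmath.mpf(1e4) * mpmath.exp(expo)))
        got = voxel_tcp(1e4 / 10.0, 10.0, 0.15, 2.0, params)
        assert got == pytest.approx(oracle, rel=1e-10)
        assert got == pytest.approx(0.99989, abs=5e-5)

    def test_zero_dose_closed_form(self, params):
        rho, v = 10.0, 10.0
        expect = np.exp(-rho * v * 2 ** (params.t_exp_days / params.t_pot_days))
        assert voxel_tcp(rho, v, 0.15, 0.0, params) == pytest.approx(expect, rel=1e-12)

    def test_monotonicity(self, params):
        doses = np.linspace(0, 4, 50)
        vals = voxel_tcp(50.0, 10.0, 0.15, doses, params)
        assert np.all(np.diff(vals) >= 0)
        rhos = np.linspace(0, 1e4, 50)
        vals2 = voxel_tcp(rhos, 10.0, 0.15, 2.0, params)
        assert np.all(np.diff(vals2) <= 0)
        assert np.all((vals > 0) & (vals <= 1))

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            voxel_tcp(-1.0, 10.0, 0.15, 2.0, params)
        with pytest.raises(ValueError):
            voxel_tcp(1.0, 10.0, 0.15, -2.0, params)


class TestPlanTCP:
    def test_product_matches_naive_loop(self, params):
        grid = VoxelGrid(shape=(5, 5, 4))
        rng = np.random.default_rng(0)
        ctv = rng.random(grid.shape) < 0.8
        rho = rng.uniform(0, 500, grid.shape) * ctv
        d = rng.uniform(1.5, 2.5, grid.shape)
        got = plan_tcp(rho, d, 0.15, params, ctv, grid)
        prod = 1.0
        for i in np.argwhere(ctv):
            prod *= voxel_tcp(rho[tuple(i)], grid.voxel_volume, 0.15, d[tuple(i)], params)
        assert got == pytest.approx(prod, rel=1e-12)

    def test_no_clonogens_gives_unity(self, params):
        grid = VoxelGrid(shape=(4, 4, 2))
        ctv = np.ones(grid.shape, bool)
        assert plan_tcp(np.zeros(grid.shape), np.full(grid.shape, 2.0), 0.15,
                        params, ctv, grid) == 1.0

    def test_population_tcp_is_convex_combination(self, params, alpha_dist):
        grid = VoxelGrid(shape=(6, 6, 4))
        rng = np.random.default_rng(1)
        ctv = np.ones(grid.shape, bool)
        rho = rng.uniform(0, 1000, grid.shape)
        d = rng.uniform(1.8, 2.2, grid.shape)
        per_alpha = [plan_tcp(rho, d, a, params, ctv, grid) for a in alpha_dist.alphas]
        got = population_tcp(rho, d, alpha_dist, params, ctv, grid)
        assert min(per_alpha) <= got <= max(per_alpha)
        assert got == pytest.approx(np.dot(alpha_dist.weights, per_alpha), rel=1e-12)

    def test_single_alpha_reduces_to_plan_tcp(self, params):
        grid = VoxelGrid(shape=(4, 4, 2))
        ctv = np.ones(grid.shape, bool)
        rho = np.full(grid.shape, 100.0)
        d = np.full(grid.shape, 2.0)
        ad = AlphaDistribution(np.array([0.15]), np.array([1.0]))
        assert population_tcp(rho, d, ad, params, ctv, grid) == pytest.approx(
            plan_tcp(rho, d, 0.15, params, ctv, grid), rel=1e-14
        )


class TestGEUD:
    def test_uniform_dose_any_a(self):
        for a in (1.0, 2.0, 6.0, 20.0):
            assert geud(np.full(100, 60.0), a) == pytest.approx(60.0)

    def test_two_voxel_closed_form(self):
        # {0, 78} Gy, a = 6: 78 * (1/2)^(1/6)
        assert geud(np.array([0.0, 78.0]), 6.0) == pytest.approx(78 * 0.5 ** (1 / 6), rel=1e-12)

    def test_a1_is_mean_and_monotone_in_a(self):
        rng = np.random.default_rng(2)
        doses = rng.uniform(0, 80, 200)
        assert geud(doses, 1.0) == pytest.approx(doses.mean())
        vals = [geud(doses, a) for a in (1, 2, 4, 8, 16)]
        assert np.all(np.diff(vals) >= 0)


class TestExpectations:
    def test_degenerate_uncertainty_reduces_exactly(self, params, alpha_dist, small_grid):
        ctv, rho, d = make_small_instance(small_grid, seed=3)
        ref = population_tcp(rho, d, alpha_dist, params, ctv, small_grid)
        got = expected_tcp(rho, d, alpha_dist, ZERO_ERROR, params, ctv, small_grid)
        assert got == pytest.approx(ref, abs=1e-10)
        D = params.n_fractions * d
        mask = ctv
        e_eud = expected_eud(D, mask, EUDParams(6.0), ZERO_ERROR, small_grid)
        assert e_eud == pytest.approx(geud(D[mask], 6.0), rel=1e-10)
        e_dose = expected_dose(D, ZERO_ERROR, mask, small_grid)
        assert np.allclose(e_dose[mask], D[mask], atol=1e-10)

    def test_translation_invariant_uniform_field(self, params, alpha_dist, error_model):
        grid = VoxelGrid(shape=(24, 24, 16))
        ctv = np.zeros(grid.shape, bool)
        ctv[9:15, 9:15, 6:10] = True
        rho = np.where(ctv, 300.0, 0.0)
        d = np.full(grid.shape, 2.0)
        ref = population_tcp(rho, d, alpha_dist, params, ctv, grid)
        got = expected_tcp(rho, d, alpha_dist, error_model, params, ctv, grid)
        assert got == pytest.approx(ref, rel=1e-6)

    def test_uniform_dose_expected_eud_unchanged(self, error_model):
        grid = VoxelGrid(shape=(24, 24, 16))
        mask = np.zeros(grid.shape, bool)
        mask[10:14, 10:14, 6:10] = True
        D = np.full(grid.shape, 60.0)
        assert expected_eud(D, mask, EUDParams(6.0), error_model, grid) == pytest.approx(
            60.0, rel=1e-9
        )

    def test_quadrature_matches_monte_carlo(self, params, alpha_dist, error_model, small_grid):
        """Systematic-shift quadrature vs direct Monte-Carlo sampling."""
        ctv, rho, d = make_small_instance(small_grid, seed=7)
        engine = ExpectationEngine(small_grid, ctv, error_model, 17, "grid")
        blurred = engine.blur(d)
        quad_tcp = expected_tcp(rho, d, alpha_dist, error_model, params, ctv,
                                small_grid, n_shift_nodes=17, shift_rule="grid")

        n_mc = 20000
        rng = np.random.default_rng(123)
        shifts = rng.normal(
            error_model.mean_xyz, error_model.sigma_sys_xyz, size=(n_mc, 3)
        )
        pts = small_grid.voxel_centers(ctv)
        rho_vec = rho[ctv]
        vals = np.empty(n_mc)
        # independent path: scipy map_coordinates + direct TCP formula
        for k in range(n_mc):
            idx = small_grid.world_to_index(pts + shifts[k]).T
            dk = ndimage.map_coordinates(blurred, idx, order=1, mode="grid-constant", cval=0.0)
            tcps = [
                np.exp(-(rho_vec * small_grid.voxel_volume * np.exp(
                    -a * params.n_fractions * dk * (1 + dk / params.alpha_beta)
                    + params.repopulation_log)).sum())
                for a in alpha_dist.alphas
            ]
            vals[k] = np.dot(alpha_dist.weights, tcps)
        mc_mean = vals.mean()
        mc_se = vals.std(ddof=1) / np.sqrt(n_mc)
        assert abs(quad_tcp - mc_mean) <= 3 * mc_se

    def test_expected_eud_matches_monte_carlo(self, params, error_model, small_grid):
        ctv, rho, d = make_small_instance(small_grid, seed=11)
        D = params.n_fractions * d
        a = 6.0
        quad = expected_eud(D, ctv, EUDParams(a), error_model, small_grid,
                            n_shift_nodes=17, shift_rule="grid")
        engine = ExpectationEngine(small_grid, ctv, error_model, 17, "grid")
        blurred = engine.blur(D)
        n_mc = 20000
        rng = np.random.default_rng(321)
        shifts = rng.normal(error_model.mean_xyz, error_model.sigma_sys_xyz, size=(n_mc, 3))
        pts = small_grid.voxel_centers(ctv)
        vals = np.empty(n_mc)
        for k in range(n_mc):
            idx = small_grid.world_to_index(pts + shifts[k]).T
            dk = ndimage.map_coordinates(blurred, idx, order=1, mode="grid-constant", cval=0.0)
            vals[k] = np.mean(dk**a) ** (1 / a)
        mc_se = vals.std(ddof=1) / np.sqrt(n_mc)
        assert abs(quad - vals.mean()) <= 3 * mc_se

    def test_tcp_monotone_in_dose_scale(self, params, alpha_dist, error_model, small_grid):
        """<TCP> strictly increases with a global dose scale (isoeffect basis)."""
        ctv, rho, d = make_small_instance(small_grid, seed=13)
        engine = ExpectationEngine(small_grid, ctv, error_model, 3)
        sampled = engine.sample_shifted(engine.blur(d))
        rho_vec = rho[ctv]
        scales = [0.6, 0.8, 1.0, 1.3, 1.7]
        vals = [
            engine.expected_tcp_from_sampled(rho_vec, s * sampled, alpha_dist, params)
            for s in scales
        ]
        assert np.all(np.diff(vals) > 0)

    def test_empty_mask_rejected(self, error_model, small_grid):
        with pytest.raises(ValueError):
            ExpectationEngine(small_grid, np.zeros(small_grid.shape, bool), error_model)
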