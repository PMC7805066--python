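"""Objective functions, analytic gradients and the two plan optimisers."""

import numpy as np
import pytest

from tcplan.dose import BeamGeometry, build_influence
from tcplan.grids import StructureSet, VoxelGrid
from tcplan.planning import (
    BiologicalObjective,
    ObjectiveSpec,
    OptimizerSettings,
    objective_value_and_gradient,
    optimize_biological,
    optimize_uniform,
    scale_to_isoeffect,
)
from tcplan.radiobiology import RadiobioParams, discretize_alpha
from tcplan.uncertainty import ErrorModel, PROSTATE_ERROR_PRESET, ZERO_ERROR


# ---------------------------------------------------------------------------
# small shared phantom + influence (module scope: built once)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_case():
    grid = VoxelGrid(shape=(24, 24, 12), spacing=(2.0, 2.0, 2.5))
    xx, yy, zz = grid.coordinates()
    c = grid.center
    external = (((xx - c[0]) / 21) ** 2 + ((yy - c[1]) / 21) ** 2) <= 1.0
    ctv = (
        ((xx - c[0]) / 8) ** 2 + ((yy - c[1]) / 8) ** 2 + ((zz - c[2]) / 5) ** 2
    ) <= 1.0
    empty = np.zeros(grid.shape, dtype=bool)
    rectum = empty.copy(); rectum[10:14, 17:20, 4:8] = True
    bladder = empty.copy(); bladder[10:14, 4:7, 4:8] = True
    hof_l = empty.copy(); hof_l[3:5, 10:14, 4:8] = True
    hof_r = empty.copy(); hof_r[19:21, 10:14, 4:8] = True
    structs = StructureSet(grid, {
        "ctv": ctv, "rectum": rectum, "bladder": bladder,
        "hof_left": hof_l, "hof_right": hof_r, "external": external,
    })
    from tcplan.uncertainty import expand_ctv

    ptv = expand_ctv(ctv, PROSTATE_ERROR_PRESET.margins_xyz, grid, external)
    structs = structs.with_mask("ptv", ptv)
    geo = BeamGeometry(gantry_angles_deg=(0.0, 90.0, 180.0, 270.0))
    infl = build_influence(grid, structs, geo)
    params = RadiobioParams()
    rho = np.zeros(grid.shape)
    rho[ctv] = 500.0
    rho[10:13, 10:13, 5:7] = 5000.0  # focal lesion
    rho[~ctv] = 0.0
    return grid, structs, infl, params, rho


# ---------------------------------------------------------------------------
# objective values and gradients
# ---------------------------------------------------------------------------

class TestObjectives:
    IDX = {"s": np.arange(10)}

    def test_square_deviation_zero_at_reference(self):
        spec = (ObjectiveSpec("s", "square_deviation", d_ref=78.0),)
        val, grad = objective_value_and_gradient(spec, np.full(10, 78.0), self.IDX)
        assert val == 0.0
        assert np.all(grad == 0)

    def test_square_overdose_inactive_below_reference(self):
        spec = (ObjectiveSpec("s", "square_overdose", d_ref=70.0),)
        val, grad = objective_value_and_gradient(spec, np.full(10, 60.0), self.IDX)
        assert val == 0.0 and np.all(grad == 0)

    def test_dose_volume_rank_selection(self):
        """10 voxels, 6 above 50 Gy, 50% allowed: exactly 1 (lowest excess)."""
        dose = np.array([30, 40, 45, 48, 51, 55, 60, 65, 70, 75], dtype=float)
        spec = (ObjectiveSpec("s", "dose_volume", d_ref=50.0, v_ref=50.0),)
        val, grad = objective_value_and_gradient(spec, dose, self.IDX)
        # brute-force oracle: sort the 6 voxels above 50 descending, spare
        # the top 5, penalise the remainder
        above = sorted([v for v in dose if v > 50], reverse=True)
        expected = sum((v - 50) ** 2 for v in above[5:]) / dose.size
        assert val == pytest.approx(expected)
        assert np.count_nonzero(grad) == 1
        assert grad[4] == pytest.approx(2 * (51 - 50) / 10)  # the 51 Gy voxel

    def test_unknown_structure_rejected(self):
        with pytest.raises(KeyError):
            objective_value_and_gradient(
                (ObjectiveSpec("nope", "square_overdose", d_ref=1.0),),
                np.zeros(10), self.IDX,
            )

    @pytest.mark.parametrize("kind,vref", [
        ("square_deviation", None),
        ("square_overdose", None),
        ("square_underdose", None),
        ("dose_volume", 40.0),
    ])
    def test_gradients_match_finite_differences(self, kind, vref):
        rng = np.random.default_rng(5)
        dose = rng.uniform(20, 90, 30)
        idx = {"s": np.arange(30)}
        spec = (ObjectiveSpec("s", kind, d_ref=55.0, v_ref=vref),)
        val, grad = objective_value_and_gradient(spec, dose, idx)
        eps = 1e-6
        for i in range(0, 30, 7):
            dp, dm = dose.copy(), dose.copy()
            dp[i] += eps
            dm[i] -= eps
            fd = (
                objective_value_and_gradient(spec, dp, idx)[0]
                - objective_value_and_gradient(spec, dm, idx)[0]
            ) / (2 * eps)
            assert grad[i] == pytest.approx(fd, abs=1e-6)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveSpec("s", "bogus", d_ref=10.0)
        with pytest.raises(ValueError):
            ObjectiveSpec("s", "dose_volume", d_ref=10.0, v_ref=0.0)
        with pytest.raises(ValueError):
            ObjectiveSpec("s", "square_deviation", d_ref=-1.0)


# ---------------------------------------------------------------------------
# biological objective gradient through blur + shifts + influence
# ---------------------------------------------------------------------------

def test_biological_gradient_matches_finite_differences(toy_case):
    """-ln<TCP> + OAR gradient vs central differences on a 50-beamlet subset."""
    grid, structs, infl, params, rho = toy_case
    ad = discretize_alpha(p=5)
    em = ErrorModel(mean=(0.5, -0.3, 0.2), sigma_sys=(2.0, 2.0, 2.0),
                    sigma_rand=(1.0, 1.0, 1.0))
    oar = (
        ObjectiveSpec("rectum", "square_overdose", d_ref=30.0, weight=0.1),
        ObjectiveSpec("ctv", "square_underdose", d_ref=78.0, weight=0.5),
    )
    obj = BiologicalObjective(infl, structs, rho, ad, em, params, oar,
                              n_shift_nodes=3)
    rng = np.random.default_rng(11)
    w0 = np.full(infl.n_beamlets, params.prescription_gy / params.n_fractions / 4.0)
    w0 *= rng.uniform(0.5, 1.5, w0.size)
    val, grad = obj(w0)
    eps = 1e-6
    cols = rng.choice(infl.n_beamlets, size=12, replace=False)
    for i in cols:
        wp, wm = w0.copy(), w0.copy()
        wp[i] += eps
        wm[i] -= eps
        fd = (obj(wp)[0] - obj(wm)[0]) / (2 * eps)
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-9)


def test_uniform_objective_gradient_through_influence(toy_case):
    grid, structs, infl, params, rho = toy_case
    from tcplan.planning import _structure_indices

    indices = _structure_indices(structs)
    specs = (
        ObjectiveSpec("ptv", "square_deviation", d_ref=78.0, weight=10.0),
        ObjectiveSpec("rectum", "dose_volume", d_ref=30.0, v_ref=40.0, weight=5.0),
    )
    n = params.n_fractions
    A = infl.matrix

    def f(w):
        D = n * (A @ w)
        val, g = objective_value_and_gradient(specs, D, indices)
        return val, n * (A.T @ g)

    rng = np.random.default_rng(3)
    w0 = rng.uniform(0.01, 0.08, infl.n_beamlets)
    val, grad = f(w0)
    eps = 1e-7
    for i in rng.choice(infl.n_beamlets, size=10, replace=False):
        wp, wm = w0.copy(), w0.copy()
        wp[i] += eps
        wm[i] -= eps
        fd = (f(wp)[0] - f(wm)[0]) / (2 * eps)
        assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


# ---------------------------------------------------------------------------
# optimisers
# ---------------------------------------------------------------------------

def test_optimize_uniform_single_voxel_quadratic():
    """One beamlet, one-voxel target: w converges to D_ref/(n * a_ii)."""
    grid = VoxelGrid(shape=(12, 12, 6))
    xx, yy, zz = grid.coordinates()
    c = grid.center
    external = (((xx - c[0]) / 11) ** 2 + ((yy - c[1]) / 11) ** 2) <= 1.0
    ctv = np.zeros(grid.shape, dtype=bool)
    ctv[6, 6, 3] = True
    empty = np.zeros(grid.shape, dtype=bool)
    others = {}
    for i, name in enumerate(("rectum", "bladder", "hof_left", "hof_right")):
        m = empty.copy(); m[2 + i, 6, 3] = True
        others[name] = m
    structs = StructureSet(grid, {"ctv": ctv, "external": external, **others})
    structs = structs.with_mask("ptv", ctv)
    infl = build_influence(grid, structs, BeamGeometry(gantry_angles_deg=(0.0,),
                                                       beamlet_width_mm=24.0))
    params = RadiobioParams()
    specs = (ObjectiveSpec("ctv", "square_deviation", d_ref=78.0, weight=1.0),)
    plan = optimize_uniform(infl, structs, params, specs=specs)
    D = params.n_fractions * infl.dose_per_fraction(plan.weights)
    assert D[6, 6, 3] == pytest.approx(78.0, rel=1e-4)


def test_optimize_uniform_symmetric_beams_symmetric_dose():
    """Mirror-symmetric phantom and beams give a mirror-symmetric dose.

    Run to tight convergence on a small instance: the optimal dose of the
    strictly convex (in dose) objective is unique and symmetric even
    though the beamlet weights are not.
    """
    grid = VoxelGrid(shape=(16, 16, 8), spacing=(2.0, 2.0, 2.5))
    xx, yy, zz = grid.coordinates()
    c = grid.center
    external = (((xx - c[0]) / 14) ** 2 + ((yy - c[1]) / 14) ** 2) <= 1.0
    ctv = (
        ((xx - c[0]) / 6) ** 2 + ((yy - c[1]) / 6) ** 2 + ((zz - c[2]) / 5) ** 2
    ) <= 1.0
    empty = np.zeros(grid.shape, dtype=bool)
    organs = {}
    for i, name in enumerate(("rectum", "bladder", "hof_left", "hof_right")):
        m = empty.copy(); m[7 + (i % 2), 1 + i, 3] = True
        organs[name] = m
    structs = StructureSet(grid, {"ctv": ctv, "external": external, **organs})
    structs = structs.with_mask("ptv", ctv)
    # coarse, well-separated beamlets keep the problem well-conditioned so
    # the optimiser converges to the unique CTV dose
    from tcplan.dose import EngineParams

    infl = build_influence(
        grid, structs,
        BeamGeometry(gantry_angles_deg=(0.0, 180.0), beamlet_width_mm=5.0),
        EngineParams(penumbra_sd_mm=2.0),
    )
    params = RadiobioParams()
    specs = (ObjectiveSpec("ctv", "square_deviation", d_ref=78.0, weight=1.0),)
    plan = optimize_uniform(
        infl, structs, params, specs=specs,
        settings=OptimizerSettings(max_iter=30000, ftol=1e-18, gtol=1e-14),
    )
    d = infl.dose_per_fraction(plan.weights)
    # the objective sees only the CTV, where its optimum is unique (and
    # hence symmetric); off-target dose is not determined by the optimum
    mirrored = d[::-1, :, :]
    assert np.abs((d - mirrored)[structs["ctv"]]).max() <= 1e-4 * d[structs["ctv"]].max()


def test_optimize_uniform_deterministic_replay(toy_case):
    grid, structs, infl, params, rho = toy_case
    s = OptimizerSettings(max_iter=60)
    p1 = optimize_uniform(infl, structs, params, settings=s)
    p2 = optimize_uniform(infl, structs, params, settings=s)
    assert np.array_equal(p1.weights, p2.weights)


def test_optimize_biological_concentrates_on_lesion(toy_case):
    """With no OAR terms, dose concentrates where the clonogens are.

    A narrow penumbra keeps beamlet spill small enough to resolve the
    concentration within the small test CTV.
    """
    grid, structs, infl, params, _ = toy_case
    from tcplan.dose import EngineParams

    sharp = build_influence(
        grid, structs, BeamGeometry(gantry_angles_deg=(0.0, 90.0, 180.0, 270.0)),
        EngineParams(penumbra_sd_mm=1.5),
    )
    ctv = structs["ctv"]
    rho = np.zeros(grid.shape)
    rho[13, 13, 5] = 2e4  # single hot voxel off-centre inside the CTV
    ad = discretize_alpha(p=3)
    plan = optimize_biological(
        sharp, structs, rho, ad, ZERO_ERROR, params, oar_specs=(),
        settings=OptimizerSettings(max_iter=150, n_shift_nodes=1),
    )
    D = params.n_fractions * sharp.dose_per_fraction(plan.weights)
    assert D[13, 13, 5] > 2.0 * np.median(D[ctv])


def test_optimize_biological_uniform_rho_near_uniform_dose(toy_case):
    """Uniform clonogens, no uncertainty, no OARs: CTV dose near-uniform."""
    grid, structs, infl, params, _ = toy_case
    ctv = structs["ctv"]
    rho = np.where(ctv, 1000.0, 0.0)
    ad = discretize_alpha(p=3)
    # a symmetric soft cap keeps the optimum interior (away from TCP
    # saturation, where the dose shape is no longer determined)
    cap = (ObjectiveSpec("ctv", "square_overdose", d_ref=80.0, weight=0.05),)
    plan = optimize_biological(
        infl, structs, rho, ad, ZERO_ERROR, params, oar_specs=cap,
        settings=OptimizerSettings(max_iter=1000, n_shift_nodes=1),
    )
    D = params.n_fractions * infl.dose_per_fraction(plan.weights)
    cov = D[ctv].std() / D[ctv].mean()
    assert cov < 0.05


def test_biological_more_dose_efficient_than_uniform(toy_case):
    """Shaping dose to the clonogen map reaches the same <TCP> with less
    mean CTV dose than the uniform plan (optimality spot-check)."""
    grid, structs, infl, params, rho = toy_case
    ad = discretize_alpha(p=5)
    em = PROSTATE_ERROR_PRESET
    settings = OptimizerSettings(max_iter=300, n_shift_nodes=3)
    plan_a = optimize_uniform(infl, structs, params, settings=settings)
    cap = (ObjectiveSpec("ctv", "square_overdose", d_ref=85.0, weight=0.05),)
    plan_b = optimize_biological(infl, structs, rho, ad, em, params,
                                 oar_specs=cap, settings=settings)
    ctv = structs["ctv"]
    a95, _ = scale_to_isoeffect(plan_a, rho, ad, em, params, ctv, n_shift_nodes=3)
    b95, _ = scale_to_isoeffect(plan_b, rho, ad, em, params, ctv, n_shift_nodes=3)
    mean_a = infl.dose_per_fraction(a95.weights)[ctv].mean()
    mean_b = infl.dose_per_fraction(b95.weights)[ctv].mean()
    assert mean_b < mean_a


# ---------------------------------------------------------------------------
# isoeffect scaling
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scaled_setup(toy_case):
    grid, structs, infl, params, rho = toy_case
    ad = discretize_alpha(p=5)
    em = PROSTATE_ERROR_PRESET
    plan = optimize_uniform(infl, structs, params,
                            settings=OptimizerSettings(max_iter=150))
    return grid, structs, infl, params, rho, ad, em, plan


class TestIsoeffect:
    def test_bisection_hits_target(self, scaled_setup):
        grid, structs, infl, params, rho, ad, em, plan = scaled_setup
        scaled, s = scale_to_isoeffect(plan, rho, ad, em, params, structs["ctv"])
        obj = BiologicalObjective(infl, structs, rho, ad, em, params, (), 5)
        assert abs(obj.expected_tcp_of(scaled.weights) - 0.95) <= 1e-4

    def test_already_at_target_returns_unity(self, scaled_setup):
        grid, structs, infl, params, rho, ad, em, plan = scaled_setup
        scaled, _ = scale_to_isoeffect(plan, rho, ad, em, params, structs["ctv"])
        _, s2 = scale_to_isoeffect(scaled, rho, ad, em, params, structs["ctv"])
        assert s2 == pytest.approx(1.0, abs=0.02)

    def test_matches_fine_grid_search(self, scaled_setup):
        grid, structs, infl, params, rho, ad, em, plan = scaled_setup
        _, s_bis = scale_to_isoeffect(plan, rho, ad, em, params, structs["ctv"])
        from tcplan.radiobiology import ExpectationEngine

        engine = ExpectationEngine(grid, structs["ctv"], em, 5)
        d = infl.dose_per_fraction(plan.weights)
        sampled = engine.sample_shifted(engine.blur(d))
        rho_vec = rho[structs["ctv"]]
        # 1e-6-resolution local grid search around the bisection answer
        ss = np.arange(s_bis - 5e-4, s_bis + 5e-4, 1e-6)
        tcps = np.array([
            engine.expected_tcp_from_sampled(rho_vec, s * sampled, ad, params)
            for s in ss
        ])
        s_grid = ss[np.argmin(np.abs(tcps - 0.95))]
        tcp_bis = engine.expected_tcp_from_sampled(rho_vec, s_bis * sampled, ad, params)
        tcp_grid = engine.expected_tcp_from_sampled(rho_vec, s_grid * sampled, ad, params)
        # both sit inside the same +-1e-4 <TCP> tolerance band
        assert abs(tcp_bis - 0.95) <= 1e-4
        assert abs(tcp_bis - tcp_grid) <= 2e-4

    def test_halving_clonogens_reduces_required_scale(self, scaled_setup):
        grid, structs, infl, params, rho, ad, em, plan = scaled_setup
        _, s_full = scale_to_isoeffect(plan, rho, ad, em, params, structs["ctv"])
        _, s_half = scale_to_isoeffect(plan, 0.5 * rho, ad, em, params, structs["ctv"])
        assert s_half < s_full

    def test_unreachable_target_raises(self, scaled_setup):
        grid, structs, infl, params, rho, ad, em, plan = scaled_setup
        tiny = plan.scaled(1e-6)
        with pytest.raises(ValueError, match="unreachable"):
            scale_to_isoeffect(tiny, rho, ad, em, params, structs["ctv"],
                               bracket=(0.5, 1.5))
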