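"""Estimation machinery: objectives, pattern search, ensembles, structures."""

import numpy as np
import pytest
from scipy import optimize

import il21pkpd as il
from il21pkpd.calibration import (
    EnsembleIncompleteError,
    FitResult,
    EnsembleFit,
    TimeSeriesDataset,
    compare_structures,
    hooke_jeeves,
    lhs_starts,
    multi_start_fit,
    prediction_consistency,
    r_squared,
    sse_objective,
)
from il21pkpd.pk import PKParams, PKTopology


def _dataset(times, mean):
    times = np.asarray(times, float)
    return TimeSeriesDataset(times, np.asarray(mean, float),
                             np.zeros(len(times)), np.full(len(times), 6))


class TestSSEObjective:
    def test_perfect_prediction_gives_zero(self):
        ds = _dataset([1, 2, 3], [4, 5, 6])
        assert sse_objective(None, ds, lambda p: np.array([4.0, 5.0, 6.0])) == 0.0

    def test_single_point_squared_residual(self):
        ds = _dataset([1], [1.0])
        assert sse_objective(None, ds, lambda p: np.array([3.0])) == 4.0

    def test_additive_over_datasets(self):
        d1, d2 = _dataset([1], [0.0]), _dataset([1], [0.0])
        f = lambda p: [np.array([1.0]), np.array([2.0])]
        assert sse_objective(None, [d1, d2], f) == pytest.approx(5.0)

    def test_simulation_failure_returns_finite_penalty(self):
        ds = _dataset([1], [0.0])

        def boom(p):
            raise RuntimeError("solver blew up")

        val = sse_objective(None, ds, boom)
        assert np.isfinite(val) and val > 1e9


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_computed_case(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2, 2, 2], [1, 2, 3])


class TestHookeJeeves:
    def test_quadratic_minimum(self):
        fit = hooke_jeeves(lambda x: (x[0] - 3.0) ** 2, [0.0], [1.0],
                           [(-10, 10)], tol=1e-10)
        assert fit.params[0] == pytest.approx(3.0, abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-10)

    def test_rosenbrock_reaches_global_minimum(self):
        rosen = lambda x: (1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2
        fit = hooke_jeeves(rosen, [-1.2, 1.0], [0.5, 0.5],
                           [(-5, 5), (-5, 5)], tol=1e-12, max_evals=60000)
        assert np.allclose(fit.params, [1.0, 1.0], atol=1e-3)

    def test_constrained_optimum_on_boundary(self):
        fit = hooke_jeeves(lambda x: (x[0] - 3.0) ** 2, [0.5], [0.25],
                           [(0.0, 1.0)], tol=1e-10)
        assert fit.params[0] == pytest.approx(1.0)

    def test_never_worse_than_start_and_inside_bounds(self):
        f = lambda x: np.sin(5 * x[0]) + 0.1 * x[0] ** 2
        fit = hooke_jeeves(f, [2.0], [0.7], [(-4, 4)], tol=1e-8)
        assert fit.sse <= f(np.array([2.0]))
        assert -4 <= fit.params[0] <= 4

    def test_matches_scipy_on_smooth_bowl(self):
        """Independent oracle: Nelder-Mead on the same 3-D bowl."""
        A = np.array([[3.0, 0.5, 0.0], [0.5, 2.0, 0.3], [0.0, 0.3, 1.5]])
        b = np.array([1.0, -2.0, 0.5])
        f = lambda x: float(np.asarray(x) @ A @ np.asarray(x) + b @ np.asarray(x))
        ref = optimize.minimize(f, [0, 0, 0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12}).x
        fit = hooke_jeeves(f, [0.0, 0.0, 0.0], [0.5] * 3, [(-5, 5)] * 3,
                           tol=1e-10, max_evals=20000)
        assert np.allclose(fit.params, ref, atol=1e-4)

    def test_non_finite_start_rejected(self):
        with pytest.raises(ValueError):
            hooke_jeeves(lambda x: float("nan"), [0.0], [0.1], [(-1, 1)])


class TestMultiStart:
    def test_convex_problem_all_sets_agree(self):
        f = lambda x: float((x[0] - 0.3) ** 2 + (x[1] + 0.2) ** 2)
        ens = multi_start_fit(f, lambda rng, k: lhs_starts([(-2, 2)] * 2, k, rng),
                              n_sets=10, seed=3, bounds=[(-2, 2)] * 2,
                              tol=1e-10, max_evals=4000)
        assert len(ens.fits) == 10
        spread = ens.param_matrix.max(axis=0) - ens.param_matrix.min(axis=0)
        assert spread.max() < 1e-4

    def test_same_seed_reproduces_ensemble(self):
        f = lambda x: float((x[0] - 0.3) ** 2)
        kw = dict(n_sets=5, seed=11, bounds=[(-2, 2)], tol=1e-10, max_evals=500)
        a = multi_start_fit(f, lambda rng, k: lhs_starts([(-2, 2)], k, rng), **kw)
        b = multi_start_fit(f, lambda rng, k: lhs_starts([(-2, 2)], k, rng), **kw)
        assert np.array_equal(a.param_matrix, b.param_matrix)

    def test_multimodal_objective_finds_both_basins(self):
        # two separated basins of equal depth at x = -1 and x = +1
        f = lambda x: float(min((x[0] + 1) ** 2, (x[0] - 1) ** 2))
        ens = multi_start_fit(f, lambda rng, k: lhs_starts([(-3, 3)], k, rng),
                              n_sets=10, seed=7, bounds=[(-3, 3)],
                              tol=1e-10, max_evals=500)
        found = np.round(ens.param_matrix[:, 0]).astype(int)
        assert {-1, 1} <= set(found)

    def test_incomplete_ensemble_raises(self):
        def f(x):
            raise ValueError("never evaluable")

        with pytest.raises(EnsembleIncompleteError):
            multi_start_fit(f, lambda rng, k: lhs_starts([(-1, 1)], k, rng),
                            n_sets=5, seed=1, bounds=[(-1, 1)], max_evals=50)


class TestPredictionConsistency:
    def _ens(self, vectors):
        return EnsembleFit([FitResult(np.asarray(v, float), 0.0) for v in vectors])

    def test_identical_sets_score_zero_and_accept(self):
        ens = self._ens([[1.0, 2.0]] * 10)
        score, ok = prediction_consistency(
            ens, ["probe"], lambda p, probe: p, tolerance=0.1)
        assert score == 0.0 and ok

    def test_divergent_set_rejected(self):
        ens = self._ens([[1.0]] * 9 + [[10.0]])
        score, ok = prediction_consistency(
            ens, ["probe"], lambda p, probe: p, tolerance=0.1)
        assert score > 0.1 and not ok

    def test_infinite_tolerance_always_accepts(self):
        ens = self._ens([[1.0], [100.0]])
        _, ok = prediction_consistency(ens, ["probe"], lambda p, probe: p,
                                       tolerance=float("inf"))
        assert ok

    def test_needs_two_fits_and_one_probe(self):
        with pytest.raises(ValueError):
            prediction_consistency(self._ens([[1.0]]), ["p"], lambda p, probe: p)
        with pytest.raises(ValueError):
            prediction_consistency(self._ens([[1.0], [1.0]]), [],
                                   lambda p, probe: p)


@pytest.fixture(scope="module")
def iv_profile():
    """Bi-phasic serum profile generated from the full bidirectional IV
    structure (strong distribution into, and slow return from, the
    secondary tissues)."""
    topo = il.iv_topology()
    par = il.default_pk_params("IV")
    par.w = {("plasma", "sec1"): 8.0, ("sec1", "plasma"): 0.8,
             ("plasma", "sec2"): 3.0, ("sec2", "plasma"): 0.5,
             ("plasma", "sec3"): 1.0, ("sec3", "plasma"): 0.3}
    par.alpha = {t: 0.0 for t in par.w}
    par.d = {"plasma": 6.0, "sec1": 0.2, "sec2": 0.2, "sec3": 0.2}
    par.beta = {c: 0.0 for c in par.d}
    times = np.array([0.02, 0.05, 0.1, 0.2, 0.35, 0.6, 1.0, 1.5, 2.0, 3.0])
    traj = il.simulate_single_dose(topo, par, 50.0, 3.2, dt=0.002)
    return TimeSeriesDataset(times, traj.at(times, traj.plasma_conc),
                             np.zeros(len(times)), np.full(len(times), 6))


class TestCompareStructures:
    def test_generating_structure_ranked_first(self, iv_profile):
        full = il.iv_topology()
        # degenerate alternative: one-way flow into the secondary tissues
        oneway = PKTopology("IV", full.compartments,
                            tuple(t for t in full.transitions
                                  if t[0] == "plasma"),
                            full.degradations)

        def init(topo):
            par = il.default_pk_params("IV")
            par.w = {t: 2.0 for t in topo.transitions}
            par.alpha = {t: 0.0 for t in topo.transitions}
            par.d = {c: 2.0 for c in topo.degradations}
            par.beta = {c: 0.0 for c in topo.degradations}
            return par

        ranked = compare_structures([oneway, full], iv_profile, 50.0, init,
                                    n_sets=4, seed=5, dt=0.005, max_evals=400)
        assert ranked[0].topology == full
        assert ranked[0].sse < ranked[1].sse

    def test_single_candidate_trivially_selected(self, iv_profile):
        full = il.iv_topology()

        def init(topo):
            return il.default_pk_params("IV")

        ranked = compare_structures([full], iv_profile, 50.0, init,
                                    n_sets=3, seed=5, dt=0.005, max_evals=200)
        assert len(ranked) == 1 and ranked[0].topology == full
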