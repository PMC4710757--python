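import numpy as np
import pytest

from ionfit import PSOConfig, hybrid_run, pso_run, two_stage_run
from ionfit.hybrid import HYBRID_SETUPS, HybridSetup, final_refine, get_setup
from ionfit.trr import TRRConfig

from test_pso import _Box


class Paraboloid:
    """Convex toy: sum((p - target)^2) with residual interface."""

    def __init__(self, target):
        self.target = np.asarray(target, dtype=float)

    def residuals(self, p):
        return np.asarray(p, dtype=float) - self.target

    def sse_cost(self, p):
        r = self.residuals(p)
        return float(r @ r)


class TestSetups:
    def test_reference_budgets(self):
        assert (HYBRID_SETUPS["low"].inner_trr_iterations,
                HYBRID_SETUPS["low"].n_iterations,
                HYBRID_SETUPS["low"].n_particles) == (5, 250, 96)
        assert (HYBRID_SETUPS["medium"].inner_trr_iterations,
                HYBRID_SETUPS["medium"].n_iterations,
                HYBRID_SETUPS["medium"].n_particles) == (10, 500, 192)
        assert (HYBRID_SETUPS["high"].inner_trr_iterations,
                HYBRID_SETUPS["high"].n_iterations,
                HYBRID_SETUPS["high"].n_particles) == (20, 1000, 384)
        assert all(s.refine_count <= s.n_particles for s in HYBRID_SETUPS.values())

    def test_invalid_setups_rejected(self):
        with pytest.raises(ValueError):
            HybridSetup("bad", 5, 0, 24)
        with pytest.raises(ValueError):
            HybridSetup("bad", 5, 10, 24, refine_count=25)
        with pytest.raises(KeyError):
            get_setup("enormous")


class TestTwoStage:
    def test_convex_toy_all_refinements_reach_optimum(self):
        obj = Paraboloid([3.0])
        space = _Box([-10.0], [10.0])
        res = two_stage_run(obj, space, PSOConfig(24, 50, seed=2), M=3)
        assert res.best_cost < 1e-18
        assert np.all(res.ranked_costs[:3] < 1e-12)
        assert res.algorithm == "two_stage"

    def test_seeded_determinism(self):
        obj = Paraboloid([1.0, -2.0])
        space = _Box([-5.0, -5.0], [5.0, 5.0])
        a = two_stage_run(obj, space, PSOConfig(8, 10, seed=4), M=2)
        b = two_stage_run(obj, space, PSOConfig(8, 10, seed=4), M=2)
        assert np.array_equal(a.best_params, b.best_params)
        assert a.best_cost == b.best_cost

    def test_refinement_improves_on_pso_stage(self):
        obj = Paraboloid([1.0, -2.0])
        space = _Box([-5.0, -5.0], [5.0, 5.0])
        res = two_stage_run(obj, space, PSOConfig(12, 15, seed=9), M=4)
        assert res.best_cost <= res.termination["pso_best_cost"]


class TestHybrid:
    def test_k0_degenerates_to_pure_pso(self):
        obj = Paraboloid([2.0, 2.0])
        space = _Box([-5.0, -5.0], [5.0, 5.0])
        setup = HybridSetup("k0", 0, 25, 12, refine_count=4)
        hy = hybrid_run(obj, space, setup=setup, seed=13, final_trr=False)
        ps = pso_run(obj, space, PSOConfig(12, 25, seed=13))
        assert np.array_equal(hy.trace["gbest_cost"], ps.trace["gbest_cost"])
        assert np.array_equal(hy.best_params, ps.best_params)

    def test_inner_refinement_accelerates_convergence(self):
        obj = Paraboloid([2.0, -1.0, 0.5])
        space = _Box([-5.0] * 3, [5.0] * 3)
        setup = HybridSetup("fast", 3, 5, 6, refine_count=2)
        hy = hybrid_run(obj, space, setup=setup, seed=1, final_trr=False)
        ps = pso_run(obj, space, PSOConfig(6, 5, seed=1))
        assert hy.best_cost < ps.best_cost

    def test_global_best_monotone(self):
        obj = Paraboloid([0.0, 0.0])
        space = _Box([-5.0, -5.0], [5.0, 5.0])
        setup = HybridSetup("m", 2, 10, 6, refine_count=2)
        res = hybrid_run(obj, space, setup=setup, seed=3)
        g = res.trace["gbest_cost"].to_numpy()
        assert np.all(np.diff(g) <= 0)

    def test_seeded_determinism(self):
        obj = Paraboloid([2.0])
        space = _Box([-5.0], [5.0])
        setup = HybridSetup("d", 2, 8, 4, refine_count=2)
        a = hybrid_run(obj, space, setup=setup, seed=21)
        b = hybrid_run(obj, space, setup=setup, seed=21)
        assert np.array_equal(a.best_params, b.best_params)
        assert a.best_cost == b.best_cost


class TestFinalRefine:
    def test_already_converged_input_unchanged(self):
        obj = Paraboloid([1.5])
        space = _Box([-5.0], [5.0])
        params = np.array([[1.5], [1.4]])
        costs = np.array([obj.sse_cost(params[0]), obj.sse_cost(params[1])])
        out_p, out_c, reasons, delta = final_refine(obj, params, costs, space, M=2)
        assert out_c[0] <= 1e-20
        assert delta == 0.0  # best entry was already at the optimum
        assert all(r in ("pTol", "fTol") for r in reasons)

    def test_refinement_never_worsens_best(self):
        obj = Paraboloid([1.0, 2.0])
        space = _Box([-5.0, -5.0], [5.0, 5.0])
        rng = np.random.default_rng(8)
        params = space.sample(rng, 6)
        costs = np.array([obj.sse_cost(p) for p in params])
        order = np.argsort(costs)
        out_p, out_c, _, delta = final_refine(
            obj, params[order], costs[order], space, M=4
        )
        assert out_c[0] <= costs.min()
        assert 0.0 <= delta <= 1.0
        assert np.all(np.diff(out_c) >= 0)

    def test_empty_input_rejected(self):
        obj = Paraboloid([0.0])
        with pytest.raises(ValueError):
            final_refine(obj, np.empty((0, 1)), np.empty(0), _Box([-1.0], [1.0]), M=1)
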