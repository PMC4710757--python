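import numpy as np
import pytest

from ionfit import TRRConfig, trr_minimize, trr_step_limited

from test_pso import _Box


def linear_residual(p):
    return np.atleast_1d(p[0] - 3.0)


def rosenbrock_residuals(p):
    return np.array([1.0 - p[0], 10.0 * (p[1] - p[0] ** 2)])


class TestTrrMinimize:
    def test_linear_least_squares(self):
        res = trr_minimize(linear_residual, np.zeros(1), _Box([-10.0], [10.0]))
        assert res.x[0] == pytest.approx(3.0, abs=1e-8)
        assert res.cost < 1e-16
        assert res.iterations < 20

    def test_rosenbrock_global_optimum(self):
        res = trr_minimize(
            rosenbrock_residuals, np.array([-1.2, 1.0]), _Box([-5.0, -5.0], [5.0, 5.0])
        )
        assert np.allclose(res.x, [1.0, 1.0], atol=1e-6)
        assert res.termination_reason in ("pTol", "fTol")

    def test_descent_and_feasibility(self):
        space = _Box([-5.0, -5.0], [5.0, 5.0])
        rng = np.random.default_rng(0)
        for _ in range(5):
            p0 = space.sample(rng)
            res = trr_minimize(rosenbrock_residuals, p0, space)
            assert res.cost <= res.initial_cost
            assert np.all(res.x >= space.lower) and np.all(res.x <= space.upper)

    def test_active_bound_respected(self):
        # optimum at 3 lies outside the box; solver must stop at the bound
        res = trr_minimize(linear_residual, np.zeros(1), _Box([-1.0], [1.0]))
        assert res.x[0] == pytest.approx(1.0, abs=1e-8)

    def test_start_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            trr_minimize(linear_residual, np.array([20.0]), _Box([-10.0], [10.0]))

    def test_nonfinite_start_residuals_rejected(self):
        def bad(p):
            return np.array([np.nan])

        with pytest.raises(ValueError):
            trr_minimize(bad, np.zeros(1), _Box([-10.0], [10.0]))

    def test_budget_exhaustion_reported(self):
        cfg = TRRConfig(max_iter=1, max_fun_eval=500)
        res = trr_minimize(
            rosenbrock_residuals, np.array([-1.2, 1.0]), _Box([-5.0, -5.0], [5.0, 5.0]), cfg
        )
        assert res.termination_reason == "maxIter"
        cfg = TRRConfig(max_iter=100000, max_fun_eval=2)
        res = trr_minimize(
            rosenbrock_residuals, np.array([-1.2, 1.0]), _Box([-5.0, -5.0], [5.0, 5.0]), cfg
        )
        assert res.termination_reason == "maxFunEval"

    def test_mid_run_failures_do_not_abort(self):
        # residuals undefined on part of the box: solver retreats instead of
        # crashing (failed points scored with a huge cost)
        def partial(p):
            if p[0] > 3.5:
                raise RuntimeError("outside model domain")
            return np.atleast_1d(np.exp(p[0]) - np.exp(3.0))

        res = trr_minimize(partial, np.zeros(1), _Box([-10.0], [10.0]))
        assert res.x[0] == pytest.approx(3.0, abs=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TRRConfig(f_tol=0.0)
        with pytest.raises(ValueError):
            TRRConfig(iteration_cap=0)


class TestStepLimited:
    def test_large_cap_reaches_convergence(self):
        res = trr_step_limited(linear_residual, np.zeros(1), _Box([-10.0], [10.0]), K=1000)
        assert res.x[0] == pytest.approx(3.0, abs=1e-8)

    def test_single_iteration_never_increases_cost(self):
        space = _Box([-5.0, -5.0], [5.0, 5.0])
        rng = np.random.default_rng(1)
        for _ in range(10):
            p0 = space.sample(rng)
            res = trr_step_limited(rosenbrock_residuals, p0, space, K=1)
            assert res.cost <= res.initial_cost
            assert np.all((res.x >= space.lower) & (res.x <= space.upper))

    def test_more_iterations_make_more_progress(self):
        space = _Box([-5.0, -5.0], [5.0, 5.0])
        p0 = np.array([-1.2, 1.0])
        c1 = trr_step_limited(rosenbrock_residuals, p0, space, K=1).cost
        c5 = trr_step_limited(rosenbrock_residuals, p0, space, K=5).cost
        assert c5 < c1

    def test_cap_reason_reported(self):
        res = trr_step_limited(rosenbrock_residuals, np.array([-1.2, 1.0]),
                               _Box([-5.0, -5.0], [5.0, 5.0]), K=2)
        assert res.termination_reason == "iteration_cap"

    def test_invalid_cap_rejected(self):
        with pytest.raises(ValueError):
            trr_step_limited(linear_residual, np.zeros(1), _Box([-10.0], [10.0]), K=0)


def test_ikr_objective_termination_and_descent(ikr_objective, ikr_narrow):
    """On the real current-fitting objective: feasible descent with a
    tolerance-based termination from a valid random start."""
    from conftest import draw_valid_params
    from ionfit import build_standard_protocol, get_model

    rng = np.random.default_rng(3)
    p0 = draw_valid_params(
        get_model("IKr"), ikr_narrow, rng, build_standard_protocol()
    )
    res = trr_minimize(ikr_objective.residuals, p0, ikr_narrow)
    assert res.cost <= res.initial_cost
    assert res.termination_reason in ("pTol", "fTol")
    assert ikr_objective.sse_cost(res.x) == pytest.approx(res.cost, rel=1e-9, abs=1e-25)
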