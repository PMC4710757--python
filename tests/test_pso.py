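import numpy as np
import pytest

from ionfit import PSOConfig, constriction_coefficient, enforce_bounds, pso_run, velocity_update
from ionfit.pso import swarm_engine
from ionfit.search_space import SearchSpace


class Quadratic1D:
    """Toy convex objective (p - 3)^2 with a SearchSpace-compatible box."""

    def sse_cost(self, p):
        return float((p[0] - 3.0) ** 2)


class _Box:
    # minimal stand-in implementing the SearchSpace surface the swarm uses
    def __init__(self, lower, upper):
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.width_class = "narrow"

    @property
    def n_params(self):
        return self.lower.shape[0]

    @property
    def width(self):
        return self.upper - self.lower

    def sample(self, rng, n=None):
        if n is None:
            return rng.uniform(self.lower, self.upper)
        return rng.uniform(self.lower, self.upper, size=(n, self.n_params))

    def contains(self, p):
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= self.lower) & np.all(p <= self.upper))


class TestConstriction:
    def test_reference_value(self):
        # phi = 4.1 gives the canonical ~0.73
        assert constriction_coefficient(2.05, 2.05) == pytest.approx(0.7298, abs=5e-5)

    def test_hand_evaluated_case(self):
        # phi = 6: 2 / (4 + sqrt(12)) = 0.26794919...
        assert constriction_coefficient(3.0, 3.0) == pytest.approx(0.2679, abs=5e-5)

    def test_boundary_phi_rejected(self):
        with pytest.raises(ValueError):
            constriction_coefficient(2.0, 2.0)


class TestVelocityUpdate:
    def test_vanishes_at_consensus(self):
        rng = np.random.default_rng(0)
        p = np.array([1.0, 2.0])
        v = velocity_update(np.zeros(2), p, p, p, 0.73, 2.05, 2.05, rng)
        assert np.allclose(v, 0.0)

    def test_pure_inertia_scaling(self):
        rng = np.random.default_rng(0)
        p = np.array([1.0, 2.0])
        v = velocity_update(np.ones(2), p, p, p, 0.73, 2.05, 2.05, rng)
        assert np.allclose(v, 0.73)

    def test_expectation_of_uniform_draws(self):
        """E[v'] = chi*(v + (phi1/2)(b_i - p) + (phi2/2)(b_g - p))."""
        rng = np.random.default_rng(42)
        v = np.array([0.5, -1.0])
        p = np.array([0.0, 0.0])
        b_i = np.array([2.0, -1.0])
        b_g = np.array([-1.0, 3.0])
        chi, phi1, phi2 = 0.73, 2.05, 2.05
        draws = np.array(
            [velocity_update(v, p, b_i, b_g, chi, phi1, phi2, rng) for _ in range(10_000)]
        )
        expected = chi * (v + phi1 / 2 * (b_i - p) + phi2 / 2 * (b_g - p))
        # MC error ~ sd/sqrt(n); tolerate 5 sd of the mean
        assert np.allclose(draws.mean(axis=0), expected, atol=0.1)


class TestEnforceBounds:
    def test_reentry_windows(self):
        space = _Box([0.0], [100.0])
        rng = np.random.default_rng(1)
        above = enforce_bounds(np.array([120.0]), space, rng)
        assert 75.0 <= above[0] <= 100.0
        below = enforce_bounds(np.array([-5.0]), space, rng)
        assert 0.0 <= below[0] <= 25.0

    def test_in_bounds_identity(self):
        space = _Box([0.0, -1.0], [100.0, 1.0])
        rng = np.random.default_rng(1)
        cand = np.array([50.0, 0.3])
        assert np.array_equal(enforce_bounds(cand, space, rng), cand)

    def test_randomized_trials_always_inside_windows(self):
        """Large randomized check of the 25% re-entry rule."""
        rng = np.random.default_rng(2)
        space = _Box([-3.0, 0.0, 10.0], [5.0, 0.5, 1000.0])
        width = space.width
        n = 100_000
        cands = rng.uniform(space.lower - 2 * width, space.upper + 2 * width, size=(n, 3))
        for i in range(0, n, 1):
            out = enforce_bounds(cands[i], space, rng)
            assert np.all(out >= space.lower) and np.all(out <= space.upper)
            hi = cands[i] > space.upper
            lo = cands[i] < space.lower
            assert np.all(out[hi] >= space.upper[hi] - 0.25 * width[hi])
            assert np.all(out[lo] <= space.lower[lo] + 0.25 * width[lo])
            inside = ~(hi | lo)
            assert np.array_equal(out[inside], cands[i][inside])


class TestPsoRun:
    def test_converges_on_convex_toy(self):
        res = pso_run(
            Quadratic1D(), _Box([-10.0], [10.0]), PSOConfig(24, 100, seed=3)
        )
        assert abs(res.best_params[0] - 3.0) < 1e-2
        assert res.best_cost < 1e-4

    def test_seeded_determinism(self):
        cfg = PSOConfig(8, 20, seed=11)
        space = _Box([-10.0], [10.0])
        a = pso_run(Quadratic1D(), space, cfg)
        b = pso_run(Quadratic1D(), space, cfg)
        assert np.array_equal(a.best_params, b.best_params)
        assert a.best_cost == b.best_cost
        assert a.trace.equals(b.trace)

    def test_global_best_monotone_and_positions_in_bounds(self):
        space = _Box([-10.0, -10.0], [10.0, 10.0])

        class Rosen:
            def sse_cost(self, p):
                return float((1 - p[0]) ** 2 + 100 * (p[1] - p[0] ** 2) ** 2)

        res = pso_run(Rosen(), space, PSOConfig(16, 50, seed=7))
        g = res.trace["gbest_cost"].to_numpy()
        assert np.all(np.diff(g) <= 0)
        assert np.all(res.ranked_params >= space.lower)
        assert np.all(res.ranked_params <= space.upper)
        assert np.all(np.diff(res.ranked_costs) >= 0)

    def test_failed_evaluations_score_infinity_not_abort(self):
        class Flaky:
            def sse_cost(self, p):
                if p[0] > 0:
                    raise RuntimeError("model failure")
                return float(p[0] ** 2)

        res = pso_run(Flaky(), _Box([-5.0], [5.0]), PSOConfig(8, 20, seed=0))
        assert np.isfinite(res.best_cost)
        assert res.best_params[0] <= 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PSOConfig(n_particles=0, n_iterations=10)
        with pytest.raises(ValueError):
            PSOConfig(phi1=1.0, phi2=1.0)


def test_engine_trace_statistics_are_order_consistent():
    space = _Box([-10.0], [10.0])
    _, _, _, trace = swarm_engine(Quadratic1D().sse_cost, space, PSOConfig(12, 15, seed=5))
    for _, row in trace.iterrows():
        assert (
            row["cost_min"]
            <= row["cost_q1"]
            <= row["cost_median"]
            <= row["cost_q3"]
            <= row["cost_max"]
        )
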