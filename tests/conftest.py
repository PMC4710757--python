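import numpy as np
import pytest

from ionfit import (
    Objective,
    build_standard_protocol,
    generate_ground_truth,
    get_model,
    make_bounds,
)


@pytest.fixture(scope="session")
def protocol():
    return build_standard_protocol()


@pytest.fixture(scope="session")
def ikr(protocol):
    return get_model("IKr")


@pytest.fixture(scope="session")
def ikur():
    return get_model("IKur")


@pytest.fixture(scope="session")
def iks():
    return get_model("IKs")


@pytest.fixture(scope="session")
def ikr_clean(ikr, protocol):
    return generate_ground_truth(ikr, protocol)


@pytest.fixture(scope="session")
def ikr_objective(ikr, protocol, ikr_clean):
    return Objective(ikr, protocol, ikr_clean)


@pytest.fixture(scope="session")
def ikr_narrow(ikr):
    return make_bounds(ikr, "narrow")


@pytest.fixture(scope="session")
def ikr_wide(ikr):
    return make_bounds(ikr, "wide")


def ode_reference_trace(model, p, sweep):
    """Independent brute-force oracle: numerical integration of the gating
    ODEs with a stiff-capable adaptive solver at tight tolerance, segment by
    segment, evaluated on the sweep's sample grid with boundary samples
    attributed to the new segment."""
    from scipy.integrate import solve_ivp

    b = sweep.boundaries
    times = sweep.sample_times()
    gates = list(model.gates)
    x = np.array([model.gate_inf(g, p, sweep.steps[0].voltage) for g in gates])
    vals = {g: np.empty_like(times) for g in gates}
    for j, st in enumerate(sweep.steps):
        inf = np.array([model.gate_inf(g, p, st.voltage) for g in gates])
        tau = np.array([model.gate_tau(g, p, st.voltage) for g in gates])
        mask = (times >= b[j] - 1e-9) & (times <= b[j + 1] + 1e-9)
        tt = np.clip(times[mask], b[j], b[j + 1])
        sol = solve_ivp(
            lambda t, y: (inf - y) / tau,
            (b[j], b[j + 1]),
            x,
            method="LSODA",
            t_eval=tt,
            rtol=1e-11,
            atol=1e-14,
        )
        for k, g in enumerate(gates):
            vals[g][mask] = sol.y[k]
        x = sol.y[:, -1]
    idx = np.minimum(np.searchsorted(b, times + 1e-9, side="right") - 1, len(sweep.steps) - 1)
    V = np.array([sweep.steps[i].voltage for i in idx])
    return model.current(p, V, vals)


def draw_valid_params(model, space, rng, protocol, max_tries=200):
    """Uniform draw from the space, redrawn until the kinetics are valid at
    every protocol voltage."""
    from ionfit import simulate
    from ionfit.simulate import SimulationError

    for _ in range(max_tries):
        p = space.sample(rng)
        try:
            simulate(model, p, protocol)
            return p
        except SimulationError:
            continue
    raise RuntimeError("no valid parameter vector found")
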