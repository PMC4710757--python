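"""Constriction-coefficient particle swarm optimization.

The swarm follows the Clerc-Kennedy constriction formulation: each
particle's velocity is damped by the constriction coefficient

    chi = 2 / (phi - 2 + sqrt(phi^2 - 4 phi)),    phi = phi1 + phi2 > 4,

after adding uniformly weighted attractions toward its personal best and the
swarm's global best (phi1 = phi2 = 2.05 by default, giving chi ~ 0.73).
A particle that leaves the box is re-inserted at a uniform random point
within 25% of the parameter range measured from the boundary it crossed.

Determinism and parallelism: one master seed spawns an independent RNG
stream per particle, so per-particle cost evaluations may run in any order
(or concurrently) without changing the trajectory. Initial velocities are
zero; initial positions are evaluated as iteration 0 before the first
velocity update; personal and global bests are updated synchronously at the
end of each iteration. A particle whose cost evaluation fails scores +inf
for that iteration rather than aborting the swarm.

The same engine drives the hybrid optimizer via an optional per-particle
refinement hook (:mod:`ionfit.hybrid`); after any refinement the velocity is
redefined as the effective displacement ``new position - old position``.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .results import RunResult
from .search_space import SearchSpace

__all__ = [
    "PSOConfig",
    "constriction_coefficient",
    "velocity_update",
    "enforce_bounds",
    "pso_run",
]

#: Fraction of the parameter range used as the boundary re-entry window.
REENTRY_FRACTION = 0.25


@dataclass(frozen=True)
class PSOConfig:
    """Swarm size, iteration budget, acceleration constants, and seed."""

    n_particles: int = 24
    n_iterations: int = 1000
    phi1: float = 2.05
    phi2: float = 2.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("n_particles and n_iterations must be >= 1")
        if self.phi1 + self.phi2 <= 4.0:
            raise ValueError("constriction requires phi1 + phi2 > 4")


def constriction_coefficient(phi1: float, phi2: float) -> float:
    """Clerc-Kennedy constriction coefficient for ``phi = phi1 + phi2 > 4``."""
    phi = phi1 + phi2
    if phi <= 4.0:
        raise ValueError(f"phi1 + phi2 must exceed 4, got {phi}")
    return 2.0 / (phi - 2.0 + math.sqrt(phi * phi - 4.0 * phi))


def velocity_update(
    velocity: np.ndarray,
    position: np.ndarray,
    personal_best: np.ndarray,
    global_best: np.ndarray,
    chi: float,
    phi1: float,
    phi2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One constriction velocity update with fresh per-component uniform draws."""
    d = position.shape[0]
    u1 = rng.uniform(0.0, phi1, size=d)
    u2 = rng.uniform(0.0, phi2, size=d)
    return chi * (
        velocity + u1 * (personal_best - position) + u2 * (global_best - position)
    )


def enforce_bounds(
    candidate: np.ndarray, space: SearchSpace, rng: np.random.Generator
) -> np.ndarray:
    """Re-insert out-of-bounds components uniformly within 25% of the range
    from the crossed boundary; in-bounds components are returned unchanged."""
    out = np.asarray(candidate, dtype=float).copy()
    margin = REENTRY_FRACTION * space.width
    below = out < space.lower
    above = out > space.upper
    for idx in np.flatnonzero(below):
        out[idx] = rng.uniform(space.lower[idx], space.lower[idx] + margin[idx])
    for idx in np.flatnonzero(above):
        out[idx] = rng.uniform(space.upper[idx] - margin[idx], space.upper[idx])
    return out


def _safe_cost(cost_fn: Callable, p: np.ndarray) -> float:
    try:
        c = float(cost_fn(p))
    except Exception:
        return math.inf
    return c if math.isfinite(c) else math.inf


def _swarm_stats(costs: np.ndarray) -> tuple:
    finite = costs[np.isfinite(costs)]
    if finite.size == 0:
        return (math.inf,) * 5
    q = np.percentile(finite, [0, 25, 50, 75, 100])
    return tuple(float(v) for v in q)


def swarm_engine(
    cost_fn: Callable,
    space: SearchSpace,
    config: PSOConfig,
    refine: Optional[Callable] = None,
):
    """Core swarm loop shared by pure PSO and the hybrid optimizer.

    ``refine``, if given, maps a boundary-feasible candidate position to a
    ``(position, cost)`` pair (e.g. a few trust-region iterations); without
    it the candidate is simply costed. Returns ``(pbest, pbest_costs,
    gbest_idx, trace_frame)`` with personal bests ranked by the caller.
    """
    N, L = config.n_particles, config.n_iterations
    chi = constriction_coefficient(config.phi1, config.phi2)
    streams = np.random.SeedSequence(config.seed).spawn(N)
    rngs = [np.random.default_rng(s) for s in streams]

    d = space.n_params
    pos = np.empty((N, d))
    vel = np.zeros((N, d))
    costs = np.empty(N)
    for i in range(N):
        pos[i] = space.sample(rngs[i])
        costs[i] = _safe_cost(cost_fn, pos[i])

    pbest = pos.copy()
    pbest_costs = costs.copy()
    gbest_idx = int(np.argmin(pbest_costs))
    gbest = pbest[gbest_idx].copy()
    gbest_cost = float(pbest_costs[gbest_idx])

    rows = [(0, *_swarm_stats(costs), gbest_cost)]
    for it in range(1, L + 1):
        for i in range(N):
            v = velocity_update(
                vel[i], pos[i], pbest[i], gbest, chi, config.phi1, config.phi2, rngs[i]
            )
            cand = enforce_bounds(pos[i] + v, space, rngs[i])
            if refine is not None:
                cand, c = refine(cand)
            else:
                c = _safe_cost(cost_fn, cand)
            vel[i] = cand - pos[i]  # effective displacement after re-entry/refinement
            pos[i] = cand
            costs[i] = c
        # synchronous personal/global best update at the end of the iteration
        improved = costs < pbest_costs
        pbest[improved] = pos[improved]
        pbest_costs[improved] = costs[improved]
        best_now = int(np.argmin(pbest_costs))
        if pbest_costs[best_now] < gbest_cost:
            gbest_idx = best_now
            gbest = pbest[best_now].copy()
            gbest_cost = float(pbest_costs[best_now])
        rows.append((it, *_swarm_stats(costs), gbest_cost))

    trace = pd.DataFrame(
        rows,
        columns=[
            "iteration",
            "cost_min",
            "cost_q1",
            "cost_median",
            "cost_q3",
            "cost_max",
            "gbest_cost",
        ],
    )
    return pbest, pbest_costs, gbest_idx, trace


def rank_by_cost(params: np.ndarray, costs: np.ndarray):
    """Stable ascending sort by cost (ties keep particle order)."""
    order = np.argsort(costs, kind="stable")
    return params[order], costs[order]


def pso_run(objective, space: SearchSpace, config: PSOConfig) -> RunResult:
    """Run pure constriction PSO on ``objective.sse_cost`` over ``space``.

    The returned ranking lists every particle's personal best.
    """
    t0 = time.perf_counter()
    pbest, pbest_costs, _, trace = swarm_engine(objective.sse_cost, space, config)
    ranked_p, ranked_c = rank_by_cost(pbest, pbest_costs)
    return RunResult(
        best_params=ranked_p[0],
        best_cost=float(ranked_c[0]),
        ranked_params=ranked_p,
        ranked_costs=ranked_c,
        trace=trace,
        algorithm="pso",
        seed=config.seed,
        config={
            "n_particles": config.n_particles,
            "n_iterations": config.n_iterations,
            "phi1": config.phi1,
            "phi2": config.phi2,
            "width_class": space.width_class,
        },
        termination={"reason": "iteration budget"},
        wall_time_s=time.perf_counter() - t0,
    )
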