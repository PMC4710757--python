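"""Combinations of swarm and trust-region optimization.

Two schemes build on the pure optimizers:

* **Two-stage** (:func:`two_stage_run`): one full PSO run, after which the
  best ``M`` distinct personal bests are refined independently by
  trust-region-reflective least squares to convergence.

* **Hybrid** (:func:`hybrid_run`): the tight per-iteration coupling. In
  every swarm iteration each particle's boundary-feasible candidate
  position undergoes ``K`` capped trust-region iterations before it is
  costed; the particle's velocity is then redefined as the effective
  displacement, so the swarm dynamics see the locally refined landscape.
  After ``L`` iterations the personal bests are sorted by cost and the top
  ``M`` are refined to convergence (the terminal refinement stage; on an
  already-converged swarm it changes the cost by well under a percent).

Preset budgets ``low`` (K=5, L=250, N=96), ``medium`` (K=10, L=500, N=192)
and ``high`` (K=20, L=1000, N=384) trade runtime against robustness; the
additional ``tiny``/``small`` presets are reduced desk-scale budgets for
quick studies and are not part of the reference study grid.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .pso import PSOConfig, rank_by_cost, swarm_engine
from .results import RunResult
from .search_space import SearchSpace
from .trr import TRRConfig, trr_minimize, trr_step_limited

__all__ = ["HybridSetup", "HYBRID_SETUPS", "two_stage_run", "hybrid_run", "final_refine"]


@dataclass(frozen=True)
class HybridSetup:
    """Hybrid budget: inner TRR iterations K, swarm iterations L, particles N,
    and the number M of personal bests refined at the end."""

    name: str
    inner_trr_iterations: int  # K
    n_iterations: int  # L
    n_particles: int  # N
    refine_count: int = 12  # M

    def __post_init__(self) -> None:
        if self.inner_trr_iterations < 0:
            raise ValueError("K must be >= 0 (0 degenerates to pure PSO)")
        if self.n_iterations < 1 or self.n_particles < 1:
            raise ValueError("L and N must be >= 1")
        if self.refine_count < 1 or self.refine_count > self.n_particles:
            raise ValueError("M must satisfy 1 <= M <= N")


#: Reference setups plus reduced desk-scale presets (``tiny``, ``small``).
HYBRID_SETUPS = {
    "low": HybridSetup("low", 5, 250, 96),
    "medium": HybridSetup("medium", 10, 500, 192),
    "high": HybridSetup("high", 20, 1000, 384),
    "tiny": HybridSetup("tiny", 5, 30, 24, refine_count=6),
    "small": HybridSetup("small", 5, 60, 48, refine_count=12),
}


def get_setup(name_or_setup) -> HybridSetup:
    if isinstance(name_or_setup, HybridSetup):
        return name_or_setup
    try:
        return HYBRID_SETUPS[name_or_setup]
    except KeyError:
        raise KeyError(
            f"unknown hybrid setup {name_or_setup!r}; have {sorted(HYBRID_SETUPS)}"
        ) from None


def _distinct_rows(params: np.ndarray, costs: np.ndarray):
    """Drop exact duplicate parameter vectors, keeping first (best) occurrence."""
    seen = set()
    keep = []
    for i in range(params.shape[0]):
        key = params[i].tobytes()
        if key not in seen:
            seen.add(key)
            keep.append(i)
    idx = np.array(keep, dtype=int)
    return params[idx], costs[idx]


def final_refine(
    objective,
    ranked_params: np.ndarray,
    ranked_costs: np.ndarray,
    space: SearchSpace,
    M: int,
    trr_config: TRRConfig = TRRConfig(),
):
    """Refine the top-``M`` ranked parameter sets to convergence.

    Returns ``(params, costs, reasons, delta)`` where ``params``/``costs``
    are the refined sets re-ranked ascending, ``reasons`` the per-refinement
    termination reasons, and ``delta`` the relative cost improvement of the
    best entry over the pre-refinement best.
    """
    ranked_params = np.atleast_2d(ranked_params)
    if ranked_params.shape[0] == 0:
        raise ValueError("ranked list must be nonempty")
    M = min(M, ranked_params.shape[0])
    before = float(ranked_costs[0])
    out_p, out_c, reasons = [], [], []
    for i in range(M):
        try:
            res = trr_minimize(objective.residuals, ranked_params[i], space, trr_config)
            out_p.append(res.x)
            out_c.append(res.cost)
            reasons.append(res.termination_reason)
        except ValueError:
            out_p.append(ranked_params[i])
            out_c.append(float(ranked_costs[i]))
            reasons.append("failed")
    params, costs = rank_by_cost(np.array(out_p), np.array(out_c))
    delta = 0.0 if before == 0 else (before - float(costs[0])) / before
    return params, costs, reasons, delta


def two_stage_run(
    objective,
    space: SearchSpace,
    config: PSOConfig,
    M: int = 12,
    trr_config: TRRConfig = TRRConfig(),
) -> RunResult:
    """Sequential PSO -> TRR: swarm search, then full refinement of the best
    ``M`` distinct personal bests."""
    t0 = time.perf_counter()
    pbest, pbest_costs, _, trace = swarm_engine(objective.sse_cost, space, config)
    ranked_p, ranked_c = rank_by_cost(pbest, pbest_costs)
    ranked_p, ranked_c = _distinct_rows(ranked_p, ranked_c)
    pso_best = float(ranked_c[0])
    params, costs, reasons, delta = final_refine(
        objective, ranked_p, ranked_c, space, M, trr_config
    )
    return RunResult(
        best_params=params[0],
        best_cost=float(costs[0]),
        ranked_params=params,
        ranked_costs=costs,
        trace=trace,
        algorithm="two_stage",
        seed=config.seed,
        config={
            "n_particles": config.n_particles,
            "n_iterations": config.n_iterations,
            "M": M,
            "width_class": space.width_class,
        },
        termination={
            "pso_best_cost": pso_best,
            "trr_reasons": reasons,
            "refinement_delta": delta,
        },
        wall_time_s=time.perf_counter() - t0,
    )


def hybrid_run(
    objective,
    space: SearchSpace,
    setup="medium",
    seed: int = 0,
    phi1: float = 2.05,
    phi2: float = 2.05,
    trr_config: TRRConfig = TRRConfig(),
    final_trr: bool = True,
) -> RunResult:
    """Per-iteration hybrid (PSO + TRR), optionally with terminal TRR.

    With ``setup.inner_trr_iterations == 0`` the run degenerates to pure PSO
    with the same seed and trajectory. ``final_trr=False`` skips the
    terminal refinement stage.
    """
    setup = get_setup(setup)
    K = setup.inner_trr_iterations
    t0 = time.perf_counter()

    if K > 0:

        def refine(candidate: np.ndarray):
            try:
                res = trr_step_limited(
                    objective.residuals, candidate, space, K, trr_config
                )
                return res.x, res.cost
            except ValueError:
                # invalid start (e.g. non-finite residuals): keep the candidate
                try:
                    return candidate, float(objective.sse_cost(candidate))
                except Exception:
                    return candidate, float("inf")

    else:
        refine = None

    config = PSOConfig(
        n_particles=setup.n_particles,
        n_iterations=setup.n_iterations,
        phi1=phi1,
        phi2=phi2,
        seed=seed,
    )
    pbest, pbest_costs, _, trace = swarm_engine(
        objective.sse_cost, space, config, refine=refine
    )
    ranked_p, ranked_c = rank_by_cost(pbest, pbest_costs)
    swarm_best = float(ranked_c[0])

    reasons: list = []
    delta = 0.0
    if final_trr:
        ranked_p, ranked_c, reasons, delta = final_refine(
            objective, ranked_p, ranked_c, space, setup.refine_count, trr_config
        )
    return RunResult(
        best_params=ranked_p[0],
        best_cost=float(ranked_c[0]),
        ranked_params=ranked_p,
        ranked_costs=ranked_c,
        trace=trace,
        algorithm="hybrid" + ("+trr" if final_trr else ""),
        seed=seed,
        config={
            "setup": setup.name,
            "K": K,
            "L": setup.n_iterations,
            "N": setup.n_particles,
            "M": setup.refine_count,
            "width_class": space.width_class,
        },
        termination={
            "swarm_best_cost": swarm_best,
            "final_trr_reasons": reasons,
            "refinement_delta": delta,
        },
        wall_time_s=time.perf_counter() - t0,
    )
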