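"""Bounded trust-region-reflective nonlinear least squares.

The solver approximates the sum-of-squares cost quadratically around the
current iterate and minimizes that model within an adaptively sized trust
region, reflecting steps at the box constraints. The implementation
delegates to an established trust-region-reflective backend
(``scipy.optimize.least_squares`` with ``method="trf"``) behind a contract
that fixes the stopping semantics used throughout this package:

* ``p_tol``  -- minimum change of the parameter-vector norm between accepted
  iterates (the backend's ``xtol``),
* ``f_tol``  -- minimum change of the cost between accepted iterates
  (the backend's ``ftol``; the backend applies it relative to the current
  cost),
* ``max_iter`` / ``max_fun_eval`` -- iteration and function-evaluation
  budgets, and
* ``iteration_cap`` -- an exact small cap ``K`` for use inside the hybrid
  optimizer.

The backend exposes only a function-evaluation budget, but each of its
iterations consumes at least one (Jacobian finite differences are not
counted), so capping evaluations at ``K`` guarantees at most ``K``
iterations; the same mapping enforces ``max_iter``. The gradient-norm
criterion is disabled so that exactly the reasons above can fire. Jacobians
are forward finite differences with relative step 1e-8.

Every accepted iterate is feasible and never increases the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
from scipy.optimize import least_squares

from .search_space import SearchSpace

__all__ = ["TRRConfig", "TRRResult", "trr_minimize", "trr_step_limited"]

TERMINATION_REASONS = ("pTol", "fTol", "maxIter", "maxFunEval", "iteration_cap")

#: Residual magnitude substituted when the model cannot be evaluated at a
#: trial point; the resulting huge cost makes the trust region reject the
#: step and shrink.
_FAILURE_RESIDUAL = 1e6


@dataclass(frozen=True)
class TRRConfig:
    """Stopping criteria of the trust-region-reflective solver."""

    f_tol: float = 1e-11  # (pA/pF)^2
    p_tol: float = 1e-11
    max_iter: int = 100_000
    max_fun_eval: int = 500_000
    iteration_cap: Optional[int] = None
    diff_step: float = 1e-8  # relative forward-difference step

    def __post_init__(self) -> None:
        if self.f_tol <= 0 or self.p_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_iter < 1 or self.max_fun_eval < 1:
            raise ValueError("budgets must be >= 1")
        if self.iteration_cap is not None and self.iteration_cap < 1:
            raise ValueError("iteration_cap must be >= 1 when set")


@dataclass
class TRRResult:
    """Outcome of a trust-region-reflective run."""

    x: np.ndarray
    cost: float  # sum of squared residuals at x
    termination_reason: str
    iterations: int
    n_fun_eval: int
    initial_cost: float

    def __post_init__(self) -> None:
        assert self.termination_reason in TERMINATION_REASONS


def _wrap_residuals(residual_fn: Callable, m: int) -> Callable:
    def fn(p):
        try:
            r = np.asarray(residual_fn(p), dtype=float)
        except Exception:
            return np.full(m, _FAILURE_RESIDUAL)
        if not np.all(np.isfinite(r)):
            return np.full(m, _FAILURE_RESIDUAL)
        return r

    return fn


def trr_minimize(
    residual_fn: Callable,
    p0,
    space: SearchSpace,
    config: TRRConfig = TRRConfig(),
) -> TRRResult:
    """Minimize ``sum(residual_fn(p)**2)`` over the box ``space`` from ``p0``.

    ``p0`` must be feasible and the residuals finite there. Points where the
    residual function fails during the search are scored with a huge cost so
    the trust region backs away from them instead of aborting.
    """
    p0 = np.asarray(p0, dtype=float)
    if not space.contains(p0):
        raise ValueError("start vector is outside the search-space bounds")
    r0 = np.asarray(residual_fn(p0), dtype=float)
    if not np.all(np.isfinite(r0)):
        raise ValueError("residuals are not finite at the start vector")
    initial_cost = float(r0 @ r0)

    if config.iteration_cap is not None:
        max_nfev = config.iteration_cap
    else:
        max_nfev = min(config.max_iter, config.max_fun_eval)

    res = least_squares(
        _wrap_residuals(residual_fn, r0.shape[0]),
        p0,
        jac="2-point",
        bounds=(space.lower, space.upper),
        method="trf",
        ftol=config.f_tol,
        xtol=config.p_tol,
        gtol=None,
        max_nfev=max_nfev,
        diff_step=config.diff_step,
    )

    if res.status == 2:
        reason = "fTol"
    elif res.status in (3, 4):
        # status 4 means both tolerances fired in one step; the step-norm
        # criterion is reported, matching its role as the finer of the two
        reason = "pTol"
    elif res.status == 0:
        if config.iteration_cap is not None:
            reason = "iteration_cap"
        elif config.max_iter <= config.max_fun_eval:
            reason = "maxIter"
        else:
            reason = "maxFunEval"
    else:  # pragma: no cover - gtol is disabled, other statuses unreachable
        raise RuntimeError(f"unexpected backend termination status {res.status}")

    x = np.clip(res.x, space.lower, space.upper)
    cost = float(res.fun @ res.fun)
    if cost > initial_cost:  # pragma: no cover - trf only accepts descent steps
        x, cost = p0.copy(), initial_cost
    return TRRResult(
        x=x,
        cost=cost,
        termination_reason=reason,
        iterations=int(res.njev if res.njev is not None else res.nfev),
        n_fun_eval=int(res.nfev),
        initial_cost=initial_cost,
    )


def trr_step_limited(
    residual_fn: Callable,
    p0,
    space: SearchSpace,
    K: int,
    config: TRRConfig = TRRConfig(),
) -> TRRResult:
    """Run at most ``K`` trust-region iterations from ``p0``.

    Returns the (possibly non-converged) iterate; the cost never exceeds the
    cost at ``p0`` and the result is feasible.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    return trr_minimize(residual_fn, p0, space, replace(config, iteration_cap=int(K)))
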