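"""Box-constrained search spaces and the least-squares objective.

Bounds are derived mechanically from each parameter's classification:

================  ======================  ========================
role              narrow                  wide
================  ======================  ========================
additive          ``[b - 60, b + 60]``    ``[b - 120, b + 120]``
multiplicative    ``[0.1 b, 10 b]``       ``[0.01 b, 100 b]``
================  ======================  ========================

where ``b`` is the base value; multiplicative bounds are sorted after
scaling so ``lower < upper`` also holds for negative bases.

The objective is the plain sum of squared errors between simulated and
observed current density, summed over every sample of every sweep with no
weighting or exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .currents import ADDITIVE, MULTIPLICATIVE, CurrentModel
from .protocol import ClampProtocol
from .simulate import ProtocolGrid, SimulationError, simulate_on_grid
from .traces import CurrentTrace

__all__ = ["SearchSpace", "make_bounds", "Objective"]

_RANGES = {
    "narrow": {"add_delta": 60.0, "mult_lo": 0.1, "mult_hi": 10.0},
    "wide": {"add_delta": 120.0, "mult_lo": 0.01, "mult_hi": 100.0},
}


@dataclass(frozen=True)
class SearchSpace:
    """Per-parameter box constraints around a model's base values."""

    model: CurrentModel
    lower: np.ndarray
    upper: np.ndarray
    width_class: str

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.shape != (self.model.n_params,):
            raise ValueError("bounds must match the model's parameter count")
        if np.any(lower >= upper):
            raise ValueError("lower bound must be strictly below upper bound")
        base = self.model.base_values
        if np.any(base <= lower) or np.any(base >= upper):
            raise ValueError("base values must lie strictly inside the bounds")

    @property
    def n_params(self) -> int:
        return self.lower.shape[0]

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, p) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= self.lower) & np.all(p <= self.upper))

    def sample(self, rng: np.random.Generator, n: Optional[int] = None) -> np.ndarray:
        """Uniform random point(s) in the box."""
        if n is None:
            return rng.uniform(self.lower, self.upper)
        return rng.uniform(self.lower, self.upper, size=(n, self.n_params))

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: name, base, role, bounds."""
        return pd.DataFrame(
            {
                "name": self.model.param_names,
                "base_value": self.model.base_values,
                "role": [p.role for p in self.model.params],
                "lower": self.lower,
                "upper": self.upper,
                "width_class": self.width_class,
            }
        )


def make_bounds(model: CurrentModel, width: str = "narrow") -> SearchSpace:
    """Build the narrow or wide search space for a current model."""
    if width not in _RANGES:
        raise ValueError(f"width must be one of {sorted(_RANGES)}, got {width!r}")
    r = _RANGES[width]
    lower = np.empty(model.n_params)
    upper = np.empty(model.n_params)
    for i, spec in enumerate(model.params):
        b = spec.base_value
        if spec.role == ADDITIVE:
            lower[i], upper[i] = b - r["add_delta"], b + r["add_delta"]
        else:
            if b == 0:
                raise ValueError(f"multiplicative parameter {spec.name!r} has base 0")
            lo, hi = r["mult_lo"] * b, r["mult_hi"] * b
            lower[i], upper[i] = min(lo, hi), max(lo, hi)
    return SearchSpace(model=model, lower=lower, upper=upper, width_class=width)


class Objective:
    """Sum-of-squared-errors objective for one observed trace.

    Caches the protocol's sampling structure so repeated evaluations inside
    an optimizer cost one simulation plus one subtraction.
    """

    def __init__(self, model: CurrentModel, protocol: ClampProtocol, observed: CurrentTrace):
        self.model = model
        self.protocol = protocol
        self.observed = observed
        self._grid = ProtocolGrid.from_protocol(protocol)
        if observed.currents.shape != (self._grid.n_sweeps, self._grid.times.shape[0]):
            raise ValueError(
                f"observed trace shape {observed.currents.shape} does not match "
                f"protocol grid {(self._grid.n_sweeps, self._grid.times.shape[0])}"
            )
        if not np.allclose(observed.times, self._grid.times):
            raise ValueError("observed sample times do not match the protocol grid")
        self._target = observed.currents.ravel()

    @property
    def n_residuals(self) -> int:
        return self._target.shape[0]

    def simulate(self, p) -> np.ndarray:
        """Model output on the observed grid, shape (n_sweeps, n_samples)."""
        return simulate_on_grid(self.model, p, self._grid)

    def residuals(self, p) -> np.ndarray:
        """Flat vector of ``I(t_i, V_j, p) - I*(t_i, V_j)`` over all sweeps."""
        try:
            return self.simulate(p).ravel() - self._target
        except SimulationError as err:
            raise SimulationError(f"{err} (at p = {np.asarray(p)!r})") from err

    def sse_cost(self, p) -> float:
        """Sum of squared residuals, (pA/pF)^2."""
        r = self.residuals(p)
        return float(r @ r)
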