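"""Optimizer run results and convergence bookkeeping."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["RunResult"]


@dataclass
class RunResult:
    """Outcome of one optimizer run (PSO, two-stage, or hybrid).

    ``ranked_params`` / ``ranked_costs`` list the best parameter sets found,
    sorted by ascending cost (ties broken by particle index); ``best_params``
    / ``best_cost`` are their first entries. ``trace`` carries per-iteration
    swarm statistics where the algorithm is iterative: columns ``iteration``,
    ``cost_min``, ``cost_q1``, ``cost_median``, ``cost_q3``, ``cost_max``,
    ``gbest_cost``.
    """

    best_params: np.ndarray
    best_cost: float
    ranked_params: np.ndarray  # (n_ranked, n_params)
    ranked_costs: np.ndarray  # (n_ranked,)
    trace: Optional[pd.DataFrame] = None
    algorithm: str = ""
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    termination: dict = field(default_factory=dict)
    wall_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.best_params = np.asarray(self.best_params, dtype=float)
        self.ranked_params = np.atleast_2d(np.asarray(self.ranked_params, dtype=float))
        self.ranked_costs = np.asarray(self.ranked_costs, dtype=float)

    def to_json_dict(self) -> dict:
        """JSON-serializable summary (without the full convergence trace)."""
        return {
            "algorithm": self.algorithm,
            "seed": self.seed,
            "best_cost": self.best_cost,
            "best_params": self.best_params.tolist(),
            "ranked_costs": self.ranked_costs.tolist(),
            "config": _jsonable(self.config),
            "termination": _jsonable(self.termination),
            "wall_time_s": self.wall_time_s,
        }

    def save(self, out_dir, stem: str) -> None:
        """Persist the summary as JSON and the convergence trace as CSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"{stem}.json").write_text(json.dumps(self.to_json_dict(), indent=2))
        if self.trace is not None:
            self.trace.to_csv(out_dir / f"{stem}_trace.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
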