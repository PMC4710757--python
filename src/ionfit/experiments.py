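"""Repeated-run experiment designs and reporting.

An :class:`ExperimentPlan` names a current, a data source (clean synthetic,
noisy synthetic at a given SNR, or a trace file), an algorithm with its
configuration, a search-space width, and a number of repetitions (25 in the
reference design). Each repetition gets its own seed derived from the master
seed, so a plan is exactly reproducible.

:func:`noise_study` reports the dual error metric per (SNR, algorithm)
cell: the optimized cost against the noisy input, the squared error of the
fitted model against the non-noisy ground truth, and the noise energy (the
squared difference between noisy and clean input) that lower-bounds the
achievable cost against the noisy input.

:func:`sweep_particles` varies the swarm size over a doubling schedule and
fits a linear regression of log10(median cost) against log2(N), the
coordinate system in which such sweeps are conventionally plotted.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .currents import get_model
from .hybrid import get_setup, hybrid_run, two_stage_run
from .protocol import ClampProtocol, build_standard_protocol
from .pso import PSOConfig, pso_run
from .search_space import Objective, SearchSpace, make_bounds
from .synthetic import NoiseSpec, add_noise, generate_ground_truth, ground_truth_sse
from .traces import read_trace_csv
from .trr import TRRConfig, trr_minimize

__all__ = [
    "ExperimentPlan",
    "DistributionSummary",
    "run_experiment",
    "noise_study",
    "sweep_particles",
    "report",
]

ALGORITHMS = ("pso", "trr", "two_stage", "hybrid")


@dataclass(frozen=True)
class ExperimentPlan:
    """A repeated-run experiment: data source, algorithm, budget, seeds."""

    current: str
    algorithm: str
    width: str = "narrow"
    n_runs: int = 25
    master_seed: int = 0
    snr_db: Optional[float] = None  # None = clean synthetic input
    input_file: Optional[str] = None  # overrides synthetic input when set
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class DistributionSummary:
    """Order statistics of final costs over the completed runs of a plan."""

    costs: np.ndarray
    termination_reasons: List[str]
    n_failed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.costs = np.asarray(self.costs, dtype=float)
        if self.costs.size == 0:
            raise ValueError("summary needs at least one completed run")

    @property
    def minimum(self) -> float:
        return float(np.min(self.costs))

    @property
    def q1(self) -> float:
        return float(np.percentile(self.costs, 25))

    @property
    def median(self) -> float:
        return float(np.median(self.costs))

    @property
    def q3(self) -> float:
        return float(np.percentile(self.costs, 75))

    @property
    def maximum(self) -> float:
        return float(np.max(self.costs))

    def reason_frequencies(self) -> Dict[str, float]:
        if not self.termination_reasons:
            return {}
        vals, counts = np.unique(self.termination_reasons, return_counts=True)
        return {str(v): float(c) / len(self.termination_reasons) for v, c in zip(vals, counts)}

    def as_row(self) -> dict:
        row = {
            "label": self.label,
            "n_runs": int(self.costs.size),
            "n_failed": self.n_failed,
            "cost_min": self.minimum,
            "cost_q1": self.q1,
            "cost_median": self.median,
            "cost_q3": self.q3,
            "cost_max": self.maximum,
        }
        for reason, freq in sorted(self.reason_frequencies().items()):
            row[f"freq_{reason}"] = freq
        return row


# ---------------------------------------------------------------------------
# plan execution
# ---------------------------------------------------------------------------


def build_objective(plan: ExperimentPlan, protocol: Optional[ClampProtocol] = None):
    """Materialize the (model, space, objective, clean trace) of a plan."""
    model = get_model(plan.current)
    protocol = protocol or build_standard_protocol()
    space = make_bounds(model, plan.width)
    clean = generate_ground_truth(model, protocol)
    if plan.input_file is not None:
        observed = read_trace_csv(plan.input_file)
    elif plan.snr_db is not None:
        noise_seed = int(
            np.random.default_rng(plan.master_seed + 104729).integers(0, 2**31 - 1)
        )
        observed = add_noise(clean, NoiseSpec(snr_db=plan.snr_db, seed=noise_seed))
    else:
        observed = clean
    return model, space, Objective(model, protocol, observed), clean


def _random_feasible_start(
    objective, space: SearchSpace, rng: np.random.Generator, max_tries: int = 200
) -> np.ndarray:
    """Uniform random start with finite residuals (redrawn if the vector is
    outside the model's valid kinetic domain)."""
    for _ in range(max_tries):
        p0 = space.sample(rng)
        try:
            if np.all(np.isfinite(objective.residuals(p0))):
                return p0
        except Exception:
            continue
    raise RuntimeError("could not draw a feasible start vector")


def run_single(plan: ExperimentPlan, objective, space: SearchSpace, seed: int) -> dict:
    """One seeded run of the plan's algorithm; returns a flat record."""
    cfg = plan.config
    t0 = time.perf_counter()
    if plan.algorithm == "trr":
        rng = np.random.default_rng(seed)
        p0 = _random_feasible_start(objective, space, rng)
        trr_cfg = TRRConfig(**cfg.get("trr", {}))
        res = trr_minimize(objective.residuals, p0, space, trr_cfg)
        record = {
            "cost": res.cost,
            "params": res.x.tolist(),
            "termination_reason": res.termination_reason,
            "iterations": res.iterations,
        }
    elif plan.algorithm == "pso":
        config = PSOConfig(
            n_particles=cfg.get("N", 24),
            n_iterations=cfg.get("L", 1000),
            seed=seed,
        )
        res = pso_run(objective, space, config)
        record = {
            "cost": res.best_cost,
            "params": res.best_params.tolist(),
            "termination_reason": "iteration budget",
        }
    elif plan.algorithm == "two_stage":
        config = PSOConfig(
            n_particles=cfg.get("N", 24),
            n_iterations=cfg.get("L", 1000),
            seed=seed,
        )
        res = two_stage_run(objective, space, config, M=cfg.get("M", 12))
        record = {
            "cost": res.best_cost,
            "params": res.best_params.tolist(),
            "termination_reason": res.termination["trr_reasons"][0]
            if res.termination["trr_reasons"]
            else "failed",
        }
    else:  # hybrid
        res = hybrid_run(
            objective,
            space,
            setup=cfg.get("setup", "medium"),
            seed=seed,
            final_trr=cfg.get("final_trr", True),
        )
        reasons = res.termination["final_trr_reasons"]
        record = {
            "cost": res.best_cost,
            "params": res.best_params.tolist(),
            "termination_reason": reasons[0] if reasons else "swarm budget",
            "refinement_delta": res.termination["refinement_delta"],
        }
    record.update(
        {
            "algorithm": plan.algorithm,
            "current": plan.current,
            "width": plan.width,
            "snr_db": plan.snr_db,
            "seed": seed,
            "wall_time_s": time.perf_counter() - t0,
        }
    )
    return record


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n)


def run_experiment(
    plan: ExperimentPlan,
    out_dir: Optional[Path] = None,
    protocol: Optional[ClampProtocol] = None,
    label: Optional[str] = None,
):
    """Execute all repetitions of a plan.

    Returns ``(summary, records)``; failed runs are recorded with their
    error and excluded from the summary statistics (with a warning).
    """
    import warnings

    model, space, objective, clean = build_objective(plan, protocol)
    seeds = derive_seeds(plan.master_seed, plan.n_runs)
    records, costs, reasons, n_failed = [], [], [], 0
    for seed in seeds:
        try:
            rec = run_single(plan, objective, space, int(seed))
            # error of the fit against the non-noisy ground truth
            sim = objective.simulate(np.array(rec["params"]))
            rec["sse_vs_ground_truth"] = float(np.sum((sim - clean.currents) ** 2))
            records.append(rec)
            costs.append(rec["cost"])
            reasons.append(rec["termination_reason"])
        except Exception as err:  # individual failures do not abort the plan
            n_failed += 1
            records.append({"seed": int(seed), "error": repr(err)})
            warnings.warn(f"run with seed {seed} failed: {err!r}", stacklevel=2)
    label = label or (
        f"{plan.current}_{plan.algorithm}_{plan.width}"
        + ("" if plan.snr_db is None else f"_snr{plan.snr_db:g}")
    )
    summary = DistributionSummary(
        costs=np.array(costs),
        termination_reasons=reasons,
        n_failed=n_failed,
        label=label,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / f"{label}.jsonl", "w") as fh:
            for rec in records:
                fh.write(json.dumps(rec) + "\n")
        pd.DataFrame([summary.as_row()]).to_csv(out_dir / f"{label}_summary.csv", index=False)
    return summary, records


# ---------------------------------------------------------------------------
# composite designs
# ---------------------------------------------------------------------------


def noise_study(
    current: str = "IKr",
    snr_levels: Sequence[Optional[float]] = (None, 60.0, 35.0, 20.0, 10.0),
    algorithms: Sequence[str] = ("trr", "pso", "two_stage", "hybrid"),
    width: str = "wide",
    n_runs: int = 25,
    master_seed: int = 0,
    config_by_algorithm: Optional[Dict[str, dict]] = None,
    out_dir: Optional[Path] = None,
) -> pd.DataFrame:
    """Noise-sensitivity grid with the dual error metric.

    One row per (SNR, algorithm) cell with the median cost against the
    (possibly noisy) input, the median squared error against the clean
    ground truth, and the noise-energy lower bound of that cell's input.
    ``snr_levels`` uses ``None`` for the clean dataset.
    """
    config_by_algorithm = config_by_algorithm or {}
    model = get_model(current)
    protocol = build_standard_protocol()
    clean = generate_ground_truth(model, protocol)
    rows = []
    for snr in snr_levels:
        for algo in algorithms:
            plan = ExperimentPlan(
                current=current,
                algorithm=algo,
                width=width,
                n_runs=n_runs,
                master_seed=master_seed,
                snr_db=snr,
                config=config_by_algorithm.get(algo, {}),
            )
            summary, records = run_experiment(plan, out_dir=out_dir, protocol=protocol)
            _, _, objective, _ = build_objective(plan, protocol)
            noise_energy = ground_truth_sse(objective.observed, clean)
            gt = [r["sse_vs_ground_truth"] for r in records if "sse_vs_ground_truth" in r]
            rows.append(
                {
                    "snr_db": snr,
                    "algorithm": algo,
                    "cost_vs_input_median": summary.median,
                    "cost_vs_input_min": summary.minimum,
                    "cost_vs_input_max": summary.maximum,
                    "sse_vs_ground_truth_median": float(np.median(gt)),
                    "noise_energy": noise_energy,
                    "n_runs": int(summary.costs.size),
                }
            )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        df.to_csv(Path(out_dir) / f"{current}_noise_study.csv", index=False)
    return df


def sweep_particles(
    current: str = "IKr",
    algorithm: str = "pso",
    n_list: Sequence[int] = tuple(24 * 2**k for k in range(10)),
    width: str = "narrow",
    n_runs: int = 25,
    L: int = 1000,
    master_seed: int = 0,
    out_dir: Optional[Path] = None,
):
    """Swarm-size sweep with a log-log regression of the medians.

    Returns ``(summaries, regression)`` where ``regression`` holds the slope
    and intercept of log10(median cost) against log2(N).
    """
    from scipy.stats import linregress

    if algorithm not in ("pso", "two_stage"):
        raise ValueError("particle sweeps apply to pso or two_stage")
    summaries = []
    for N in n_list:
        plan = ExperimentPlan(
            current=current,
            algorithm=algorithm,
            width=width,
            n_runs=n_runs,
            master_seed=master_seed,
            config={"N": int(N), "L": int(L)},
        )
        summary, _ = run_experiment(plan, out_dir=out_dir, label=None)
        summary.label += f"_N{N}"
        summaries.append(summary)
    medians = np.array([s.median for s in summaries])
    fit = linregress(np.log2(np.asarray(n_list, dtype=float)), np.log10(medians))
    regression = {"slope": float(fit.slope), "intercept": float(fit.intercept)}
    if out_dir is not None:
        df = pd.DataFrame([s.as_row() | {"N": n} for s, n in zip(summaries, n_list)])
        df.to_csv(Path(out_dir) / f"{current}_{algorithm}_sweep.csv", index=False)
        (Path(out_dir) / f"{current}_{algorithm}_sweep_regression.json").write_text(
            json.dumps(regression, indent=2)
        )
    return summaries, regression


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def report(results_dir, out_dir=None, true_params: Optional[np.ndarray] = None):
    """Collect saved run records into tables and figures.

    Emits one summary CSV over all record files, a cost box plot per
    experiment, and (when ground-truth parameters are supplied or recorded)
    a relative parameter-deviation box plot for each experiment.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir is not None else results_dir / "report"
    record_files = sorted(results_dir.glob("*.jsonl"))
    if not record_files:
        raise FileNotFoundError(f"no run records (*.jsonl) under {results_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    all_rows, boxes, labels = [], [], []
    for path in record_files:
        records = [json.loads(line) for line in path.read_text().splitlines() if line]
        ok = [r for r in records if "cost" in r]
        if not ok:
            continue
        costs = np.array([r["cost"] for r in ok])
        summary = DistributionSummary(
            costs=costs,
            termination_reasons=[r.get("termination_reason", "") for r in ok],
            n_failed=len(records) - len(ok),
            label=path.stem,
        )
        all_rows.append(summary.as_row())
        boxes.append(costs)
        labels.append(path.stem)

        current = ok[0].get("current")
        truth = true_params
        if truth is None and current is not None:
            truth = get_model(current).base_values
        if truth is not None and len(ok[0].get("params", [])) == len(truth):
            dev = (np.array([r["params"] for r in ok]) - truth) / truth
            fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(truth)), 4))
            ax.boxplot(dev, tick_labels=get_model(current).param_names)
            ax.axhline(0.0, color="k", lw=0.5)
            ax.set_ylabel("relative deviation from ground truth")
            ax.set_title(path.stem)
            plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)
            fig.tight_layout()
            fig.savefig(out_dir / f"{path.stem}_param_deviation.png", dpi=150)
            plt.close(fig)

    pd.DataFrame(all_rows).to_csv(out_dir / "summaries.csv", index=False)

    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(boxes)), 4))
    ax.boxplot(boxes, tick_labels=labels)
    ax.set_yscale("log")
    ax.set_ylabel("sum of squared errors [(pA/pF)$^2$]")
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "cost_boxplot.png", dpi=150)
    plt.close(fig)

    # convergence traces, if any were saved next to the records
    trace_files = sorted(results_dir.glob("*_trace.csv"))
    if trace_files:
        fig, ax = plt.subplots(figsize=(6, 4))
        for tf in trace_files:
            tr = pd.read_csv(tf)
            ax.plot(tr["iteration"], tr["gbest_cost"], label=tf.stem, lw=1)
        ax.set_yscale("log")
        ax.set_xlabel("iteration")
        ax.set_ylabel("global best cost [(pA/pF)$^2$]")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out_dir / "convergence.png", dpi=150)
        plt.close(fig)
    return out_dir
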