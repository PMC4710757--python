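"""Synthetic voltage-clamp data: ground-truth traces and calibrated noise.

Ground-truth traces are simulated at the model's published base parameters;
an estimation pipeline working on them is blinded to those parameters by
construction (they are recorded only in the trace metadata for later
scoring). Noise is additive Gaussian white noise calibrated to a requested
signal-to-noise ratio in dB:

    sigma^2 = P_signal / 10^(SNR_dB / 10)

where ``P_signal`` is the mean squared current pooled over every sample of
every sweep. Noise samples are i.i.d. across time and sweeps.

The study design uses one noisy copy per SNR level in {10, 20, 35, 60} dB
alongside the clean trace; :func:`make_noise_suite` reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .currents import CurrentModel
from .protocol import ClampProtocol
from .simulate import simulate
from .traces import CurrentTrace, write_trace_csv

__all__ = [
    "STUDY_SNR_DB",
    "NoiseSpec",
    "generate_ground_truth",
    "add_noise",
    "ground_truth_sse",
    "make_noise_suite",
    "write_noise_suite",
]

#: SNR levels (dB) of the noise-sensitivity study.
STUDY_SNR_DB = (10.0, 20.0, 35.0, 60.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white-noise specification: target SNR in dB and RNG seed."""

    snr_db: float
    seed: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def generate_ground_truth(model: CurrentModel, protocol: ClampProtocol) -> CurrentTrace:
    """Simulate the model at its base (published) parameter values.

    Deterministic: repeated calls return identical traces.
    """
    trace = simulate(model, model.base_values, protocol)
    trace.meta.update(
        {
            "ground_truth": True,
            "true_params": model.base_values.tolist(),
            "snr_db": None,
        }
    )
    return trace


def signal_power(trace: CurrentTrace) -> float:
    """Mean squared current over all samples of all sweeps, (pA/pF)^2."""
    return float(np.mean(trace.currents**2))


def add_noise(trace: CurrentTrace, spec: NoiseSpec) -> CurrentTrace:
    """Corrupt a trace with seeded additive Gaussian white noise at ``spec.snr_db``."""
    p_sig = signal_power(trace)
    if p_sig == 0.0:
        raise ValueError("SNR is undefined for an all-zero trace")
    sigma2 = p_sig / 10.0 ** (spec.snr_db / 10.0)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, np.sqrt(sigma2), size=trace.currents.shape)
    return trace.copy_with(
        trace.currents + noise,
        snr_db=spec.snr_db,
        noise_seed=spec.seed,
        noise_sigma2=sigma2,
    )


def ground_truth_sse(noisy: CurrentTrace, clean: CurrentTrace) -> float:
    """Sum of squared sample-wise differences between two traces on one grid.

    Used both as the error metric against the non-noisy ground truth and,
    applied to (noisy input, clean input), as the noise-energy lower bound
    on the cost achievable against the noisy input.
    """
    if not noisy.same_grid(clean):
        raise ValueError("traces are on different sample grids")
    d = noisy.currents - clean.currents
    return float(np.sum(d * d))


def make_noise_suite(
    model: CurrentModel,
    protocol: ClampProtocol,
    seed: int,
    snr_levels: Sequence[float] = STUDY_SNR_DB,
) -> dict:
    """Clean trace plus one noisy copy per SNR level (keyed by dB; clean under ``None``)."""
    clean = generate_ground_truth(model, protocol)
    rng = np.random.default_rng(seed)
    suite = {None: clean}
    for snr in snr_levels:
        sub = int(rng.integers(0, 2**31 - 1))
        suite[float(snr)] = add_noise(clean, NoiseSpec(snr_db=float(snr), seed=sub))
    return suite


def write_noise_suite(suite: dict, out_dir, prefix: Optional[str] = None) -> Path:
    """Write a noise suite as CSV files plus a small JSON manifest."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clean = suite[None]
    prefix = prefix or (clean.model_id or "trace")
    manifest = {"model": clean.model_id, "files": {}}
    for snr, trace in suite.items():
        tag = "clean" if snr is None else f"snr{snr:g}dB"
        fname = f"{prefix}_{tag}.csv"
        write_trace_csv(trace, out_dir / fname)
        manifest["files"][tag] = {
            "file": fname,
            "snr_db": snr,
            "noise_seed": trace.meta.get("noise_seed"),
            "noise_sigma2": trace.meta.get("noise_sigma2"),
        }
    manifest_path = out_dir / f"{prefix}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
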