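"""Current-trace container and delimited-text I/O.

A :class:`CurrentTrace` holds current density (pA/pF) for every sweep of a
clamp protocol on a shared, strictly increasing sample-time grid, plus
provenance metadata (synthetic vs measured, generating model id).

The file format is plain CSV, one file per recording: column 1 is
``time_ms``, columns 2..N+1 are the per-sweep current densities. The header
row carries the step voltage of each sweep (``I_-70mV`` etc.) when known.
Readers accept the 1.5-5 ms sample intervals typical of patch-clamp exports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CurrentTrace", "read_trace_csv", "write_trace_csv"]


@dataclass
class CurrentTrace:
    """Sampled current density per sweep.

    Attributes
    ----------
    times : ndarray, shape (n_samples,)
        Sample times in ms, strictly increasing, shared by all sweeps.
    currents : ndarray, shape (n_sweeps, n_samples)
        Current density in pA/pF.
    source : str
        ``"synthetic"`` or ``"measured"``.
    model_id : str or None
        Generating current formulation for synthetic traces.
    step_voltages : ndarray or None
        Step voltage of each sweep in mV, if known.
    meta : dict
        Free-form provenance (e.g. noise seed, SNR, generating parameters).
    """

    times: np.ndarray
    currents: np.ndarray
    source: str = "synthetic"
    model_id: Optional[str] = None
    step_voltages: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.atleast_2d(np.asarray(self.currents, dtype=float))
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.currents.shape[1] != self.times.shape[0]:
            raise ValueError(
                f"currents has {self.currents.shape[1]} samples per sweep, "
                f"times has {self.times.shape[0]}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.step_voltages is not None:
            self.step_voltages = np.asarray(self.step_voltages, dtype=float)
            if self.step_voltages.shape[0] != self.n_sweeps:
                raise ValueError("one step voltage per sweep required")

    @property
    def n_sweeps(self) -> int:
        return self.currents.shape[0]

    @property
    def n_samples(self) -> int:
        """Total sample count over all sweeps."""
        return int(self.currents.size)

    def same_grid(self, other: "CurrentTrace") -> bool:
        return (
            self.currents.shape == other.currents.shape
            and self.times.shape == other.times.shape
            and np.allclose(self.times, other.times)
        )

    def copy_with(self, currents: np.ndarray, **meta) -> "CurrentTrace":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return CurrentTrace(
            times=self.times.copy(),
            currents=np.asarray(currents, dtype=float),
            source=self.source,
            model_id=self.model_id,
            step_voltages=None if self.step_voltages is None else self.step_voltages.copy(),
            meta=new_meta,
        )


def write_trace_csv(trace: CurrentTrace, path) -> None:
    """Write a trace as CSV with step voltages encoded in the header."""
    if trace.step_voltages is not None:
        cols = [f"I_{v:g}mV" for v in trace.step_voltages]
    else:
        cols = [f"I_sweep{i}" for i in range(trace.n_sweeps)]
    df = pd.DataFrame(trace.currents.T, columns=cols)
    df.insert(0, "time_ms", trace.times)
    df.to_csv(path, index=False, float_format="%.10g")


_VOLT_RE = re.compile(r"I_(-?\d+(?:\.\d+)?)mV")


def read_trace_csv(path, source: str = "measured") -> CurrentTrace:
    """Read a trace file written by :func:`write_trace_csv` or an equivalent
    patch-clamp CSV export (first column time in ms, one column per sweep)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one sweep")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    currents = df.iloc[:, 1:].to_numpy(dtype=float).T
    voltages = []
    for c in df.columns[1:]:
        m = _VOLT_RE.fullmatch(str(c).strip())
        voltages.append(float(m.group(1)) if m else np.nan)
    sv = np.array(voltages)
    return CurrentTrace(
        times=times,
        currents=currents,
        source=source,
        step_voltages=None if np.isnan(sv).any() else sv,
        meta={"path": str(Path(path))},
    )
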