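"""Exact piecewise-analytic voltage-clamp simulation.

Because the clamp voltage is constant within each protocol segment, every
gate's steady state and time constant are constant there too, and the gating
ODE is solved exactly by the exponential update of
:func:`ionfit.gating.gate_update`. The simulator therefore:

1. initializes each gate at its steady state for the first segment's
   (holding) voltage,
2. propagates gate values analytically through the segments, evaluating
   them at every sample time, and
3. computes the current density from the instantaneous gate values and the
   segment voltage (driving force, instantaneous inactivation and
   voltage-dependent conductance factors included).

A sample falling exactly on a segment boundary takes the new segment's
voltage; the gate values are continuous across the boundary either way.

Parameter vectors that produce non-finite rates or non-positive time
constants at any protocol voltage raise :class:`SimulationError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from ._fast import HAVE_NUMBA, fast_trace
from .currents import CurrentModel
from .protocol import ClampProtocol, SweepProtocol
from .traces import CurrentTrace

__all__ = ["SimulationError", "simulate", "ProtocolGrid"]

_BOUNDARY_EPS = 1e-9  # ms; attributes a boundary-coincident sample to the new segment


class SimulationError(ValueError):
    """Raised when a parameter vector is outside the model's valid domain."""


@dataclass
class ProtocolGrid:
    """Precomputed sampling structure of a uniform-segmentation protocol.

    ``voltages`` has one row per sweep and one column per segment; all
    sweeps share segment durations and the sample grid. Building this once
    per objective removes protocol bookkeeping from the inner fitting loop.
    """

    durations: np.ndarray  # (n_segments,)
    voltages: np.ndarray  # (n_sweeps, n_segments)
    times: np.ndarray  # (n_samples_per_sweep,)
    seg_slices: List[slice]  # samples covered by each segment
    rel_times: List[np.ndarray]  # sample times relative to segment onset

    @classmethod
    def from_protocol(cls, protocol: ClampProtocol) -> "ProtocolGrid":
        if not protocol.is_uniform:
            raise SimulationError(
                "sweeps must share segment durations; simulate non-uniform "
                "protocols sweep by sweep"
            )
        sweep0 = protocol.sweeps[0]
        durations = np.array([s.duration for s in sweep0.steps])
        voltages = np.array([[s.voltage for s in sw.steps] for sw in protocol.sweeps])
        times = sweep0.sample_times()
        bounds = sweep0.boundaries
        idx = np.searchsorted(bounds, times + _BOUNDARY_EPS, side="right") - 1
        idx = np.minimum(idx, len(durations) - 1)
        slices, rel = [], []
        for j in range(len(durations)):
            sel = np.flatnonzero(idx == j)
            if sel.size:
                slices.append(slice(sel[0], sel[-1] + 1))
                rel.append(times[sel] - bounds[j])
            else:
                slices.append(slice(0, 0))
                rel.append(np.empty(0))
        return cls(durations, voltages, times, slices, rel)

    @property
    def n_sweeps(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_segments(self) -> int:
        return self.durations.shape[0]

    def kernel_arrays(self):
        """Flattened (seg_offsets, rel_times) layout for the compiled kernel."""
        if not hasattr(self, "_kernel_cache"):
            counts = [sl.stop - sl.start for sl in self.seg_slices]
            offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
            rel = np.concatenate(self.rel_times) if self.rel_times else np.empty(0)
            # sample indices are contiguous and ordered by segment, so the
            # concatenated layout matches the output's time axis directly
            self._kernel_cache = (offsets, rel)
        return self._kernel_cache


def _gate_tables(model: CurrentModel, p: np.ndarray, voltages: np.ndarray):
    """Steady states and time constants for every gate at every sweep-segment
    voltage, validated to be finite with tau > 0."""
    tables = {}
    for gate in model.gates:
        x_inf = np.asarray(model.gate_inf(gate, p, voltages), dtype=float)
        tau = np.asarray(model.gate_tau(gate, p, voltages), dtype=float)
        bad = ~np.isfinite(tau) | (tau <= 0) | ~np.isfinite(x_inf)
        if np.any(bad):
            i = np.argwhere(bad)[0]
            v = voltages[tuple(i)]
            raise SimulationError(
                f"{model.current_id}: gate {gate!r} has invalid kinetics at "
                f"Vm = {v:g} mV (x_inf = {x_inf[tuple(i)]:g}, tau = {tau[tuple(i)]:g} ms); "
                "the parameter vector is outside the model domain"
            )
        tables[gate] = (x_inf, tau)
    return tables


def simulate_on_grid(
    model: CurrentModel, p, grid: ProtocolGrid, use_kernel: bool = True
) -> np.ndarray:
    """Current density array of shape (n_sweeps, n_samples_per_sweep).

    ``use_kernel=False`` forces the plain-numpy reference path (the compiled
    kernel is checked against it in the test suite).
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise SimulationError(f"{model.current_id}: non-finite entries in parameter vector")

    if use_kernel and HAVE_NUMBA:
        offsets, rel = grid.kernel_arrays()
        out = fast_trace(
            model.current_id,
            p,
            grid.voltages,
            model.E_K,
            len(model.gates),
            np.asarray(model.gate_exponents, dtype=np.int64),
            grid.durations,
            offsets,
            rel,
        )
        if out is not None:
            return out
        # invalid kinetics somewhere: fall through so the numpy path raises
        # with the offending gate and voltage identified

    tables = _gate_tables(model, p, grid.voltages)
    out = np.empty((grid.n_sweeps, grid.times.shape[0]))
    # gate state at the current segment onset, per sweep
    state = {g: tables[g][0][:, 0].copy() for g in model.gates}  # steady state at holding V
    for j in range(grid.n_segments):
        sl, rel = grid.seg_slices[j], grid.rel_times[j]
        gate_vals = {}
        for g in model.gates:
            x_inf = tables[g][0][:, j]
            tau = tables[g][1][:, j]
            if rel.size:
                decay = np.exp(-rel[None, :] / tau[:, None])
                gate_vals[g] = x_inf[:, None] + (state[g] - x_inf)[:, None] * decay
            # advance the state to the segment end
            state[g] = x_inf + (state[g] - x_inf) * np.exp(-grid.durations[j] / tau)
        if rel.size:
            Vm = grid.voltages[:, j][:, None]
            out[:, sl] = model.current(p, Vm, gate_vals)
    if not np.all(np.isfinite(out)):
        raise SimulationError(
            f"{model.current_id}: non-finite current (voltage factor overflow); "
            "the parameter vector is outside the model domain"
        )
    return out


def simulate(model: CurrentModel, p, protocol: ClampProtocol) -> CurrentTrace:
    """Simulate ``model`` with parameters ``p`` under ``protocol``.

    Returns a synthetic :class:`~ionfit.traces.CurrentTrace` with one row
    per sweep on the protocol's sampling grid.
    """
    if protocol.is_uniform:
        grid = ProtocolGrid.from_protocol(protocol)
        currents = simulate_on_grid(model, p, grid)
        times = grid.times
    else:
        durs = {sw.duration for sw in protocol.sweeps}
        if len(durs) != 1:
            raise SimulationError("sweeps of unequal total duration are not supported")
        rows = []
        for sw in protocol.sweeps:
            g = ProtocolGrid.from_protocol(ClampProtocol(sweeps=(sw,)))
            rows.append(simulate_on_grid(model, p, g)[0])
            times = g.times
        currents = np.vstack(rows)
    n_seg = len(protocol.sweeps[0].steps)
    step_seg = 1 if n_seg > 1 else 0
    return CurrentTrace(
        times=times,
        currents=currents,
        source="synthetic",
        model_id=model.current_id,
        step_voltages=np.array([sw.steps[step_seg].voltage for sw in protocol.sweeps]),
        meta={},
    )
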