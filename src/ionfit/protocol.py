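"""Step voltage-clamp protocols.

A protocol is a collection of *sweeps*; each sweep holds the membrane at a
sequence of constant voltages (``VoltageStep``) and is sampled on a regular
time grid. Because the voltage is piecewise constant, the gating ODEs of
Hodgkin-Huxley-type currents can be solved exactly segment by segment
(see :mod:`ionfit.simulate`).

Sampling convention: samples lie at ``t = 0, dt, 2*dt, ...`` up to and
including the sweep duration. A sample that falls exactly on a voltage-step
boundary is attributed to the *new* segment (the step is considered to have
occurred), which matters for instantaneous voltage-dependent factors of the
current, not for the gate values themselves (those are continuous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "VoltageStep",
    "SweepProtocol",
    "ClampProtocol",
    "build_standard_protocol",
    "STANDARD_STEP_VOLTAGES",
]

#: Step voltages of the standard activation protocol, mV.
STANDARD_STEP_VOLTAGES = tuple(float(v) for v in range(-70, 51, 10))


@dataclass(frozen=True)
class VoltageStep:
    """One constant-voltage segment of a clamp sweep.

    Parameters
    ----------
    duration : float
        Segment length in ms, strictly positive.
    voltage : float
        Command transmembrane voltage in mV.
    """

    duration: float
    voltage: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"step duration must be finite and > 0, got {self.duration}")
        if not math.isfinite(self.voltage):
            raise ValueError(f"step voltage must be finite, got {self.voltage}")


@dataclass(frozen=True)
class SweepProtocol:
    """An ordered sequence of voltage steps sampled every ``sample_interval`` ms."""

    steps: tuple[VoltageStep, ...]
    sample_interval: float

    def __post_init__(self) -> None:
        if len(self.steps) == 0:
            raise ValueError("a sweep needs at least one voltage step")
        object.__setattr__(self, "steps", tuple(self.steps))
        if not (math.isfinite(self.sample_interval) and self.sample_interval > 0):
            raise ValueError("sample_interval must be finite and > 0")

    @property
    def duration(self) -> float:
        """Total sweep length in ms."""
        return float(sum(s.duration for s in self.steps))

    @property
    def boundaries(self) -> np.ndarray:
        """Segment onset/offset times, length ``len(steps) + 1``, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.steps])])

    @property
    def voltages(self) -> np.ndarray:
        return np.array([s.voltage for s in self.steps])

    def sample_times(self) -> np.ndarray:
        """The sampling grid ``0, dt, ..., duration`` (inclusive of both ends)."""
        n = int(round(self.duration / self.sample_interval))
        return np.arange(n + 1) * self.sample_interval


@dataclass(frozen=True)
class ClampProtocol:
    """A multi-sweep clamp program. All sweeps share one sample interval."""

    sweeps: tuple[SweepProtocol, ...]

    def __post_init__(self) -> None:
        if len(self.sweeps) == 0:
            raise ValueError("a protocol needs at least one sweep")
        object.__setattr__(self, "sweeps", tuple(self.sweeps))
        intervals = {s.sample_interval for s in self.sweeps}
        if len(intervals) != 1:
            raise ValueError(f"all sweeps must share one sample interval, got {sorted(intervals)}")

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self) -> Iterator[SweepProtocol]:
        return iter(self.sweeps)

    @property
    def sample_interval(self) -> float:
        return self.sweeps[0].sample_interval

    @property
    def total_duration(self) -> float:
        """Summed duration of all sweeps, ms."""
        return float(sum(s.duration for s in self.sweeps))

    @property
    def n_samples(self) -> int:
        """Total number of samples across all sweeps."""
        return int(sum(len(s.sample_times()) for s in self.sweeps))

    @property
    def is_uniform(self) -> bool:
        """True if every sweep has the same segment durations (voltages may differ)."""
        ref = tuple(s.duration for s in self.sweeps[0].steps)
        return all(tuple(st.duration for st in sw.steps) == ref for sw in self.sweeps)

    def step_voltages(self, segment: int = 1) -> np.ndarray:
        """Voltage of the given segment in each sweep (default: the test step)."""
        return np.array([sw.steps[segment].voltage for sw in self.sweeps])

    # -- plain-config (de)serialization ------------------------------------

    def to_dict(self) -> dict:
        return {
            "sample_interval_ms": self.sample_interval,
            "sweeps": [
                [{"duration_ms": st.duration, "voltage_mV": st.voltage} for st in sw.steps]
                for sw in self.sweeps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClampProtocol":
        dt = float(d["sample_interval_ms"])
        sweeps = tuple(
            SweepProtocol(
                steps=tuple(
                    VoltageStep(float(st["duration_ms"]), float(st["voltage_mV"])) for st in sw
                ),
                sample_interval=dt,
            )
            for sw in d["sweeps"]
        )
        return cls(sweeps=sweeps)


def build_standard_protocol(
    hold_ms: float = 20.0,
    hold_mV: float = -80.0,
    step_ms: float = 400.0,
    step_voltages: Sequence[float] = STANDARD_STEP_VOLTAGES,
    tail_ms: float = 400.0,
    tail_mV: float = -110.0,
    sample_interval: float = 2.0,
) -> ClampProtocol:
    """Build the standard activation protocol.

    Defaults give 13 sweeps of 20 ms at -80 mV, 400 ms at a step voltage
    from -70 to +50 mV in 10 mV increments, and 400 ms at -110 mV, sampled
    every 2 ms -- 820 ms per sweep, 10.66 s in total.
    """
    sweeps = tuple(
        SweepProtocol(
            steps=(
                VoltageStep(hold_ms, hold_mV),
                VoltageStep(step_ms, float(v)),
                VoltageStep(tail_ms, tail_mV),
            ),
            sample_interval=sample_interval,
        )
        for v in step_voltages
    )
    return ClampProtocol(sweeps=sweeps)
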