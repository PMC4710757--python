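"""Gating-variable primitives.

A Hodgkin-Huxley gate ``x`` relaxes toward a voltage-dependent steady state
``x_inf(V)`` with time constant ``tau(V)``:

    dx/dt = (x_inf - x) / tau

Under a piecewise-constant voltage both ``x_inf`` and ``tau`` are constant
within each segment, so the ODE has the exact solution

    x(t) = x_inf + (x0 - x_inf) * exp(-(t - t0) / tau)

(:func:`gate_update`), which is the Rush-Larsen exponential update taken to
its exact limit. No numerical ODE solver is needed in the production path.

The rate functions of the delayed-rectifier currents have the generic form
``A * u / (1 - exp(-u/s))`` whose value at the removable singularity ``u = 0``
is ``A * s``; :func:`rate_linoverexpm1` evaluates this robustly via ``expm1``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["boltzmann", "rate_linoverexpm1", "rate_activation", "gate_update"]

#: |u/s| below this threshold switches the u/(1-exp(-u/s)) form to its
#: series limit; expm1 keeps the ratio accurate well beyond this point, the
#: guard only protects the exact-zero division.
_SINGULARITY_TOL = 1e-12


def boltzmann(Vm, v_shift, slope):
    """Sigmoid ``1 / (1 + exp(-(Vm + v_shift)/slope))``.

    Increasing in ``Vm`` for positive ``slope``; value 0.5 at
    ``Vm = -v_shift``.
    """
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-(np.asarray(Vm, dtype=float) + v_shift) / slope))


def rate_linoverexpm1(Vm, scale, shift_num, shift_exp, slope):
    """Rate of the form ``scale * (Vm + shift_num) / (exp((Vm + shift_exp)/slope) - 1)``.

    With ``shift_num == shift_exp`` (and negated via the sign of ``slope``)
    this covers both canonical forms

    * ``A*u / (1 - exp(-u/s))``  -- pass ``slope = -s`` and negate ``scale``,
      or simply use :func:`rate_activation` below, and
    * ``A*u / (exp(u/s) - 1)``   -- directly.

    At the removable singularity (both shifts equal, exponent argument -> 0)
    the series limit ``scale * slope`` is returned. If only the denominator
    vanishes the expression genuinely diverges and ``inf`` is returned; the
    simulator treats non-finite rates as a parameter-domain error.
    """
    Vm = np.asarray(Vm, dtype=float)
    u = (Vm + shift_exp) / slope
    num = scale * (Vm + shift_num)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        den = np.expm1(u)
        out = num / den
    small = np.abs(u) < _SINGULARITY_TOL
    if np.any(small):
        # exact limit when the numerator shares the root; otherwise divergent
        limit = np.where(
            np.abs(np.asarray(Vm + shift_num)) < _SINGULARITY_TOL * abs(slope),
            scale * slope,
            np.inf,
        )
        out = np.where(small, limit, out)
    if out.ndim == 0:
        return float(out)
    return out


def rate_activation(Vm, scale, shift, slope):
    """Rate ``scale * (Vm + shift) / (1 - exp(-(Vm + shift)/slope))``.

    The single shift is shared between numerator and exponential, so the
    singularity at ``Vm = -shift`` is always removable with limit
    ``scale * slope``. Positive for all ``Vm`` when ``scale, slope > 0``.
    """
    # A*u/(1 - exp(-u/s)) == (-A)*u/(exp(u/(-s)) - 1)
    return rate_linoverexpm1(Vm, -scale, shift, shift, -slope)


def gate_update(x0, x_inf, tau, dt):
    """Exact exponential relaxation of a gate over a constant-voltage interval.

    Parameters
    ----------
    x0 : float or ndarray
        Gate value at the start of the interval.
    x_inf : float or ndarray
        Steady-state value for the interval's voltage.
    tau : float or ndarray
        Time constant in ms, strictly positive.
    dt : float or ndarray
        Elapsed time in ms, non-negative.

    Returns
    -------
    float or ndarray
        ``x_inf + (x0 - x_inf) * exp(-dt/tau)``; always between ``x0`` and
        ``x_inf`` inclusive.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("gate time constant must be > 0")
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("dt must be >= 0")
    out = x_inf + (np.asarray(x0, dtype=float) - x_inf) * np.exp(-dt / tau)
    if out.ndim == 0:
        return float(out)
    return out
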