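"""Compiled inner loops of the clamp simulator.

The analytic simulation has two parts: (1) small per-(sweep, segment)
tables — the voltage-only current factor plus each gate's steady state and
time constant — and (2) the per-sample exponential relaxation and gate
product. Both are plain scalar arithmetic, so they are compiled with numba;
part (2) is model-independent (:func:`_trace_kernel`), part (1) has one
builder per current formulation mirroring the numpy definitions in
:mod:`ionfit.currents`, against which the test suite verifies them. When
numba is unavailable the simulator transparently falls back to the numpy
reference path.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


_SINGULARITY_TOL = 1e-12  # must match ionfit.gating


@njit(cache=True, inline="always")
def _valid(vfac, x_inf, tau):
    return (
        math.isfinite(vfac)
        and math.isfinite(x_inf)
        and math.isfinite(tau)
        and tau > 0.0
    )


@njit(cache=True, inline="always")
def _rate_u(Vm, scale, c_num, c_exp, slope):
    """scale * (Vm + c_num) / (exp((Vm + c_exp)/slope) - 1), expm1-robust."""
    u = (Vm + c_exp) / slope
    if abs(u) < _SINGULARITY_TOL:
        if abs(Vm + c_num) < _SINGULARITY_TOL * abs(slope):
            return scale * slope
        return math.inf
    return scale * (Vm + c_num) / math.expm1(u)


@njit(cache=True, inline="always")
def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=True)
def _ikr_tables(p, V, E_K, vfac, x_inf, tau):
    S, J = V.shape
    for s in range(S):
        for j in range(J):
            v = V[s, j]
            vfac[s, j] = p[0] * (v - E_K) * _sigmoid(-(v + p[1]) / p[2])
            x_inf[0, s, j] = _sigmoid((v + p[3]) / p[4])
            alpha = _rate_u(v, -p[5], p[6], p[6], -p[7])
            beta = _rate_u(v, p[8], p[9], p[10], p[11])
            tau[0, s, j] = 1.0 / (alpha + beta)
            if not _valid(vfac[s, j], x_inf[0, s, j], tau[0, s, j]):
                return False
    return True


@njit(cache=True)
def _ikur_tables(p, V, E_K, vfac, x_inf, tau):
    S, J = V.shape
    for s in range(S):
        for j in range(J):
            v = V[s, j]
            g = p[0] * (p[1] + p[2] * _sigmoid((v + p[3]) / p[4]))
            vfac[s, j] = g * (v - E_K)
            a_ua = p[5] / (math.exp(-(v + p[6]) / p[7]) + math.exp(-(v + p[8]) / p[9]))
            b_ua = p[10] / (p[11] + math.exp((v + p[12]) / p[13]))
            x_inf[0, s, j] = _sigmoid((v + p[14]) / p[15])
            tau[0, s, j] = 1.0 / (3.0 * (a_ua + b_ua))
            a_ui = p[16] / (p[17] + math.exp(-(v + p[18]) / p[19]))
            b_ui = p[20] * math.exp((v + p[21]) / p[22])
            x_inf[1, s, j] = _sigmoid(-(v + p[23]) / p[24])
            tau[1, s, j] = 1.0 / (3.0 * (a_ui + b_ui))
            if not (
                _valid(vfac[s, j], x_inf[0, s, j], tau[0, s, j])
                and _valid(0.0, x_inf[1, s, j], tau[1, s, j])
            ):
                return False
    return True


@njit(cache=True)
def _iks_tables(p, V, E_K, vfac, x_inf, tau):
    S, J = V.shape
    for s in range(S):
        for j in range(J):
            v = V[s, j]
            vfac[s, j] = p[0] * (v - E_K)
            x_inf[0, s, j] = math.sqrt(_sigmoid((v + p[8]) / p[9]))
            alpha = _rate_u(v, -p[1], p[2], p[2], -p[3])
            beta = _rate_u(v, p[4], p[5], p[6], p[7])
            tau[0, s, j] = 0.5 / (alpha + beta)
            if not _valid(vfac[s, j], x_inf[0, s, j], tau[0, s, j]):
                return False
    return True


TABLE_BUILDERS = {"IKr": _ikr_tables, "IKur": _ikur_tables, "IKs": _iks_tables}


@njit(cache=True)
def _trace_kernel(vfac, x_inf, tau, exponents, durations, seg_offsets, rel_times, out):
    """Fill ``out[s, t]`` with the simulated current density.

    Shapes: vfac (S, J); x_inf, tau (G, S, J); exponents (G,); durations
    (J,); seg_offsets (J+1,) start index of each segment's samples in the
    concatenated rel_times (T,); out (S, T).
    """
    G, S, J = x_inf.shape
    state = np.empty(G)
    for s in range(S):
        for g in range(G):
            state[g] = x_inf[g, s, 0]  # steady state at the holding voltage
        for j in range(J):
            for t in range(seg_offsets[j], seg_offsets[j + 1]):
                prod = 1.0
                for g in range(G):
                    x = x_inf[g, s, j] + (state[g] - x_inf[g, s, j]) * math.exp(
                        -rel_times[t] / tau[g, s, j]
                    )
                    for _ in range(exponents[g]):
                        prod *= x
                out[s, t] = vfac[s, j] * prod
            for g in range(G):
                state[g] = x_inf[g, s, j] + (state[g] - x_inf[g, s, j]) * math.exp(
                    -durations[j] / tau[g, s, j]
                )
    return out


def fast_trace(current_id, p, voltages, E_K, n_gates, exponents, durations, seg_offsets, rel_times):
    """Tables + trace in compiled code; returns None when invalid kinetics or
    a non-finite voltage factor are encountered (caller raises with context)."""
    S, J = voltages.shape
    vfac = np.empty((S, J))
    x_inf = np.empty((n_gates, S, J))
    tau = np.empty((n_gates, S, J))
    if not TABLE_BUILDERS[current_id](p, voltages, E_K, vfac, x_inf, tau):
        return None
    out = np.empty((S, rel_times.shape[0]))
    return _trace_kernel(vfac, x_inf, tau, exponents, durations, seg_offsets, rel_times, out)
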