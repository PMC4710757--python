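"""Delayed-rectifier potassium current formulations (human atrial myocyte).

Three Hodgkin-Huxley-type current-density formulations from the
Courtemanche et al. human atrial cell model are provided:

* ``IKr``  -- rapid delayed rectifier; one activation gate ``x_r`` plus an
  instantaneous voltage-dependent inactivation factor; 12 adjustable
  parameters.
* ``IKur`` -- ultra-rapid delayed rectifier; activation gate ``u_a`` (cubed),
  inactivation gate ``u_i``, and a voltage-dependent conductance; 25
  adjustable parameters.
* ``IKs``  -- slow delayed rectifier; one activation gate ``x_s`` squared
  (the square-root steady-state form makes the channel's equilibrium open
  fraction a first-power Boltzmann); 10 adjustable parameters.

Every numeric constant of the current and gating equations is an adjustable
parameter, classified *additive* (voltage shifts, mV) or *multiplicative*
(conductances, rate scales, slopes, dimensionless offsets). Each rate
function carries an explicit multiplicative scale factor, set to unity where
the original formulation has none, and each current carries an overall
conductance factor. Two conventions complete the enumeration:

* In the ``x_r``/``x_s`` activation rates ``A*u/(1 - exp(-u/s))`` the voltage
  shift is a single parameter shared between numerator and exponential (the
  singularity stays removable).
* In the deactivation rates ``A*u/(exp(u/s) - 1)`` the numerator and
  exponential voltage shifts are two independent parameters with equal base
  values.

Temperature (Q10) factors and gate exponents are fixed model constants, not
adjustable. The potassium Nernst voltage ``E_K`` is fixed at -86.8 mV
(Nernst relation with [K+]o = 5.4 mM, [K+]i = 139 mM at 310 K) and is never
estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .gating import boltzmann, rate_activation, rate_linoverexpm1

__all__ = [
    "E_K_MV",
    "K_Q10",
    "ParameterSpec",
    "CurrentModel",
    "ikr_model",
    "ikur_model",
    "iks_model",
    "get_model",
    "MODEL_IDS",
    "gate_steady_state",
    "gate_time_constant",
    "gate_rate_alpha_xr",
    "gate_rate_beta_xr",
]

#: Potassium Nernst voltage, mV (fixed constant, excluded from estimation).
E_K_MV = -86.8

#: Temperature correction factor on the IKur gate rates (fixed constant).
K_Q10 = 3.0

ADDITIVE = "additive"
MULTIPLICATIVE = "multiplicative"


@dataclass(frozen=True)
class ParameterSpec:
    """One adjustable model parameter.

    ``role`` controls how search-space bounds are built around
    ``base_value``: additive parameters vary by +/- an absolute offset,
    multiplicative ones by a factor (see :mod:`ionfit.search_space`).
    """

    name: str
    base_value: float
    role: str  # "additive" | "multiplicative"
    units: str = ""

    def __post_init__(self) -> None:
        if self.role not in (ADDITIVE, MULTIPLICATIVE):
            raise ValueError(f"role must be additive|multiplicative, got {self.role!r}")
        if self.role == MULTIPLICATIVE and self.base_value == 0:
            raise ValueError(f"multiplicative parameter {self.name!r} must have nonzero base")


def _p(name: str, base: float, role: str, units: str = "") -> ParameterSpec:
    return ParameterSpec(name, base, role, units)


class CurrentModel:
    """A current formulation: adjustable parameters, gates, and the current law.

    Subclasses implement the voltage dependence of each gate's steady state
    and time constant plus the instantaneous current as a function of the
    gate values. All voltage-dependent methods are vectorized over ``Vm``.

    Every formulation here factors as

        I(t) = f(Vm, p) * prod_g x_g(t)**e_g

    with ``f`` collecting the conductance, driving force, and any
    instantaneous voltage-dependent factors (:meth:`voltage_factor`), and
    integer gate exponents ``e_g`` (:attr:`gate_exponents`); the simulator's
    fast path relies on this factorization.
    """

    current_id: str = ""
    gates: Tuple[str, ...] = ()
    gate_exponents: Tuple[int, ...] = ()

    def __init__(self, params: Tuple[ParameterSpec, ...], E_K: float = E_K_MV):
        self.params = tuple(params)
        self.E_K = float(E_K)
        self._index = {p.name: i for i, p in enumerate(self.params)}

    # -- parameter vector helpers ------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def base_values(self) -> np.ndarray:
        return np.array([p.base_value for p in self.params])

    @property
    def param_names(self) -> Tuple[str, ...]:
        return tuple(p.name for p in self.params)

    def index(self, name: str) -> int:
        return self._index[name]

    def _check_p(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if p.shape != (self.n_params,):
            raise ValueError(
                f"{self.current_id} expects {self.n_params} parameters, got shape {p.shape}"
            )
        return p

    def _check_gate(self, gate: str) -> None:
        if gate not in self.gates:
            raise KeyError(f"unknown gate {gate!r} for {self.current_id}; have {self.gates}")

    # -- contract for subclasses -------------------------------------------

    def gate_inf(self, gate: str, p, Vm):
        """Steady-state open fraction of ``gate`` at voltage ``Vm``."""
        raise NotImplementedError

    def gate_rates(self, gate: str, p, Vm):
        """Opening/closing rates ``(alpha, beta)`` in 1/ms at ``Vm``."""
        raise NotImplementedError

    def gate_tau(self, gate: str, p, Vm):
        """Time constant of ``gate`` in ms at ``Vm`` (default: 1/(alpha+beta))."""
        alpha, beta = self.gate_rates(gate, p, Vm)
        return 1.0 / (alpha + beta)

    def voltage_factor(self, p, Vm):
        """Gate-independent factor of the current at ``Vm``, pA/pF per unit
        open probability."""
        raise NotImplementedError

    def current(self, p, Vm, gate_values: Dict[str, np.ndarray]):
        """Instantaneous current density in pA/pF from gate open fractions."""
        out = np.asarray(self.voltage_factor(p, Vm), dtype=float).copy()
        for gate, expo in zip(self.gates, self.gate_exponents):
            out = out * np.asarray(gate_values[gate], dtype=float) ** expo
        return out


# ---------------------------------------------------------------------------
# IKr: rapid delayed rectifier
# ---------------------------------------------------------------------------

_IKR_PARAMS = (
    _p("g_Kr", 0.029411765, MULTIPLICATIVE, "nS/pF"),
    _p("inact_v_shift", 15.0, ADDITIVE, "mV"),
    _p("inact_slope", 22.4, MULTIPLICATIVE, "mV"),
    _p("xr_inf_v_shift", 14.1, ADDITIVE, "mV"),
    _p("xr_inf_slope", 6.5, MULTIPLICATIVE, "mV"),
    _p("alpha_xr_scale", 3.0e-4, MULTIPLICATIVE, "1/ms/mV"),
    _p("alpha_xr_v_shift", 14.1, ADDITIVE, "mV"),
    _p("alpha_xr_slope", 5.0, MULTIPLICATIVE, "mV"),
    _p("beta_xr_scale", 7.3898e-5, MULTIPLICATIVE, "1/ms/mV"),
    _p("beta_xr_v_shift_num", -3.3328, ADDITIVE, "mV"),
    _p("beta_xr_v_shift_exp", -3.3328, ADDITIVE, "mV"),
    _p("beta_xr_slope", 5.1237, MULTIPLICATIVE, "mV"),
)


class IKrModel(CurrentModel):
    """I_Kr = g_Kr * x_r * (Vm - E_K) / (1 + exp((Vm + 15)/22.4))."""

    current_id = "IKr"
    gates = ("x_r",)
    gate_exponents = (1,)

    def __init__(self, E_K: float = E_K_MV):
        super().__init__(_IKR_PARAMS, E_K)

    def gate_inf(self, gate, p, Vm):
        self._check_gate(gate)
        p = self._check_p(p)
        return boltzmann(Vm, p[3], p[4])

    def gate_rates(self, gate, p, Vm):
        self._check_gate(gate)
        p = self._check_p(p)
        alpha = rate_activation(Vm, p[5], p[6], p[7])
        beta = rate_linoverexpm1(Vm, p[8], p[9], p[10], p[11])
        return alpha, beta

    def voltage_factor(self, p, Vm):
        p = self._check_p(p)
        Vm = np.asarray(Vm, dtype=float)
        with np.errstate(over="ignore"):
            inact = 1.0 / (1.0 + np.exp((Vm + p[1]) / p[2]))
        return p[0] * (Vm - self.E_K) * inact


# ---------------------------------------------------------------------------
# IKur: ultra-rapid delayed rectifier
# ---------------------------------------------------------------------------

_IKUR_PARAMS = (
    _p("g_Kur_scale", 1.0, MULTIPLICATIVE, ""),
    _p("g_Kur_const", 0.005, MULTIPLICATIVE, "nS/pF"),
    _p("g_Kur_gated", 0.05, MULTIPLICATIVE, "nS/pF"),
    _p("g_Kur_v_shift", -15.0, ADDITIVE, "mV"),
    _p("g_Kur_slope", 13.0, MULTIPLICATIVE, "mV"),
    _p("alpha_ua_scale", 0.65, MULTIPLICATIVE, "1/ms"),
    _p("alpha_ua_v_shift1", 10.0, ADDITIVE, "mV"),
    _p("alpha_ua_slope1", 8.5, MULTIPLICATIVE, "mV"),
    _p("alpha_ua_v_shift2", -30.0, ADDITIVE, "mV"),
    _p("alpha_ua_slope2", 59.0, MULTIPLICATIVE, "mV"),
    _p("beta_ua_scale", 0.65, MULTIPLICATIVE, "1/ms"),
    _p("beta_ua_offset", 2.5, MULTIPLICATIVE, ""),
    _p("beta_ua_v_shift", 82.0, ADDITIVE, "mV"),
    _p("beta_ua_slope", 17.0, MULTIPLICATIVE, "mV"),
    _p("ua_inf_v_shift", 30.3, ADDITIVE, "mV"),
    _p("ua_inf_slope", 9.6, MULTIPLICATIVE, "mV"),
    _p("alpha_ui_scale", 1.0, MULTIPLICATIVE, "1/ms"),
    _p("alpha_ui_offset", 21.0, MULTIPLICATIVE, ""),
    _p("alpha_ui_v_shift", -185.0, ADDITIVE, "mV"),
    _p("alpha_ui_slope", 28.0, MULTIPLICATIVE, "mV"),
    _p("beta_ui_scale", 1.0, MULTIPLICATIVE, "1/ms"),
    _p("beta_ui_v_shift", -158.0, ADDITIVE, "mV"),
    _p("beta_ui_slope", 16.0, MULTIPLICATIVE, "mV"),
    _p("ui_inf_v_shift", -99.45, ADDITIVE, "mV"),
    _p("ui_inf_slope", 27.48, MULTIPLICATIVE, "mV"),
)


class IKurModel(CurrentModel):
    """I_Kur = g_Kur(Vm) * u_a^3 * u_i * (Vm - E_K).

    ``g_Kur(Vm) = s * (0.005 + 0.05 / (1 + exp(-(Vm - 15)/13)))`` with an
    overall conductance scale ``s`` (base 1). Gate rates are divided by the
    fixed temperature factor ``K_Q10 = 3`` in the time constants.
    """

    current_id = "IKur"
    gates = ("u_a", "u_i")
    gate_exponents = (3, 1)

    def __init__(self, E_K: float = E_K_MV):
        super().__init__(_IKUR_PARAMS, E_K)

    def gate_inf(self, gate, p, Vm):
        self._check_gate(gate)
        p = self._check_p(p)
        if gate == "u_a":
            return boltzmann(Vm, p[14], p[15])
        return boltzmann(Vm, p[23], -p[24])  # decreasing sigmoid: 1/(1+exp(+(Vm+c)/s))

    def gate_rates(self, gate, p, Vm):
        self._check_gate(gate)
        p = self._check_p(p)
        Vm = np.asarray(Vm, dtype=float)
        with np.errstate(over="ignore"):
            if gate == "u_a":
                alpha = p[5] / (np.exp(-(Vm + p[6]) / p[7]) + np.exp(-(Vm + p[8]) / p[9]))
                beta = p[10] / (p[11] + np.exp((Vm + p[12]) / p[13]))
            else:
                alpha = p[16] / (p[17] + np.exp(-(Vm + p[18]) / p[19]))
                beta = p[20] * np.exp((Vm + p[21]) / p[22])
        return alpha, beta

    def gate_tau(self, gate, p, Vm):
        alpha, beta = self.gate_rates(gate, p, Vm)
        return 1.0 / (K_Q10 * (alpha + beta))

    def voltage_factor(self, p, Vm):
        p = self._check_p(p)
        Vm = np.asarray(Vm, dtype=float)
        with np.errstate(over="ignore"):
            g = p[0] * (p[1] + p[2] / (1.0 + np.exp(-(Vm + p[3]) / p[4])))
        return g * (Vm - self.E_K)


# ---------------------------------------------------------------------------
# IKs: slow delayed rectifier
# ---------------------------------------------------------------------------

_IKS_PARAMS = (
    _p("g_Ks", 0.12941176, MULTIPLICATIVE, "nS/pF"),
    _p("alpha_xs_scale", 4.0e-5, MULTIPLICATIVE, "1/ms/mV"),
    _p("alpha_xs_v_shift", -19.9, ADDITIVE, "mV"),
    _p("alpha_xs_slope", 17.0, MULTIPLICATIVE, "mV"),
    _p("beta_xs_scale", 3.5e-5, MULTIPLICATIVE, "1/ms/mV"),
    _p("beta_xs_v_shift_num", -19.9, ADDITIVE, "mV"),
    _p("beta_xs_v_shift_exp", -19.9, ADDITIVE, "mV"),
    _p("beta_xs_slope", 9.0, MULTIPLICATIVE, "mV"),
    _p("xs_inf_v_shift", -19.9, ADDITIVE, "mV"),
    _p("xs_inf_slope", 12.7, MULTIPLICATIVE, "mV"),
)


class IKsModel(CurrentModel):
    """I_Ks = g_Ks * x_s^2 * (Vm - E_K).

    ``x_s_inf`` is the square root of a Boltzmann sigmoid, so the squared
    gate has a first-power Boltzmann equilibrium. ``tau_xs`` carries the
    fixed factor 1/2: ``tau = 0.5 / (alpha + beta)``.
    """

    current_id = "IKs"
    gates = ("x_s",)
    gate_exponents = (2,)

    def __init__(self, E_K: float = E_K_MV):
        super().__init__(_IKS_PARAMS, E_K)

    def gate_inf(self, gate, p, Vm):
        self._check_gate(gate)
        p = self._check_p(p)
        return np.sqrt(boltzmann(Vm, p[8], p[9]))

    def gate_rates(self, gate, p, Vm):
        self._check_gate(gate)
        p = self._check_p(p)
        alpha = rate_activation(Vm, p[1], p[2], p[3])
        beta = rate_linoverexpm1(Vm, p[4], p[5], p[6], p[7])
        return alpha, beta

    def gate_tau(self, gate, p, Vm):
        alpha, beta = self.gate_rates(gate, p, Vm)
        return 0.5 / (alpha + beta)

    def voltage_factor(self, p, Vm):
        p = self._check_p(p)
        Vm = np.asarray(Vm, dtype=float)
        return p[0] * (Vm - self.E_K)


# ---------------------------------------------------------------------------
# registry and free-function interface
# ---------------------------------------------------------------------------

MODEL_IDS = ("IKr", "IKur", "IKs")

_FACTORIES = {"IKr": IKrModel, "IKur": IKurModel, "IKs": IKsModel}


def ikr_model(E_K: float = E_K_MV) -> IKrModel:
    return IKrModel(E_K)


def ikur_model(E_K: float = E_K_MV) -> IKurModel:
    return IKurModel(E_K)


def iks_model(E_K: float = E_K_MV) -> IKsModel:
    return IKsModel(E_K)


def get_model(current_id: str, E_K: float = E_K_MV) -> CurrentModel:
    """Build a current model by id (``IKr``, ``IKur``, or ``IKs``)."""
    try:
        return _FACTORIES[current_id](E_K)
    except KeyError:
        raise KeyError(f"unknown current id {current_id!r}; expected one of {MODEL_IDS}") from None


def gate_steady_state(model: CurrentModel, gate: str, p, Vm):
    """Steady-state open fraction of ``gate`` at ``Vm`` (in (0, 1))."""
    return model.gate_inf(gate, p, Vm)


def gate_time_constant(model: CurrentModel, gate: str, p, Vm):
    """Gate time constant in ms at ``Vm``: ``1/(alpha + beta)`` up to the
    model's fixed temperature factor."""
    return model.gate_tau(gate, p, Vm)


def gate_rate_alpha_xr(p, Vm):
    """Opening rate of the IKr activation gate, 1/ms."""
    return ikr_model().gate_rates("x_r", p, Vm)[0]


def gate_rate_beta_xr(p, Vm):
    """Closing rate of the IKr activation gate, 1/ms."""
    return ikr_model().gate_rates("x_r", p, Vm)[1]
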