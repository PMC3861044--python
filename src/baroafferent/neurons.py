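"""Firing-rate generation: nerve-ending strain -> firing rate (Hz).

Two algebraic output maps:

* ``LinearNeuron`` — affine amplifier ``f = s1*eps_ne + s2``.  Deliberately
  not clamped at zero by default: under strongly rectifying stimuli the
  affine map goes negative, which is exactly the behaviour that motivates
  the integrate-and-fire alternative.  Pass ``clamp=True`` for downstream
  uses that need nonnegative rates.
* ``IFNeuron`` — leaky integrate-and-fire rate map.  The membrane is an RC
  circuit ``Cm dV/dt = I - g V`` (voltage relative to equilibrium); the
  charging time to threshold has the closed form
  ``T_th = (Cm/g) * log(I / (I - g*Vth))`` for ``I > g*Vth`` and no
  solution otherwise, and the instantaneous rate is ``f = 1/(T_th + Delta)``
  with absolute refractory period ``Delta``, or 0 for sub-threshold drive.

The stimulus current is affine in strain, ``I = s1*eps_ne + s2``.  The
firing rate is interpreted as an instantaneous algebraic function of
strain; no spike-level events enter the ODE integration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "LinearNeuronParams",
    "IFNeuronParams",
    "NeuronModel",
    "LinearNeuron",
    "IFNeuron",
    "linear_firing",
    "stimulus_current",
    "threshold_time",
    "if_firing",
    "neuron_from_dict",
    "neuron_to_dict",
]

#: Default absolute refractory period (s).  Observed maximal baroreceptor
#: firing rates of ~140 Hz bound the refractory period by ~1/140 s.
DEFAULT_REFRACTORY = 0.007

# Default membrane constants are modelling choices loosely informed by
# nodose-neuron electrophysiology (a membrane time constant Cm/g = 5 ms and
# a 10 mV threshold above equilibrium); they are not literature values.
DEFAULT_CM_NF = 5.0  # nF
DEFAULT_G_NS = 1000.0  # nS
DEFAULT_VTH_V = 0.01  # V relative to equilibrium


@dataclass(frozen=True)
class LinearNeuronParams:
    """Gain ``s1`` (Hz per unit strain) and shift ``s2`` (Hz)."""

    s1: float
    s2: float


@dataclass(frozen=True)
class IFNeuronParams:
    """Leaky integrate-and-fire constants.

    ``Cm`` (nF), ``g`` (nS) — so ``Cm/g`` is in seconds — threshold ``Vth``
    (V, relative to equilibrium), refractory period ``delta`` (s), and the
    affine stimulus-current map ``I = s1*eps_ne + s2`` (nA).
    """

    s1: float
    s2: float
    Cm: float = DEFAULT_CM_NF
    g: float = DEFAULT_G_NS
    Vth: float = DEFAULT_VTH_V
    delta: float = DEFAULT_REFRACTORY

    def __post_init__(self) -> None:
        if self.Cm <= 0 or self.g <= 0 or self.Vth <= 0 or self.delta <= 0:
            raise ValueError("Cm, g, Vth and delta must all be > 0")

    @property
    def tau_m(self) -> float:
        """Membrane time constant Cm/g (s)."""
        return self.Cm / self.g

    @property
    def threshold_current(self) -> float:
        """Leak current at threshold voltage, ``g * Vth`` (nA)."""
        return self.g * self.Vth


def linear_firing(eps_ne, params: LinearNeuronParams, clamp: bool = False):
    f = params.s1 * np.asarray(eps_ne, dtype=float) + params.s2
    return np.maximum(f, 0.0) if clamp else f


def stimulus_current(eps_ne, params: IFNeuronParams):
    return params.s1 * np.asarray(eps_ne, dtype=float) + params.s2


def threshold_time(I, params: IFNeuronParams):
    """Charging time to threshold (s); ``inf`` when the drive never reaches it.

    Sub-threshold drive (``I <= g*Vth``) is a valid outcome, not an error.
    """
    I = np.asarray(I, dtype=float)
    Ith = params.threshold_current
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(I > Ith, params.tau_m * np.log(I / (I - Ith)), np.inf)
    if T.ndim == 0:
        return float(T)
    return T


def if_firing(eps_ne, params: IFNeuronParams):
    """Instantaneous firing rate of the integrate-and-fire map (Hz)."""
    T = threshold_time(stimulus_current(eps_ne, params), params)
    f = np.where(np.isfinite(T), 1.0 / (np.asarray(T) + params.delta), 0.0)
    if f.ndim == 0:
        return float(f)
    return f


class NeuronModel:
    """Common interface of the firing-rate stage."""

    kind: str = ""

    def __init__(self, params) -> None:
        self.params = params

    def firing_rate(self, eps_ne):
        raise NotImplementedError

    #: True when the output map is smooth in its parameters (allows
    #: gradient-based fitting); the IF map has a threshold discontinuity.
    smooth: bool = True

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.params})"


class LinearNeuron(NeuronModel):
    kind = "linear"
    smooth = True

    def __init__(self, params: LinearNeuronParams, clamp: bool = False) -> None:
        super().__init__(params)
        self.clamp = clamp

    def firing_rate(self, eps_ne):
        return linear_firing(eps_ne, self.params, clamp=self.clamp)


class IFNeuron(NeuronModel):
    kind = "integrate_fire"
    smooth = False

    def __init__(self, params: IFNeuronParams) -> None:
        super().__init__(params)

    def firing_rate(self, eps_ne):
        return if_firing(eps_ne, self.params)

    def threshold_strain(self) -> float:
        """Strain at which the stimulus current equals the leak at threshold."""
        return (self.params.threshold_current - self.params.s2) / self.params.s1


_KIND_MAP = {
    "linear": (LinearNeuron, LinearNeuronParams),
    "integrate_fire": (IFNeuron, IFNeuronParams),
}


def neuron_from_dict(config: dict) -> NeuronModel:
    """Build a neuron model from ``{"type": ..., "params": {...}}``."""
    try:
        kind = config["type"]
        raw = config["params"]
    except (KeyError, TypeError) as exc:
        raise ValueError("neuron config must have 'type' and 'params'") from exc
    if kind not in _KIND_MAP:
        raise ValueError(f"unknown neuron type {kind!r}")
    cls, params_cls = _KIND_MAP[kind]
    return cls(params_cls(**raw))


def neuron_to_dict(neuron: NeuronModel) -> dict:
    return {"type": neuron.kind, "params": asdict(neuron.params)}
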