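"""Analytic pressure stimuli with exact time derivatives.

All stimuli are callables of time (s) returning pressure (mmHg), and carry
an exact derivative so that downstream viscoelastic components never have
to differentiate sampled trajectories numerically.  The smooth stimuli are
built from sinusoids and hyperbolic tangents; the ramp/triangle stimulus is
piecewise linear and exists for qualitative experiments only.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "SinusoidParams",
    "StepParams",
    "SquareParams",
    "RampParams",
    "PressureStimulus",
    "Sinusoid",
    "Step",
    "Square",
    "Ramp",
    "sinusoidal_pressure",
    "step_pressure",
    "square_pressure",
    "ramp_pressure",
    "stimulus_from_dict",
    "stimulus_to_dict",
]

#: Default tanh steepness (1/s) for the square pulse when unspecified.
#: Makes the transition width negligible against the ~4 s plateau.
DEFAULT_SQUARE_STEEPNESS = 50.0


@dataclass(frozen=True)
class SinusoidParams:
    """Sinusoidal pressure: mean + amplitude * sin(angular_frequency*t + phase)."""

    mean_pressure: float
    amplitude: float
    angular_frequency: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.angular_frequency <= 0:
            raise ValueError("angular_frequency must be > 0")

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.angular_frequency


@dataclass(frozen=True)
class StepParams:
    """Smooth tanh step from ``p_base`` to ``p_target`` centred at ``onset``."""

    p_base: float
    p_target: float
    onset: float
    steepness: float = 1.0

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")


@dataclass(frozen=True)
class SquareParams:
    """Smooth square pulse: up-step at ``t_up``, down-step at ``t_down``."""

    p_base: float
    p_up: float
    t_up: float
    t_down: float
    steepness_up: float = DEFAULT_SQUARE_STEEPNESS
    steepness_down: float = DEFAULT_SQUARE_STEEPNESS

    def __post_init__(self) -> None:
        if not self.t_up < self.t_down:
            raise ValueError("t_up must be < t_down")
        if self.steepness_up <= 0 or self.steepness_down <= 0:
            raise ValueError("steepnesses must be > 0")


@dataclass(frozen=True)
class RampParams:
    """Piecewise-linear ramp; with ``symmetric_descend`` a triangle wave."""

    p_start: float
    p_end: float
    t_start: float
    t_end: float
    symmetric_descend: bool = False

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")


def sinusoidal_pressure(t, params: SinusoidParams):
    t = np.asarray(t, dtype=float)
    return params.mean_pressure + params.amplitude * np.sin(
        params.angular_frequency * t + params.phase
    )


def _dsinusoid(t, params: SinusoidParams):
    t = np.asarray(t, dtype=float)
    return (
        params.amplitude
        * params.angular_frequency
        * np.cos(params.angular_frequency * t + params.phase)
    )


def _sech2(x):
    """Overflow-safe sech(x)**2."""
    e = np.exp(-2.0 * np.abs(np.asarray(x, dtype=float)))
    return 4.0 * e / (1.0 + e) ** 2


def step_pressure(t, params: StepParams):
    t = np.asarray(t, dtype=float)
    return params.p_base + 0.5 * (params.p_target - params.p_base) * (
        1.0 + np.tanh(params.steepness * (t - params.onset))
    )


def _dstep(t, params: StepParams):
    t = np.asarray(t, dtype=float)
    sech2 = _sech2(params.steepness * (t - params.onset))
    return 0.5 * (params.p_target - params.p_base) * params.steepness * sech2


def square_pressure(t, params: SquareParams):
    t = np.asarray(t, dtype=float)
    half = 0.5 * (params.p_up - params.p_base)
    return params.p_base + half * (
        np.tanh(params.steepness_up * (t - params.t_up))
        - np.tanh(params.steepness_down * (t - params.t_down))
    )


def _dsquare(t, params: SquareParams):
    t = np.asarray(t, dtype=float)
    half = 0.5 * (params.p_up - params.p_base)
    su = _sech2(params.steepness_up * (t - params.t_up))
    sd = _sech2(params.steepness_down * (t - params.t_down))
    return half * (params.steepness_up * su - params.steepness_down * sd)


def ramp_pressure(t, params: RampParams):
    t = np.asarray(t, dtype=float)
    dur = params.t_end - params.t_start
    slope = (params.p_end - params.p_start) / dur
    if params.symmetric_descend:
        up = params.p_start + slope * (t - params.t_start)
        down = params.p_end - slope * (t - params.t_end)
        p = np.where(
            t < params.t_start,
            params.p_start,
            np.where(
                t < params.t_end,
                up,
                np.where(t < params.t_end + dur, down, params.p_start),
            ),
        )
    else:
        p = np.clip(
            params.p_start + slope * (t - params.t_start),
            min(params.p_start, params.p_end),
            max(params.p_start, params.p_end),
        )
    return p


def _dramp(t, params: RampParams):
    t = np.asarray(t, dtype=float)
    dur = params.t_end - params.t_start
    slope = (params.p_end - params.p_start) / dur
    inside_up = (t >= params.t_start) & (t < params.t_end)
    if params.symmetric_descend:
        inside_down = (t >= params.t_end) & (t < params.t_end + dur)
        return np.where(inside_up, slope, np.where(inside_down, -slope, 0.0))
    return np.where(inside_up, slope, 0.0)


class PressureStimulus:
    """A pressure waveform ``p(t)`` with exact derivative ``dp(t)``.

    Subclasses bind a parameter dataclass to the evaluation functions above.
    Instances are callable: ``stim(t)`` returns pressure in mmHg.
    """

    kind: str = ""

    def __init__(self, params) -> None:
        self.params = params

    def __call__(self, t):
        return self.pressure(t)

    def pressure(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def derivative(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def suggested_max_step(self) -> float:
        """Largest solver step that cannot stride across a stimulus feature."""
        return np.inf

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.params})"


class Sinusoid(PressureStimulus):
    kind = "sinusoid"

    def __init__(self, params: SinusoidParams) -> None:
        super().__init__(params)

    def pressure(self, t):
        return sinusoidal_pressure(t, self.params)

    def derivative(self, t):
        return _dsinusoid(t, self.params)

    def suggested_max_step(self) -> float:
        return self.params.period / 20.0


class Step(PressureStimulus):
    kind = "step"

    def __init__(self, params: StepParams) -> None:
        super().__init__(params)

    def pressure(self, t):
        return step_pressure(t, self.params)

    def derivative(self, t):
        return _dstep(t, self.params)

    def suggested_max_step(self) -> float:
        return 0.25 / self.params.steepness


class Square(PressureStimulus):
    kind = "square"

    def __init__(self, params: SquareParams) -> None:
        super().__init__(params)

    def pressure(self, t):
        return square_pressure(t, self.params)

    def derivative(self, t):
        return _dsquare(t, self.params)

    def suggested_max_step(self) -> float:
        return 0.25 / max(self.params.steepness_up, self.params.steepness_down)


class Ramp(PressureStimulus):
    kind = "ramp"

    def __init__(self, params: RampParams) -> None:
        super().__init__(params)

    def pressure(self, t):
        return ramp_pressure(t, self.params)

    def derivative(self, t):
        return _dramp(t, self.params)

    def suggested_max_step(self) -> float:
        return (self.params.t_end - self.params.t_start) / 10.0


_KIND_MAP = {
    "sinusoid": (Sinusoid, SinusoidParams),
    "step": (Step, StepParams),
    "square": (Square, SquareParams),
    "ramp": (Ramp, RampParams),
}


def stimulus_from_dict(config: dict) -> PressureStimulus:
    """Build a stimulus from ``{"type": ..., "params": {...}}``."""
    try:
        kind = config["type"]
        raw = config["params"]
    except (KeyError, TypeError) as exc:
        raise ValueError("stimulus config must have 'type' and 'params'") from exc
    if kind not in _KIND_MAP:
        raise ValueError(f"unknown stimulus type {kind!r}")
    cls, params_cls = _KIND_MAP[kind]
    return cls(params_cls(**raw))


def stimulus_to_dict(stimulus: PressureStimulus) -> dict:
    return {"type": stimulus.kind, "params": asdict(stimulus.params)}
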