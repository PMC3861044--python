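"""Arterial wall deformation: pressure -> circumferential wall strain.

Three wall models are provided:

* ``LinearWall`` — thin-shell Laplace-law elasticity, strain proportional
  to pressure through a lumped compliance ``k_wall`` (1/mmHg).
* ``NonlinearWall`` — sigmoidal pressure-area relation with saturation at
  high and low pressure; strain follows from the area ratio.
* ``SLSWall`` — standard linear solid (Maxwell element in parallel with a
  spring), integrated with an exponential (integrating-factor) scheme.

All three are also expressible as a quasi-linear viscoelastic (QLV)
convolution of a creep kernel with the rate of an elastic response; see
:func:`qlv_strain_trajectory` and :func:`qlv_spec_for`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
from scipy.signal import fftconvolve

from baroafferent.stimuli import PressureStimulus

__all__ = [
    "LinearWallParams",
    "NonlinearWallParams",
    "SLSWallParams",
    "QLVSpec",
    "WallModel",
    "LinearWall",
    "NonlinearWall",
    "SLSWall",
    "linear_elastic_strain",
    "nonlinear_elastic_strain",
    "sls_strain_trajectory",
    "qlv_strain_trajectory",
    "qlv_spec_for",
    "wall_from_dict",
    "wall_to_dict",
]


@dataclass(frozen=True)
class LinearWallParams:
    """Lumped compliance ``k_wall = r0 / (E h)`` of the linear elastic wall."""

    k_wall: float

    def __post_init__(self) -> None:
        if self.k_wall <= 0:
            raise ValueError("k_wall must be > 0")


@dataclass(frozen=True)
class NonlinearWallParams:
    """Sigmoidal pressure-area wall.

    ``A(p) = A0 + (Am - A0) * p**k / (alpha**k + p**k)`` with strain
    ``sqrt(A/A0) - 1`` (zero deformation at zero transmural pressure).
    """

    A0: float
    Am: float
    alpha: float
    k: float

    def __post_init__(self) -> None:
        if not 0 < self.A0 < self.Am:
            raise ValueError("require Am > A0 > 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")


@dataclass(frozen=True)
class SLSWallParams:
    """Standard linear solid wall exposed through its identifiable quantities.

    ``tau_a`` is the strain-relaxation timescale, ``tau_b`` the stress
    (pressure) lead timescale; ``k_wall`` the static compliance.  The wall
    strain obeys ``tau_a * deps/dt = k_wall*(p + tau_b*dp/dt) - eps``.
    """

    k_wall: float
    tau_a: float
    tau_b: float

    def __post_init__(self) -> None:
        if self.k_wall <= 0:
            raise ValueError("k_wall must be > 0")
        if self.tau_a <= 0 or self.tau_b <= 0:
            raise ValueError("tau_a and tau_b must be > 0")


@dataclass(frozen=True)
class QLVSpec:
    """A (creep kernel, elastic response) pair for the QLV convolution.

    ``creep(t)`` is the unit-step creep function (finite at 0), and
    ``elastic_response(p)`` the instantaneous elastic strain with analytic
    pressure derivative ``d_elastic_dp(p)``.
    """

    creep: Callable[[np.ndarray], np.ndarray]
    elastic_response: Callable[[np.ndarray], np.ndarray]
    d_elastic_dp: Callable[[np.ndarray], np.ndarray]


def linear_elastic_strain(p, params: LinearWallParams):
    return params.k_wall * np.asarray(p, dtype=float)


def nonlinear_elastic_strain(p, params: NonlinearWallParams):
    p = np.asarray(p, dtype=float)
    A = _sigmoid_area(p, params)
    return np.sqrt(A / params.A0) - 1.0


def _sigmoid_area(p, params: NonlinearWallParams):
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(
            p > 0, p**params.k / (params.alpha**params.k + p**params.k), 0.0
        )
    return params.A0 + (params.Am - params.A0) * frac


def _d_nonlinear_strain_dp(p, params: NonlinearWallParams):
    p = np.asarray(p, dtype=float)
    A = _sigmoid_area(p, params)
    ak, k = params.alpha**params.k, params.k
    with np.errstate(divide="ignore", invalid="ignore"):
        dfrac = np.where(p > 0, k * ak * p ** (k - 1) / (ak + p**k) ** 2, 0.0)
    dA = (params.Am - params.A0) * dfrac
    return 0.5 * dA / np.sqrt(A * params.A0)


class WallModel:
    """Common interface of the wall stage used by composite models."""

    kind: str = ""
    #: True when the wall carries an internal ODE state (SLS).
    has_state: bool = False

    def __init__(self, params) -> None:
        self.params = params

    def static_strain(self, p):
        """Equilibrium (fully crept) strain at constant pressure ``p``."""
        raise NotImplementedError

    def d_static_strain_dp(self, p):
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.params})"


class LinearWall(WallModel):
    kind = "linear"

    def __init__(self, params: LinearWallParams) -> None:
        super().__init__(params)

    def static_strain(self, p):
        return linear_elastic_strain(p, self.params)

    def d_static_strain_dp(self, p):
        return np.broadcast_to(self.params.k_wall, np.shape(p)).astype(float)


class NonlinearWall(WallModel):
    kind = "nonlinear"

    def __init__(self, params: NonlinearWallParams) -> None:
        super().__init__(params)

    def static_strain(self, p):
        return nonlinear_elastic_strain(p, self.params)

    def d_static_strain_dp(self, p):
        return _d_nonlinear_strain_dp(p, self.params)


class SLSWall(WallModel):
    kind = "sls"
    has_state = True

    def __init__(self, params: SLSWallParams) -> None:
        super().__init__(params)

    def static_strain(self, p):
        return self.params.k_wall * np.asarray(p, dtype=float)

    def d_static_strain_dp(self, p):
        return np.broadcast_to(self.params.k_wall, np.shape(p)).astype(float)

    def forcing(self, p, dp):
        """Right-hand forcing ``k_wall*(p + tau_b*dp)`` of the strain ODE."""
        return self.params.k_wall * (
            np.asarray(p, dtype=float) + self.params.tau_b * np.asarray(dp, dtype=float)
        )

    def state_rhs(self, eps_w, p, dp):
        return (self.forcing(p, dp) - eps_w) / self.params.tau_a

    def initial_state(self, p0: float, dp0: float) -> float:
        """Relaxed-start strain: zero of the strain ODE at ``(p0, dp0)``."""
        return float(self.forcing(p0, dp0))


def sls_strain_trajectory(
    pressure: PressureStimulus,
    params: SLSWallParams,
    t_grid: np.ndarray,
    eps0: float | None = None,
    dt_max: float = 5e-4,
) -> np.ndarray:
    """Integrate the SLS wall strain along ``t_grid``.

    Uses the integrating-factor (exponential) form of the strain ODE with
    linear interpolation of the forcing over substeps, which is A-stable and
    exact for constant pressure.  ``eps0`` defaults to the relaxed value at
    the start of the grid.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    wall = SLSWall(params)
    tau = params.tau_a
    if eps0 is None:
        eps0 = wall.initial_state(
            float(pressure(t_grid[0])), float(pressure.derivative(t_grid[0]))
        )
    steps = np.diff(t_grid)
    uniform = t_grid.size > 1 and np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12)
    if uniform and steps[0] <= dt_max:
        # vectorized path: the exponential step is a first-order linear
        # recursion, evaluated with an IIR filter
        from scipy.signal import lfilter

        h = float(steps[0])
        a = h / tau
        E = np.exp(-a)
        psi = 1.0 - (1.0 - E) / a
        c0 = (1.0 - E) - psi
        u = wall.forcing(pressure(t_grid), pressure.derivative(t_grid))
        drive = c0 * u[:-1] + psi * u[1:]
        out = np.empty_like(t_grid)
        out[0] = float(eps0)
        filtered, _ = lfilter([1.0], [1.0, -E], drive, zi=np.array([E * eps0]))
        out[1:] = filtered
        return out

    out = np.empty_like(t_grid)
    out[0] = eps = float(eps0)
    for i in range(t_grid.size - 1):
        h_total = t_grid[i + 1] - t_grid[i]
        m = max(1, min(int(np.ceil(h_total / dt_max)), 100_000))
        sub = np.linspace(t_grid[i], t_grid[i + 1], m + 1)
        u = wall.forcing(pressure(sub), pressure.derivative(sub))
        h = h_total / m
        a = h / tau
        E = np.exp(-a)
        psi = 1.0 - (1.0 - E) / a  # weight on the right endpoint
        c0 = (1.0 - E) - psi
        for k in range(m):
            eps = E * eps + c0 * u[k] + psi * u[k + 1]
        out[i + 1] = eps
    return out


def qlv_strain_trajectory(
    spec: QLVSpec,
    pressure: PressureStimulus,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Quasi-linear viscoelastic strain by discrete creep convolution.

    Assumes relaxed preload: pressure held at its initial value for all
    earlier times, so the strain starts fully crept at the elastic value.
    The convolution of the creep kernel with the elastic-response rate is
    discretized by trapezoidal quadrature on a uniform grid.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must contain at least two points")
    dt = np.diff(t_grid)
    if np.any(dt <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise ValueError("qlv_strain_trajectory requires a uniform grid")
    h = float(dt[0])

    p = pressure(t_grid)
    dp = pressure.derivative(t_grid)
    rate = spec.d_elastic_dp(p) * dp  # d/dt of the elastic response
    kernel = np.asarray(spec.creep(t_grid - t_grid[0]), dtype=float)
    if not np.all(np.isfinite(kernel)):
        raise ValueError("creep kernel not evaluable on the required support")

    # cumulative trapezoid of K(t_i - s) * rate(s) over s in [t_0, t_i]
    full = fftconvolve(kernel, rate)[: t_grid.size]
    integral = h * (full - 0.5 * (kernel * rate[0] + kernel[0] * rate))

    eps_e0 = float(np.asarray(spec.elastic_response(p[0])))
    return eps_e0 + integral


def qlv_spec_for(wall: WallModel) -> QLVSpec:
    """The (creep, elastic response) pair reproducing ``wall`` under QLV."""
    if isinstance(wall, (LinearWall, NonlinearWall)):
        return QLVSpec(
            creep=lambda t: np.ones_like(np.asarray(t, dtype=float)),
            elastic_response=wall.static_strain,
            d_elastic_dp=wall.d_static_strain_dp,
        )
    if isinstance(wall, SLSWall):
        tau_a, tau_b = wall.params.tau_a, wall.params.tau_b

        def creep(t):
            t = np.asarray(t, dtype=float)
            return 1.0 - (1.0 - tau_b / tau_a) * np.exp(-t / tau_a)

        return QLVSpec(
            creep=creep,
            elastic_response=wall.static_strain,
            d_elastic_dp=wall.d_static_strain_dp,
        )
    raise TypeError(f"no QLV reduction registered for {type(wall).__name__}")


_KIND_MAP = {
    "linear": (LinearWall, LinearWallParams),
    "nonlinear": (NonlinearWall, NonlinearWallParams),
    "sls": (SLSWall, SLSWallParams),
}


def wall_from_dict(config: dict) -> WallModel:
    """Build a wall model from ``{"type": ..., "params": {...}}``."""
    try:
        kind = config["type"]
        raw = config["params"]
    except (KeyError, TypeError) as exc:
        raise ValueError("wall config must have 'type' and 'params'") from exc
    if kind not in _KIND_MAP:
        raise ValueError(f"unknown wall type {kind!r}")
    cls, params_cls = _KIND_MAP[kind]
    return cls(params_cls(**raw))


def wall_to_dict(wall: WallModel) -> dict:
    return {"type": wall.kind, "params": asdict(wall.params)}
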