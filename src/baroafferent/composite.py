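"""Composite baroreceptor models: pressure stimulus -> firing-rate trace.

A composite model couples a wall model, a Voigt-body chain, and a neuron
into an algebraic-differential system: differential equations enter only
through the mechanoreceptor chain (and the SLS wall strain when present);
wall strain and firing rate are algebraic along the solution.

Six named configurations are first-class (three linear-wall chains with a
linear neuron, the SLS wall with two Voigt bodies and a linear neuron, and
the nonlinear wall with two Voigt bodies and either neuron); any other
combination simulates fine but is flagged as non-canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from baroafferent import mechanoreceptors as mech
from baroafferent.mechanoreceptors import VoigtChainParams, chain_from_dict, chain_to_dict
from baroafferent.neurons import NeuronModel, neuron_from_dict, neuron_to_dict
from baroafferent.stimuli import PressureStimulus
from baroafferent.wall_models import SLSWall, WallModel, wall_from_dict, wall_to_dict

__all__ = [
    "CompositeModel",
    "SimulationResult",
    "CANONICAL_MODELS",
    "assemble",
    "model_from_dict",
    "model_to_dict",
    "steady_initial_conditions",
    "simulate",
]

#: The six canonical (wall kind, n Voigt bodies, neuron kind) combinations.
CANONICAL_MODELS = {
    ("linear", 1, "linear"): "LE-V1-L",
    ("linear", 2, "linear"): "LE-V2-L",
    ("linear", 3, "linear"): "LE-V3-L",
    ("sls", 2, "linear"): "LVE-V2-L",
    ("nonlinear", 2, "linear"): "NLE-V2-L",
    ("nonlinear", 2, "integrate_fire"): "NLE-V2-IF",
}


@dataclass
class CompositeModel:
    wall: WallModel
    chain: VoigtChainParams
    neuron: NeuronModel
    name: str

    @property
    def signature(self) -> tuple:
        return (self.wall.kind, self.chain.n, self.neuron.kind)

    @property
    def canonical(self) -> bool:
        return self.signature in CANONICAL_MODELS

    @property
    def n_states(self) -> int:
        return self.chain.n + (1 if self.wall.has_state else 0)


@dataclass
class SimulationResult:
    """Trajectories along the output grid; all arrays share one length.

    ``states`` holds the raw ODE states (row per state) when the result
    comes from :func:`simulate`; it is ``None`` for traces read from disk.
    """

    t: np.ndarray
    pressure: np.ndarray
    eps_w: np.ndarray
    eps_ne: np.ndarray
    f: np.ndarray
    states: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        if not all(len(a) == n for a in (self.pressure, self.eps_w, self.eps_ne, self.f)):
            raise ValueError("all trajectory arrays must share one length")
        if self.states is not None and self.states.shape[-1] != n:
            raise ValueError("states must have one column per time point")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "pressure_mmhg": self.pressure,
                "wall_strain": self.eps_w,
                "ne_strain": self.eps_ne,
                "firing_hz": self.f,
            }
        )


def assemble(wall_kind: str, n_voigt: int, neuron_kind: str, params: dict) -> CompositeModel:
    """Build a composite model from component kinds and a nested params dict.

    ``params`` carries one block per component: ``{"wall": {...},
    "chain": {...}, "neuron": {...}}`` (chain length must match
    ``n_voigt``).  Combinations outside the canonical table are accepted
    but carry a generated, non-canonical name.
    """
    for block in ("wall", "chain", "neuron"):
        if block not in params:
            raise ValueError(f"missing parameter block {block!r}")
    wall = wall_from_dict({"type": wall_kind, "params": params["wall"]})
    chain = chain_from_dict(params["chain"])
    if chain.n != n_voigt:
        raise ValueError(f"chain parameters have n={chain.n}, expected {n_voigt}")
    neuron = neuron_from_dict({"type": neuron_kind, "params": params["neuron"]})
    signature = (wall_kind, n_voigt, neuron_kind)
    name = CANONICAL_MODELS.get(signature, f"custom-{wall_kind}-v{n_voigt}-{neuron_kind}")
    return CompositeModel(wall=wall, chain=chain, neuron=neuron, name=name)


def model_from_dict(config: dict) -> CompositeModel:
    wall = wall_from_dict(config["wall"])
    chain = chain_from_dict(config["chain"])
    neuron = neuron_from_dict(config["neuron"])
    signature = (wall.kind, chain.n, neuron.kind)
    name = config.get(
        "name", CANONICAL_MODELS.get(signature, f"custom-{wall.kind}-v{chain.n}-{neuron.kind}")
    )
    return CompositeModel(wall=wall, chain=chain, neuron=neuron, name=name)


def model_to_dict(model: CompositeModel) -> dict:
    return {
        "name": model.name,
        "wall": wall_to_dict(model.wall),
        "chain": chain_to_dict(model.chain),
        "neuron": neuron_to_dict(model.neuron),
    }


def steady_initial_conditions(
    model: CompositeModel, p0: float, dp0: float = 0.0
) -> np.ndarray:
    """Relaxed-start state: every state derivative vanishes at ``(p0, dp0)``.

    For the SLS wall the relaxed strain is ``k_wall*(p0 + tau_b*dp0)`` (the
    zero of its strain ODE); elastic walls contribute no state.  The chain
    is then placed at its closed-form steady state for that wall strain.
    """
    if model.wall.has_state:
        assert isinstance(model.wall, SLSWall)
        eps_w0 = model.wall.initial_state(p0, dp0)
        chain0 = mech.steady_state(eps_w0, model.chain)
        return np.concatenate([chain0, [eps_w0]])
    eps_w0 = float(np.asarray(model.wall.static_strain(p0)))
    return mech.steady_state(eps_w0, model.chain)


def _build_rhs_jac(model: CompositeModel, stimulus: PressureStimulus):
    A, b = mech.chain_matrices(model.chain)
    n = model.chain.n
    if model.wall.has_state:
        wall: SLSWall = model.wall  # type: ignore[assignment]
        tau_a = wall.params.tau_a
        J = np.zeros((n + 1, n + 1))
        J[:n, :n] = A
        J[:n, n] = b
        J[n, n] = -1.0 / tau_a

        def rhs(t, y):
            eps_w = y[n]
            dy = np.empty(n + 1)
            dy[:n] = A @ y[:n] + b * eps_w
            dy[n] = (wall.forcing(stimulus(t), stimulus.derivative(t)) - eps_w) / tau_a
            return dy

    else:
        J = A

        def rhs(t, y):
            eps_w = float(np.asarray(model.wall.static_strain(stimulus(t))))
            return A @ y + b * eps_w

    return rhs, (lambda t, y: J)


def simulate(
    model: CompositeModel,
    stimulus: PressureStimulus,
    t_grid: np.ndarray,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "LSODA",
    max_step: float | None = None,
) -> SimulationResult:
    """Integrate the composite model and evaluate its outputs on ``t_grid``.

    ``y0`` defaults to the relaxed state for the stimulus value and slope
    at the start of the grid.  A stiff-capable integrator is used since the
    chain rates ``beta_i`` may be spread by more than an order of
    magnitude; the (constant) Jacobian is supplied analytically.
    ``max_step`` keeps the solver from striding across narrow stimulus
    transitions (e.g. steep tanh steps) after long quiescent stretches; by
    default it is taken from ``stimulus.suggested_max_step()``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if y0 is None:
        y0 = steady_initial_conditions(
            model, float(stimulus(t_grid[0])), float(stimulus.derivative(t_grid[0]))
        )
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (model.n_states,):
        raise ValueError(f"y0 must have shape ({model.n_states},)")

    if max_step is None:
        max_step = stimulus.suggested_max_step()
    rhs, jac = _build_rhs_jac(model, stimulus)
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        jac=jac if method in ("LSODA", "BDF", "Radau") else None,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration of model {model.name!r} failed: {sol.message} "
            f"(reached t={sol.t[-1] if sol.t.size else t_grid[0]:.4g})"
        )

    n = model.chain.n
    pressure = np.asarray(stimulus(t_grid), dtype=float)
    if model.wall.has_state:
        eps_w = sol.y[n]
    else:
        eps_w = np.asarray(model.wall.static_strain(pressure), dtype=float)
    eps_ne = eps_w - sol.y[0]
    f = np.asarray(model.neuron.firing_rate(eps_ne), dtype=float)
    return SimulationResult(
        t=t_grid, pressure=pressure, eps_w=eps_w, eps_ne=eps_ne, f=f, states=sol.y
    )
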