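"""Mechanoreceptor coupling: wall strain -> nerve-ending strain.

The nerve ending is modelled as a spring (elasticity of the ending itself)
in series with ``n`` Voigt bodies (spring ``K_i`` parallel to dashpot
``B_i``) representing the viscoelastic connective tissue, ``n`` in
{1, 2, 3}.  Only the rate coefficients

    ``alpha_i = K / B_i``  and  ``beta_i = K_i / B_i``   (1/s)

are identifiable, not the raw spring/dashpot constants.  The state
``eps_i`` is the cumulative strain carried by Voigt bodies ``i..n``, so the
spring strain sensed by the mechanoreceptors is ``eps_ne = eps_w - eps_1``.

Force balance along the series chain gives the linear time-invariant system

    ``d(eps_i)/dt = (sum_{j>=i} alpha_j) (eps_w - eps_1)
                    - sum_{j>=i} beta_j (eps_j - eps_{j+1})``

with ``eps_{n+1} = 0``.  Each Voigt body contributes one relaxation
timescale; the timescales are the (positive) roots of ``det(I + tau*A)``
where ``A`` is the state matrix, for which closed-form coefficient
expressions in alpha/beta are used below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoigtChainParams",
    "ChainState",
    "chain_matrices",
    "chain_rhs",
    "nerve_ending_strain",
    "relaxation_timescales",
    "timescale_polynomial",
    "steady_state",
    "dc_gain",
    "chain_from_dict",
    "chain_to_dict",
]


@dataclass(frozen=True)
class VoigtChainParams:
    """Rate coefficients of an ``n``-Voigt-body chain, ``n`` in {1, 2, 3}."""

    alpha: tuple
    beta: tuple

    def __post_init__(self) -> None:
        alpha = tuple(float(a) for a in self.alpha)
        beta = tuple(float(b) for b in self.beta)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        if len(alpha) != len(beta):
            raise ValueError("alpha and beta must have equal length")
        if len(alpha) not in (1, 2, 3):
            raise ValueError("chain supports n in {1, 2, 3} Voigt bodies")
        if any(a <= 0 for a in alpha) or any(b <= 0 for b in beta):
            raise ValueError("all alpha_i and beta_i must be > 0")

    @property
    def n(self) -> int:
        return len(self.alpha)


#: Alias documenting the state layout: ChainState[i-1] = eps_i, the
#: cumulative strain of Voigt bodies i..n.
ChainState = np.ndarray


def chain_matrices(params: VoigtChainParams) -> tuple[np.ndarray, np.ndarray]:
    """State matrix ``A`` and input vector ``b``: ``d(state)/dt = A@state + b*eps_w``."""
    n = params.n
    al, be = np.asarray(params.alpha), np.asarray(params.beta)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(n):
        s_i = al[i:].sum()
        A[i, 0] -= s_i
        A[i, i] -= be[i]
        for j in range(i + 1, n):
            A[i, j] -= be[j] - be[j - 1]
        b[i] = s_i
    return A, b


def chain_rhs(state: ChainState, eps_w: float, params: VoigtChainParams) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (params.n,):
        raise ValueError(f"state must have shape ({params.n},), got {state.shape}")
    A, b = chain_matrices(params)
    return A @ state + b * eps_w


def nerve_ending_strain(state: ChainState, eps_w):
    """Strain sensed by the mechanoreceptors: ``eps_ne = eps_w - eps_1``."""
    state = np.atleast_2d(np.asarray(state, dtype=float))
    return np.asarray(eps_w, dtype=float) - np.squeeze(state[..., 0])


def timescale_polynomial(params: VoigtChainParams) -> np.ndarray:
    """Coefficients (highest power first) of the timescale polynomial.

    Relaxation timescales are the roots of ``det(I + tau*A) = 0``.  The
    coefficients are closed-form symmetric functions of alpha and beta;
    note every product mixing ``alpha_i`` with its own ``beta_i`` or with
    another ``alpha_j`` drops out.
    """
    al, be = params.alpha, params.beta
    n = params.n
    if n == 1:
        a1, b1 = al[0], be[0]
        return np.array([-(a1 + b1), 1.0])
    if n == 2:
        (a1, a2), (b1, b2) = al, be
        return np.array(
            [a1 * b2 + a2 * b1 + b1 * b2, -(a1 + a2 + b1 + b2), 1.0]
        )
    (a1, a2, a3), (b1, b2, b3) = al, be
    c1 = a1 + a2 + a3 + b1 + b2 + b3
    c2 = (
        a1 * (b2 + b3)
        + a2 * (b1 + b3)
        + a3 * (b1 + b2)
        + b1 * b2
        + b1 * b3
        + b2 * b3
    )
    c3 = a1 * b2 * b3 + a2 * b1 * b3 + a3 * b1 * b2 + b1 * b2 * b3
    return np.array([-c3, c2, -c1, 1.0])


def relaxation_timescales(params: VoigtChainParams) -> np.ndarray:
    """Relaxation timescales (s) of the chain, sorted ascending.

    Uses the closed-form characteristic polynomial; falls back to the
    eigenvalues of the state matrix (with a warning) when roots come out
    numerically complex, which happens only for near-coincident ``beta_i``.
    """
    if params.n == 1:
        return np.array([1.0 / (params.alpha[0] + params.beta[0])])
    roots = np.roots(timescale_polynomial(params))
    if np.any(np.abs(roots.imag) > 1e-9 * np.abs(roots).max()):
        warnings.warn(
            "timescale polynomial has complex roots (near-coincident "
            "beta_i); falling back to state-matrix eigenvalues",
            stacklevel=2,
        )
        A, _ = chain_matrices(params)
        roots = -1.0 / np.linalg.eigvals(A)
    roots = roots.real
    if np.any(roots <= 0):
        raise ValueError("invalid parameter regime: non-positive timescales")
    return np.sort(roots)


def steady_state(eps_w_const: float, params: VoigtChainParams) -> ChainState:
    """Chain state at which all derivatives vanish for constant wall strain.

    Closed form from the series force balance: at rest the common tension
    gives each Voigt body the strain ``(alpha_j / beta_j) * eps_ne`` with
    ``eps_ne = eps_w / (1 + sum_j alpha_j / beta_j)``, and the states are
    the tail sums of those element strains.
    """
    al, be = np.asarray(params.alpha), np.asarray(params.beta)
    ratio = al / be
    eps_ne = float(eps_w_const) / (1.0 + ratio.sum())
    return np.cumsum(ratio[::-1])[::-1] * eps_ne


def dc_gain(params: VoigtChainParams) -> float:
    """Static gain of ``eps_ne`` with respect to ``eps_w`` (strictly in (0, 1))."""
    ratio = np.asarray(params.alpha) / np.asarray(params.beta)
    return 1.0 / (1.0 + ratio.sum())


def chain_from_dict(config: dict) -> VoigtChainParams:
    """Build chain parameters from ``{"n": ..., "alpha": [...], "beta": [...]}``."""
    try:
        alpha, beta = config["alpha"], config["beta"]
    except (KeyError, TypeError) as exc:
        raise ValueError("chain config must have 'alpha' and 'beta'") from exc
    params = VoigtChainParams(alpha=tuple(alpha), beta=tuple(beta))
    if "n" in config and int(config["n"]) != params.n:
        raise ValueError("'n' inconsistent with alpha/beta length")
    return params


def chain_to_dict(params: VoigtChainParams) -> dict:
    return {"n": params.n, "alpha": list(params.alpha), "beta": list(params.beta)}
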