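"""Detectors for qualitative firing-rate phenomena.

Each detector is a deterministic function of an already computed
:class:`~baroafferent.composite.SimulationResult`; detectors never
re-simulate.  Firing below ``ZERO_RATE_TOL`` counts as silence — exact
zeros come from the integrate-and-fire sub-threshold branch, the tolerance
only guards float noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from baroafferent.composite import SimulationResult

__all__ = [
    "FeatureReport",
    "ZERO_RATE_TOL",
    "detect_threshold",
    "detect_saturation",
    "ped_silence_duration",
    "hysteresis_area",
    "fit_exponential_decay",
    "adaptation_exponential_count",
    "detect_rectification",
]

#: Firing rates below this (Hz) count as silence.
ZERO_RATE_TOL = 1e-9


@dataclass
class FeatureReport:
    threshold_pressure: float | None = None
    saturation_rate: float | None = None
    ped_silence: float = 0.0
    hysteresis_area: float = 0.0
    adaptation_exponentials: int | None = None
    rectified: bool = False
    min_firing: float = 0.0


def detect_threshold(sim: SimulationResult) -> float | None:
    """Threshold pressure on a monotone pressure ramp.

    Returns the lowest pressure at which firing turns on and stays on for
    the remainder of the ramp ("sustained"), or ``None`` when the trace
    never fires or never falls silent.
    """
    silent = sim.f < ZERO_RATE_TOL
    if not silent.any() or silent.all():
        return None
    # sustained firing on a monotone ramp: everything past the last silent
    # sample (avoids onset-flicker heuristics)
    last_silent = int(np.max(np.nonzero(silent)))
    if last_silent + 1 >= sim.f.size:
        return None
    return float(sim.pressure[last_silent + 1])


def detect_saturation(
    sim: SimulationResult, slope_fraction: float = 0.05
) -> float | None:
    """Plateau firing rate under a ramp reaching high pressure.

    Saturation is declared when the terminal slope df/dp falls below
    ``slope_fraction`` of the maximal slope along the firing portion; the
    returned level is the terminal firing rate.  ``None`` when no plateau.
    """
    firing = sim.f > ZERO_RATE_TOL
    if firing.sum() < 5:
        return None
    f = sim.f[firing]
    p = sim.pressure[firing]
    dp = np.gradient(p)
    if np.any(dp == 0):
        return None
    slope = np.gradient(f) / dp
    terminal = slope[-3:].mean()
    if abs(terminal) < slope_fraction * np.max(np.abs(slope)):
        return float(f[-1])
    return None


def ped_silence_duration(sim: SimulationResult, t_after: float) -> float:
    """Length (s) of the longest contiguous silent interval after ``t_after``."""
    mask = sim.t >= t_after
    t = sim.t[mask]
    silent = sim.f[mask] < ZERO_RATE_TOL
    best = 0.0
    start = None
    for i, s in enumerate(silent):
        if s and start is None:
            start = i
        elif not s and start is not None:
            best = max(best, t[i - 1] - t[start])
            start = None
    if start is not None:
        best = max(best, t[-1] - t[start])
    return float(best)


def hysteresis_area(sim: SimulationResult, close_loop: bool = True) -> float:
    """Signed shoelace area of the (pressure, firing) loop (mmHg*Hz).

    The trace must cover one complete up-down pressure cycle; with
    ``close_loop`` the last point is joined back to the first.
    """
    p, f = sim.pressure, sim.f
    if p.size < 3:
        raise ValueError("incomplete cycle: need at least three points")
    if close_loop:
        p = np.append(p, p[0])
        f = np.append(f, f[0])
    return float(0.5 * np.sum(p[:-1] * f[1:] - p[1:] * f[:-1]))


def fit_exponential_decay(t: np.ndarray, y: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    """Least-squares fit of ``y ~ c0 + sum_i c_i exp(-t/tau_i)``.

    Returns ``(residual_norm, taus)``.  Amplitudes are solved linearly for
    each candidate set of rates (variable projection), so only the ``k``
    timescales are nonlinear unknowns.
    """
    t = np.asarray(t, dtype=float) - t[0]
    y = np.asarray(y, dtype=float)
    span = t[-1] if t[-1] > 0 else 1.0

    def design(log_taus):
        taus = np.exp(log_taus)
        return np.column_stack([np.ones_like(t)] + [np.exp(-t / tau) for tau in taus])

    def resid(log_taus):
        X = design(log_taus)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X @ coef - y

    # spread the initial guesses log-uniformly over the segment span
    x0 = np.log(span * np.logspace(-1.5, 0, k))
    sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
    return float(np.linalg.norm(sol.fun)), np.sort(np.exp(sol.x))


def adaptation_exponential_count(
    sim: SimulationResult,
    t_start: float,
    t_end: float | None = None,
    rel_tol: float = 5e-3,
    k_max: int = 3,
) -> tuple[int, dict]:
    """Smallest number of exponentials resolving the post-overshoot decay.

    Fits ``k = 1..k_max`` decaying exponentials (plus offset) to the firing
    trace on ``[t_start, t_end]`` and returns the smallest ``k`` whose
    residual norm drops below ``rel_tol`` times the norm of the centred
    signal, together with the per-``k`` residuals for inspection.
    """
    mask = sim.t >= t_start
    if t_end is not None:
        mask &= sim.t <= t_end
    t, y = sim.t[mask], sim.f[mask]
    if t.size < 10:
        raise ValueError("decay segment too short")
    if y[0] <= y[-1]:
        raise ValueError("segment is not a decay")
    scale = np.linalg.norm(y - y.mean())
    residual_by_k = {}
    chosen = k_max
    for k in range(1, k_max + 1):
        res, _ = fit_exponential_decay(t, y, k)
        residual_by_k[k] = res
        if res <= rel_tol * scale and chosen == k_max:
            chosen = k
            # keep filling residual_by_k for diagnostics
    return chosen, residual_by_k


def detect_rectification(
    sim: SimulationResult, period: float, n_cycles_required: int = 3
) -> tuple[bool, float]:
    """Per-cycle silence under a periodic stimulus.

    Returns ``(rectified, min_firing)``.  Rectified is True iff every full
    cycle in the trace contains both a silent sub-interval and positive
    firing elsewhere.  ``min_firing`` documents negative excursions of
    unclamped linear neurons (which never count as rectification).
    """
    t0, t1 = sim.t[0], sim.t[-1]
    n_cycles = int(np.floor((t1 - t0) / period))
    min_firing = float(sim.f.min())
    if n_cycles < n_cycles_required:
        return False, min_firing
    rectified = True
    for c in range(n_cycles):
        mask = (sim.t >= t0 + c * period) & (sim.t < t0 + (c + 1) * period)
        f = sim.f[mask]
        silent = f < ZERO_RATE_TOL
        has_silence = bool(silent.any()) and bool((f[silent] > -ZERO_RATE_TOL).all())
        has_firing = bool((f > ZERO_RATE_TOL).any())
        if not (has_silence and has_firing):
            rectified = False
            break
    return rectified, min_firing
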