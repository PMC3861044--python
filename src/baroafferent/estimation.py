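"""Parameter estimation and identifiability analysis.

Workflow mirrored by the public operations:

1. :func:`residuals` — pointwise model-data mismatch normalized by the
   dataset's mean firing rate; :func:`cost_rmse` / :func:`r_squared` for
   fit quality.
2. :func:`sensitivities` — central finite-difference output sensitivities,
   by default with respect to log-scaled parameters
   ``theta = theta_nominal * exp(x)`` (enforces positivity and conditions
   the optimization).
3. :func:`rank_and_select` — two-norm ranking, QR-SVD subset ordering and
   covariance-based correlation pruning down to an identifiable subset.
4. :func:`fit` / :func:`fit_simultaneous` — Levenberg-Marquardt for smooth
   models, Nelder-Mead for models with the discontinuous
   integrate-and-fire output map.

Parameters are addressed by flat names: chain rates ``alpha1..alpha3``,
``beta1..beta3``; neuron constants by field name (``s1``, ``s2``, ...);
wall constants prefixed ``wall.`` and stimulus constants ``stim.``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from baroafferent.composite import CompositeModel, model_from_dict, model_to_dict, simulate
from baroafferent.stimuli import PressureStimulus, stimulus_from_dict, stimulus_to_dict

__all__ = [
    "Dataset",
    "SensitivityReport",
    "FitResult",
    "get_parameters",
    "apply_parameters",
    "residuals",
    "cost_rmse",
    "r_squared",
    "sensitivities",
    "rank_and_select",
    "fit",
    "fit_simultaneous",
]

_CHAIN_RE = re.compile(r"^(alpha|beta)([123])$")


@dataclass
class Dataset:
    """An observed firing-rate time series."""

    t: np.ndarray
    f_obs: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_obs = np.asarray(self.f_obs, dtype=float)
        if self.t.shape != self.f_obs.shape or self.t.ndim != 1 or self.t.size == 0:
            raise ValueError("t and f_obs must be equal-length 1-D arrays")

    @property
    def f_mean(self) -> float:
        """Average firing rate of the set, used to normalize residuals."""
        m = float(np.mean(self.f_obs))
        if m <= 0:
            raise ValueError("dataset mean firing rate must be > 0")
        return m


@dataclass
class SensitivityReport:
    """Time-resolved sensitivities plus the selection outcome."""

    names: tuple
    t: np.ndarray
    S: np.ndarray  # shape (len(t), len(names))
    scale: str
    magnitudes: dict = field(default_factory=dict)
    ranking: tuple = ()
    correlation: np.ndarray | None = None
    correlation_names: tuple = ()
    selected: tuple = ()
    fixed: tuple = ()


@dataclass
class FitResult:
    estimates: dict
    rmse: float
    rmse_hz: float
    r2: float
    method: str
    n_iter: int
    n_fev: int
    converged: bool
    cost_trace: list = field(default_factory=list)
    message: str = ""


# ---------------------------------------------------------------------------
# flat parameter access


def get_parameters(
    model: CompositeModel, stimulus: PressureStimulus | None = None
) -> dict:
    """Flat name -> value mapping over model (and optionally stimulus) parameters."""
    cfg = model_to_dict(model)
    theta: dict[str, float] = {}
    for key, val in cfg["wall"]["params"].items():
        theta[f"wall.{key}"] = float(val)
    for i, (a, b) in enumerate(zip(cfg["chain"]["alpha"], cfg["chain"]["beta"]), start=1):
        theta[f"alpha{i}"] = float(a)
        theta[f"beta{i}"] = float(b)
    for key, val in cfg["neuron"]["params"].items():
        theta[key] = float(val)
    if stimulus is not None:
        for key, val in stimulus_to_dict(stimulus)["params"].items():
            if isinstance(val, bool):
                continue
            theta[f"stim.{key}"] = float(val)
    return theta


def apply_parameters(
    model: CompositeModel,
    stimulus: PressureStimulus,
    theta: dict,
) -> tuple[CompositeModel, PressureStimulus]:
    """Return copies of model and stimulus with ``theta`` entries applied."""
    cfg = model_to_dict(model)
    stim_cfg = stimulus_to_dict(stimulus)
    for name, value in theta.items():
        value = float(value)
        m = _CHAIN_RE.match(name)
        if m is not None:
            kind, idx = m.group(1), int(m.group(2)) - 1
            if idx >= len(cfg["chain"][kind]):
                raise KeyError(f"chain has no parameter {name!r}")
            cfg["chain"][kind][idx] = value
        elif name.startswith("wall."):
            key = name[5:]
            if key not in cfg["wall"]["params"]:
                raise KeyError(f"wall has no parameter {key!r}")
            cfg["wall"]["params"][key] = value
        elif name.startswith("stim."):
            key = name[5:]
            if key not in stim_cfg["params"]:
                raise KeyError(f"stimulus has no parameter {key!r}")
            stim_cfg["params"][key] = value
        else:
            if name not in cfg["neuron"]["params"]:
                raise KeyError(f"unknown parameter {name!r}")
            cfg["neuron"]["params"][name] = value
    return model_from_dict(cfg), stimulus_from_dict(stim_cfg)


# ---------------------------------------------------------------------------
# residuals and cost


def residuals(
    model: CompositeModel,
    stimulus: PressureStimulus,
    dataset: Dataset,
    theta: dict | None = None,
    **sim_kw,
) -> np.ndarray:
    """Pointwise residuals ``(f_model - f_obs) / f_mean``."""
    if theta:
        model, stimulus = apply_parameters(model, stimulus, theta)
    sim = simulate(model, stimulus, dataset.t, **sim_kw)
    return (sim.f - dataset.f_obs) / dataset.f_mean


def cost_rmse(r: np.ndarray) -> float:
    """Root-mean-square of the (normalized) residual vector."""
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("residual vector is empty")
    return float(np.sqrt(np.mean(r**2)))


def r_squared(f_model: np.ndarray, f_obs: np.ndarray) -> float:
    """Coefficient of determination of the model against the observations."""
    f_model = np.asarray(f_model, dtype=float)
    f_obs = np.asarray(f_obs, dtype=float)
    ss_res = np.sum((f_obs - f_model) ** 2)
    ss_tot = np.sum((f_obs - np.mean(f_obs)) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return float(1.0 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# sensitivities and subset selection


def _simulate_f(model, stimulus, t_grid, **sim_kw):
    return simulate(model, stimulus, t_grid, **sim_kw).f


def sensitivities(
    model: CompositeModel,
    stimulus: PressureStimulus,
    names: tuple | list,
    t_grid: np.ndarray,
    h: float = 1e-4,
    scale: str = "log",
    f_mean: float | None = None,
    **sim_kw,
) -> SensitivityReport:
    """Central finite-difference sensitivities of the firing rate.

    ``scale="log"`` perturbs ``x`` in ``theta = theta0 * exp(x)`` by ``+-h``
    (the estimation coordinates); ``scale="linear"`` perturbs ``theta``
    itself by a relative step ``h``.  The step is chosen well above the
    square root of the 1e-8 integration tolerance so truncation and solver
    error stay balanced.  When ``f_mean`` is given the columns are
    normalized by it, matching the residual scaling.
    """
    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")
    t_grid = np.asarray(t_grid, dtype=float)
    theta0 = get_parameters(model, stimulus)
    names = tuple(names)
    for name in names:
        if name not in theta0:
            raise KeyError(f"unknown parameter {name!r}")
        if theta0[name] == 0:
            raise ValueError(f"cannot rescale parameter {name!r} with zero nominal")
    cols = []
    for name in names:
        base = theta0[name]
        hi = base * np.exp(h) if scale == "log" else base * (1.0 + h)
        lo = base * np.exp(-h) if scale == "log" else base * (1.0 - h)
        f_hi = _simulate_f(*apply_parameters(model, stimulus, {name: hi}), t_grid, **sim_kw)
        f_lo = _simulate_f(*apply_parameters(model, stimulus, {name: lo}), t_grid, **sim_kw)
        denom = 2.0 * h if scale == "log" else hi - lo
        cols.append((f_hi - f_lo) / denom)
    S = np.column_stack(cols) if cols else np.empty((t_grid.size, 0))
    if f_mean is not None:
        S = S / f_mean
    mags = {n: float(np.linalg.norm(S[:, j]) / np.sqrt(t_grid.size)) for j, n in enumerate(names)}
    ranking = tuple(sorted(names, key=lambda n: -mags[n]))
    return SensitivityReport(
        names=names, t=t_grid, S=S, scale=scale, magnitudes=mags, ranking=ranking
    )


def _correlation_matrix(S: np.ndarray) -> np.ndarray:
    """Correlations from the covariance ``C = sigma^2 (S^T S)^-1``.

    The noise variance cancels in the correlation coefficients, so it is
    not needed here; callers estimating absolute covariances should scale
    by the residual variance at the current iterate.
    """
    M = S.T @ S
    C = np.linalg.pinv(M)
    d = np.sqrt(np.diag(C))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = C / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def rank_and_select(
    report: SensitivityReport,
    gamma: float = 0.9,
    rank_tol: float = 1e-8,
    insensitive_tol: float = 1e-10,
) -> tuple:
    """Select an identifiable parameter subset; updates ``report`` in place.

    Steps: discard parameters with (relatively) negligible sensitivity;
    order the rest by QR with column pivoting applied to the leading
    right-singular subspace of the sensitivity matrix (truncated at its
    numerical rank); then grow the subset greedily in pivot order,
    admitting a parameter only while every pairwise correlation magnitude
    within the candidate subset stays at or below ``gamma``.  A skipped
    (correlated) parameter is the less sensitive member of its offending
    pair by construction, since pivoting visits dominant columns first.
    """
    S, names = report.S, list(report.names)
    mags = report.magnitudes
    top = max(mags.values(), default=0.0)
    fixed = [n for n in names if top == 0 or mags[n] <= insensitive_tol * top]
    active = [n for n in names if n not in fixed]
    if not active:
        report.selected, report.fixed = (), tuple(fixed)
        return ()
    idx = [names.index(n) for n in active]
    Sa = S[:, idx]

    # QR-SVD ordering: numerical rank from the SVD, importance order from
    # pivoted QR of the leading right-singular vectors.
    _, sv, Vt = np.linalg.svd(Sa, full_matrices=False)
    rank = int(np.sum(sv > rank_tol * sv[0]))
    _, _, piv = _pivoted_qr(Vt[:rank, :])
    ordered = [active[j] for j in piv]
    fixed += ordered[rank:]

    selected: list[str] = []
    for name in ordered[:rank]:
        cand = selected + [name]
        cand_idx = [names.index(n) for n in cand]
        corr = _correlation_matrix(S[:, cand_idx])
        iu = np.triu_indices(len(cand), k=1)
        if len(cand) == 1 or np.all(np.abs(corr[iu]) <= gamma):
            selected.append(name)
        else:
            fixed.append(name)

    sel_idx = [names.index(n) for n in selected]
    report.correlation = _correlation_matrix(S[:, sel_idx]) if selected else None
    report.correlation_names = tuple(selected)
    report.selected = tuple(selected)
    report.fixed = tuple(fixed)
    return report.selected


def _pivoted_qr(B: np.ndarray):
    from scipy.linalg import qr

    return qr(B, pivoting=True, mode="economic")


# ---------------------------------------------------------------------------
# fitting


def _make_objective(model, stimulus, datasets, subset, sim_kw):
    """Residual function of the log-scale coordinates x (theta = theta0*exp(x))."""
    pairs = [(stimulus, d) for d in datasets] if isinstance(stimulus, PressureStimulus) else list(zip(stimulus, datasets))
    theta0 = get_parameters(model, pairs[0][0])
    nominal = np.array([theta0[n] for n in subset])

    def theta_of(x):
        return dict(zip(subset, nominal * np.exp(x)))

    def resid(x):
        th = theta_of(x)
        out = []
        for stim, ds in pairs:
            out.append(residuals(model, stim, ds, theta=th, **sim_kw))
        return np.concatenate(out)

    return resid, theta_of, pairs


def _finalize(model, stimulus, datasets, subset, theta_hat, resid_fun, x_hat, method,
              n_iter, n_fev, converged, cost_trace, message, sim_kw):
    r = resid_fun(x_hat)
    rmse = cost_rmse(r)
    f_obs_all = np.concatenate([d.f_obs for d in datasets])
    f_mod_all = np.concatenate(
        [
            _simulate_f(*apply_parameters(model, stim, theta_hat), d.t, **sim_kw)
            for stim, d in ([(stimulus, d) for d in datasets] if isinstance(stimulus, PressureStimulus) else zip(stimulus, datasets))
        ]
    )
    rmse_hz = float(np.sqrt(np.mean((f_mod_all - f_obs_all) ** 2)))
    return FitResult(
        estimates=theta_hat,
        rmse=rmse,
        rmse_hz=rmse_hz,
        r2=r_squared(f_mod_all, f_obs_all),
        method=method,
        n_iter=n_iter,
        n_fev=n_fev,
        converged=converged,
        cost_trace=cost_trace,
        message=message,
    )


def fit(
    model: CompositeModel,
    stimulus: PressureStimulus,
    dataset: Dataset,
    subset: tuple | list,
    method: str = "lm",
    xtol: float = 1e-10,
    max_nfev: int | None = None,
    **sim_kw,
) -> FitResult:
    """Estimate the ``subset`` parameters on log scale from one dataset.

    ``method="lm"`` (Levenberg-Marquardt) requires a smooth model output
    and is refused for integrate-and-fire neurons, whose thresholded rate
    map is discontinuous; use ``method="nelder-mead"`` there.
    """
    return fit_simultaneous(model, [stimulus], [dataset], subset, method=method,
                            xtol=xtol, max_nfev=max_nfev, **sim_kw)


def fit_simultaneous(
    model: CompositeModel,
    stimuli_list,
    datasets,
    subset: tuple | list,
    method: str = "lm",
    xtol: float = 1e-10,
    max_nfev: int | None = None,
    **sim_kw,
) -> FitResult:
    """One parameter vector minimizing the pooled cost over all datasets."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    if isinstance(stimuli_list, PressureStimulus):
        stimuli_list = [stimuli_list] * len(datasets)
    else:
        stimuli_list = list(stimuli_list)
    if len(stimuli_list) != len(datasets):
        raise ValueError("need one stimulus per dataset")
    if any(n.startswith("stim.") for n in subset) and len(datasets) > 1:
        raise ValueError("stimulus parameters cannot be shared across datasets")

    resid_fun, theta_of, _ = _make_objective(model, stimuli_list, datasets, subset, sim_kw)
    method_key = method.lower().replace("_", "-")
    cost_trace: list[float] = []

    if method_key == "lm":
        if not model.neuron.smooth:
            raise ValueError(
                "Levenberg-Marquardt refused: the integrate-and-fire output map "
                "is discontinuous at threshold; a gradient-based method is not "
                "applicable — use method='nelder-mead'"
            )

        def tracked(x):
            r = resid_fun(x)
            cost_trace.append(float(np.sum(r**2)))
            return r

        sol = optimize.least_squares(
            tracked,
            np.zeros(len(subset)),
            method="lm",
            xtol=xtol,
            ftol=1e-12,
            max_nfev=max_nfev,
        )
        x_hat, n_iter, n_fev = sol.x, sol.nfev, sol.nfev
        converged, message = bool(sol.success), sol.message
    elif method_key == "nelder-mead":

        def cost(x):
            c = float(np.sum(resid_fun(x) ** 2))
            cost_trace.append(c)
            return c

        opts = {"xatol": 1e-6, "fatol": 1e-8, "adaptive": True}
        if max_nfev is not None:
            opts["maxfev"] = max_nfev
        sol = optimize.minimize(cost, np.zeros(len(subset)), method="Nelder-Mead", options=opts)
        # one restart from the converged simplex guards against premature
        # simplex collapse
        sol2 = optimize.minimize(cost, sol.x, method="Nelder-Mead", options=opts)
        best = sol2 if sol2.fun <= sol.fun else sol
        x_hat = best.x
        n_iter = int(sol.nit + sol2.nit)
        n_fev = int(sol.nfev + sol2.nfev)
        converged, message = bool(best.success), best.message
    else:
        raise ValueError("method must be 'lm' or 'nelder-mead'")

    theta_hat = theta_of(x_hat)
    return _finalize(model, stimuli_list, datasets, subset, theta_hat, resid_fun,
                     x_hat, method_key, n_iter, n_fev, converged, cost_trace,
                     message, sim_kw)
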