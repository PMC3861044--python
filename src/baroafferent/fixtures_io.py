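"""Synthetic firing-rate datasets and the file I/O shared by the CLI.

The original recordings behind the quantitative experiments (sinusoidal,
four-step and square-pulse stimulation of rat aortic baroreceptors) are
not distributed; :func:`bundled_protocols` reproduces their stimulus
envelopes and :func:`generate_dataset` emulates recordings by simulating a
chosen model and adding seeded Gaussian noise scaled by the mean firing
rate (matching the residual normalization used for fitting).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from baroafferent.composite import SimulationResult, model_from_dict, simulate
from baroafferent.estimation import Dataset
from baroafferent.stimuli import stimulus_from_dict

__all__ = [
    "SyntheticSpec",
    "nominal_parameters",
    "nominal_model_config",
    "bundled_protocols",
    "generate_dataset",
    "read_timeseries",
    "write_timeseries",
    "read_trace",
    "write_trace",
]

# Nominal component parameters used across the bundled protocols.  Chain
# rate pairs are deliberately spread so the models' adaptation timescales
# stay separated.
_NOMINAL_WALL = {
    "linear": {"k_wall": 0.0063},
    "sls": {"k_wall": 0.0063, "tau_a": 0.028, "tau_b": 0.01},
    "nonlinear": {"A0": 1.0, "Am": 32.6, "alpha": 150.0, "k": 10.0},
}
_NOMINAL_CHAIN = {
    1: {"alpha": [0.5], "beta": [0.5]},
    2: {"alpha": [0.5, 0.4], "beta": [0.5, 2.0]},
    3: {"alpha": [0.5, 0.4, 1.0], "beta": [0.5, 2.0, 10.0]},
}
_NOMINAL_NEURON = {
    "linear": {"s1": 480.0, "s2": 100.0},
    # stimulus-current map (nA) chosen so the nominal nonlinear-wall model
    # fires at ~80-130 Hz over the 115-180 mmHg protocols (threshold strain
    # (g*Vth - s2)/s1 = 0.2) yet silences under the post-square-pulse
    # strain undershoot
    "integrate_fire": {"s1": 40.0, "s2": 2.0},
}


def nominal_parameters(wall_kind: str, n_voigt: int, neuron_kind: str) -> dict:
    """Nested nominal parameter blocks for :func:`baroafferent.assemble`."""
    return {
        "wall": copy.deepcopy(_NOMINAL_WALL[wall_kind]),
        "chain": copy.deepcopy(_NOMINAL_CHAIN[n_voigt]),
        "neuron": copy.deepcopy(_NOMINAL_NEURON[neuron_kind]),
    }


def nominal_model_config(wall_kind: str, n_voigt: int, neuron_kind: str) -> dict:
    params = nominal_parameters(wall_kind, n_voigt, neuron_kind)
    return {
        "wall": {"type": wall_kind, "params": params["wall"]},
        "chain": params["chain"],
        "neuron": {"type": neuron_kind, "params": params["neuron"]},
    }


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic recording."""

    name: str
    model: dict  # config accepted by composite.model_from_dict
    stimulus: dict  # config accepted by stimuli.stimulus_from_dict
    t_start: float
    t_end: float
    sampling_rate: float
    noise_sd_fraction: float = 0.02
    noise_kind: str = "additive"  # or "multiplicative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if self.noise_kind not in ("additive", "multiplicative"):
            raise ValueError("noise_kind must be 'additive' or 'multiplicative'")

    @property
    def t_grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) * self.sampling_rate))
        return self.t_start + np.arange(n + 1) / self.sampling_rate


def generate_dataset(spec: SyntheticSpec, return_clean: bool = False):
    """Simulate the generating model and add seeded Gaussian noise.

    Additive noise has standard deviation ``noise_sd_fraction`` times the
    mean of the clean trace; multiplicative noise scales each sample by
    ``1 + fraction * N(0, 1)``.  Identical specs (same seed) give
    identical datasets.
    """
    model = model_from_dict(spec.model)
    stimulus = stimulus_from_dict(spec.stimulus)
    sim = simulate(model, stimulus, spec.t_grid)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_fraction == 0:
        f_obs = sim.f.copy()
    elif spec.noise_kind == "additive":
        sd = spec.noise_sd_fraction * float(np.mean(sim.f))
        f_obs = sim.f + rng.normal(0.0, sd, size=sim.f.shape)
    else:
        f_obs = sim.f * (1.0 + spec.noise_sd_fraction * rng.normal(size=sim.f.shape))
    dataset = Dataset(t=sim.t.copy(), f_obs=f_obs)
    if return_clean:
        return dataset, sim
    return dataset


# Stimulus envelopes of the six emulated experiments: a ~1 Hz sinusoid
# around 127 +- 5 mmHg recorded for 5 s; four smooth steps from a 115 mmHg
# baseline; and a 140->180->140 mmHg square pulse with a 4 s plateau (the
# record length of the square-pulse experiment is not documented; 20 s
# leaves room for full recovery).
_STEP_TARGETS = {"step1": 128.0, "step2": 134.0, "step3": 137.0, "step4": 143.0}


def bundled_protocols(
    model_config: dict | None = None,
    noise_sd_fraction: float = 0.02,
    seed: int = 0,
) -> list[SyntheticSpec]:
    """The six emulated recording protocols, driven by ``model_config``.

    The default generating model is the preferred one (nonlinear wall, two
    Voigt bodies, integrate-and-fire neuron) at nominal parameters.
    """
    if model_config is None:
        model_config = nominal_model_config("nonlinear", 2, "integrate_fire")
    specs = [
        SyntheticSpec(
            name="sinusoid",
            model=copy.deepcopy(model_config),
            stimulus={
                "type": "sinusoid",
                "params": {
                    "mean_pressure": 127.0,
                    "amplitude": 5.0,
                    "angular_frequency": 6.44,
                    "phase": 46.84,
                },
            },
            t_start=0.0,
            t_end=5.0,
            sampling_rate=200.0,
            noise_sd_fraction=noise_sd_fraction,
            seed=seed,
        )
    ]
    for i, (name, target) in enumerate(_STEP_TARGETS.items(), start=1):
        specs.append(
            SyntheticSpec(
                name=name,
                model=copy.deepcopy(model_config),
                stimulus={
                    "type": "step",
                    "params": {
                        "p_base": 115.0,
                        "p_target": target,
                        "onset": 2.0,
                        "steepness": 1.0,
                    },
                },
                t_start=0.0,
                t_end=15.0,
                sampling_rate=50.0,
                noise_sd_fraction=noise_sd_fraction,
                seed=seed + i,
            )
        )
    specs.append(
        SyntheticSpec(
            name="square",
            model=copy.deepcopy(model_config),
            stimulus={
                "type": "square",
                "params": {
                    "p_base": 140.0,
                    "p_up": 180.0,
                    "t_up": 4.6,
                    "t_down": 8.7,
                },
            },
            t_start=0.0,
            t_end=20.0,
            sampling_rate=50.0,
            noise_sd_fraction=noise_sd_fraction,
            seed=seed + 5,
        )
    )
    return specs


# ---------------------------------------------------------------------------
# file I/O (plain-text CSV, dot decimal separator, UTF-8)

_DATASET_COLUMNS = ("time_s", "firing_hz")
_TRACE_COLUMNS = ("time_s", "pressure_mmhg", "wall_strain", "ne_strain", "firing_hz")


def _parse_csv(path, columns) -> dict:
    out = {c: [] for c in columns}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        got = tuple(h.strip() for h in header.split(","))
        if got != columns:
            raise ValueError(
                f"{path}: expected header {','.join(columns)!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.strip().split(",")
            if len(cells) != len(columns):
                raise ValueError(f"{path}: line {lineno}: expected {len(columns)} cells")
            for col, cell in zip(columns, cells):
                try:
                    out[col].append(float(cell))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric value {cell!r} in {col}"
                    ) from exc
    return {c: np.asarray(v, dtype=float) for c, v in out.items()}


def _write_csv(path, columns, arrays) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(columns) + "\n")
        for row in zip(*arrays):
            fh.write(",".join(repr(float(x)) for x in row) + "\n")


def read_timeseries(path) -> Dataset:
    """Read a two-column (time_s, firing_hz) dataset CSV."""
    cols = _parse_csv(path, _DATASET_COLUMNS)
    t = cols["time_s"]
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    return Dataset(t=t, f_obs=cols["firing_hz"])


def write_timeseries(dataset: Dataset, path) -> None:
    _write_csv(path, _DATASET_COLUMNS, (dataset.t, dataset.f_obs))


def read_trace(path) -> SimulationResult:
    """Read a five-column simulation trace CSV."""
    cols = _parse_csv(path, _TRACE_COLUMNS)
    if np.any(np.diff(cols["time_s"]) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    return SimulationResult(
        t=cols["time_s"],
        pressure=cols["pressure_mmhg"],
        eps_w=cols["wall_strain"],
        eps_ne=cols["ne_strain"],
        f=cols["firing_hz"],
    )


def write_trace(result: SimulationResult, path) -> None:
    _write_csv(
        path,
        _TRACE_COLUMNS,
        (result.t, result.pressure, result.eps_w, result.eps_ne, result.f),
    )
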