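"""Experiment orchestration: conditions, repeats, sweeps.

Each *repeat* regenerates everything from its own seed — the 30 stimulus
images of the control set, the weight tensor, and both inhibition-range
fields — then records one forward pass per image (a 400-unit x 30-numerosity
response table).  An *experiment* runs a condition (``full``, ``no_input_li``,
``no_output_li`` or ``no_li``) over one or more control sets for a number of
repeats (default 30) and pushes the pooled responses through the tuning
analysis.

A sweep replaces the *mean* of one layer's inhibition-range distribution with
each value from a list (the per-unit heterogeneity, i.e. the distribution's
spread, is retained) and records one preference distribution per value;
``sweep_mode="constant"`` uses a homogeneous field instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import tuning
from .network import Network, NetworkParams
from .stimuli import generate_control_set

CONDITIONS = {
    # condition -> (ablate_input_li, ablate_output_li)
    "full": (False, False),
    "no_input_li": (True, False),
    "no_output_li": (False, True),
    "no_li": (True, True),
}

OUTPUT_SIGMA_SWEEP = (0.10, 0.15, 0.20, 0.26, 0.30, 0.35, 0.40)
INPUT_SIGMA_SWEEP = (0.55, 0.60, 0.65, 0.67, 0.70, 0.75, 0.80)


@dataclass(frozen=True)
class ExperimentConfig:
    condition: str = "full"
    control_sets: tuple = (1, 2, 3, 4)
    repeats: int = 30
    seed: int = 0
    params: NetworkParams = field(default_factory=NetworkParams)
    sweep_layer: str | None = None  # "input" or "output"
    sweep_values: tuple = ()
    sweep_mode: str = "mean"  # "mean" keeps per-unit spread; "constant" does not
    normalization: str = "minmax"
    share_streams: bool = False  # same stimuli/weights across conditions
    analyze_fits: bool = True  # Gaussian fits are the slow part; preference
    # distributions and curves alone need much less time

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if any(v <= 0 for v in self.sweep_values):
            raise ValueError("sweep sigma values must be positive")
        if self.sweep_layer not in (None, "input", "output"):
            raise ValueError("sweep_layer must be 'input' or 'output'")

    def condition_params(self) -> NetworkParams:
        ablate_in, ablate_out = CONDITIONS[self.condition]
        return replace(self.params, ablate_input_li=ablate_in,
                       ablate_output_li=ablate_out)


@dataclass
class SetResult:
    """Tuning analysis of one (condition, control set) cell."""

    set_id: int
    responses: np.ndarray  # (repeats, units, 30)
    curves: list
    preferences: np.ndarray
    distribution: np.ndarray
    pooled: dict  # preference -> PooledCurve (for display)
    unit_fits: dict  # scale -> list[GaussianFitResult], one per responsive unit
    pooled_fits: dict  # scale -> list[GaussianFitResult], one per pooled curve
    r2_mean: dict  # scale -> float (per-preference mean of unit-fit r2)
    slopes: dict  # scale -> float or nan (OLS of unit-fit sigma vs preference)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    sets: dict  # set_id -> SetResult
    sweep_distributions: dict = field(default_factory=dict)
    # sweep sigma -> {set_id -> length-30 distribution}

    def mean_r2(self, scale_id: str) -> float:
        vals = [s.r2_mean[scale_id] for s in self.sets.values()
                if np.isfinite(s.r2_mean.get(scale_id, np.nan))]
        return float(np.mean(vals)) if vals else float("nan")

    def mean_slope(self, scale_id: str) -> float:
        vals = [s.slopes[scale_id] for s in self.sets.values()
                if np.isfinite(s.slopes.get(scale_id, np.nan))]
        return float(np.mean(vals)) if vals else float("nan")

    def compressed_slope(self) -> float:
        """Slope averaged over the three compressed scales and all sets."""
        return float(np.mean([self.mean_slope(s)
                              for s in ("sqrt", "cuberoot", "log2")]))


def _repeat_seed(config: ExperimentConfig, set_id: int, repeat: int,
                 sweep_index: int = -1) -> np.random.SeedSequence:
    key = [config.seed, set_id, repeat, sweep_index + 1]
    if not config.share_streams:
        key.insert(1, sorted(CONDITIONS).index(config.condition))
    return np.random.SeedSequence(key)


def run_repeat(
    set_id: int, params: NetworkParams, seed
) -> np.ndarray:
    """One repeat: fresh stimuli + fresh network, one pass per numerosity.

    ``seed`` may be an int or a SeedSequence.  Returns a (units, 30) table.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    stim_ss, net_ss = ss.spawn(2)
    images = generate_control_set(set_id, rng=np.random.default_rng(stim_ss))
    net = Network.sample(params, np.random.default_rng(net_ss))
    table = np.stack([net.respond(img).reshape(-1) for img in images], axis=1)
    return table


def analyze_responses(
    set_id: int,
    responses: np.ndarray,
    output_shape: tuple = (20, 20),
    normalization: str = "minmax",
    fit: bool = True,
) -> SetResult:
    """Run the full tuning analysis on a (repeats, units, 30) table."""
    curves = tuning.mean_tuning_curves(responses, output_shape)
    prefs = np.array([c.preferred_numerosity for c in curves])
    distribution = tuning.preference_distribution(responses)
    pooled = {
        p: tuning.pool_curves(curves, p, normalization)
        for p in tuning.PREFERENCE_GRID
    }
    unit_fits, pooled_fits, r2_mean, slopes = {}, {}, {}, {}
    for scale_id in tuning.SCALE_ORDER if fit else ():
        ufits = tuning.fit_unit_curves(curves, scale_id)
        unit_fits[scale_id] = ufits
        pooled_fits[scale_id] = [
            tuning.fit_gaussian_on_scale(pc, scale_id)
            for pc in pooled.values()
            if not pc.absent
        ]
        r2_mean[scale_id] = tuning.mean_r_square_by_preference(ufits)
        try:
            slopes[scale_id] = tuning.sigma_slope(ufits)
        except ValueError:
            slopes[scale_id] = float("nan")
    return SetResult(set_id, responses, curves, prefs, distribution,
                     pooled, unit_fits, pooled_fits, r2_mean, slopes)


def _sweep_params(params: NetworkParams, layer: str, sigma: float,
                  mode: str) -> NetworkParams:
    if layer == "input":
        sd = params.input_sigma_sd if mode == "mean" else 0.0
        return replace(params, input_sigma_mu=sigma, input_sigma_sd=sd)
    sd = params.output_sigma_sd if mode == "mean" else 0.0
    return replace(params, output_sigma_mu=sigma, output_sigma_sd=sd)


def run_experiment(config: ExperimentConfig, progress=None) -> ExperimentResult:
    """Run a condition over its control sets (and optional sigma sweep)."""
    params = config.condition_params()
    sets = {}
    for set_id in config.control_sets:
        tables = []
        for rep in range(config.repeats):
            if progress is not None:
                progress(config.condition, set_id, rep)
            tables.append(
                run_repeat(set_id, params, _repeat_seed(config, set_id, rep))
            )
        sets[set_id] = analyze_responses(
            set_id, np.stack(tables), params.output_shape,
            config.normalization, fit=config.analyze_fits,
        )

    sweep_distributions = {}
    if config.sweep_layer is not None:
        for sw_idx, sigma in enumerate(config.sweep_values):
            sw_params = _sweep_params(params, config.sweep_layer, sigma,
                                      config.sweep_mode)
            per_set = {}
            for set_id in config.control_sets:
                tables = [
                    run_repeat(
                        set_id, sw_params,
                        _repeat_seed(config, set_id, rep, sw_idx),
                    )
                    for rep in range(config.repeats)
                ]
                per_set[set_id] = tuning.preference_distribution(np.stack(tables))
            sweep_distributions[sigma] = per_set
    return ExperimentResult(config, sets, sweep_distributions)
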