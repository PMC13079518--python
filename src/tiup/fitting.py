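"""Weighted least-squares fitting of the population-code model to DLs.

The four parameters (lambda_max, K, n, sigma2) are estimated jointly from the
duration and brightness thresholds of one experiment by minimizing

    SSR_w = sum over conditions of (E - O)^2 / Var(O)

where E is the model DL (duration DLs from the closed form W*t, luminance DLs
from exact transducer inversion), O the observed condition-mean DL and Var(O)
its across-participant variance. Optimization is a downhill (Nelder-Mead)
simplex on log-transformed parameters with a multi-start grid; uncertainty is
quantified by a two-stage participant-level bootstrap.

When all tested luminances sit far below K, lambda_max and K trade off along
a ridge and only n, sigma2 and the composite lambda_max/K^n are identified;
the multi-start simplex returns one point on that ridge.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model_core import ModelParams, _dl_L_grid, _dl_t_grid
from .observer import TASK_BRIGHTNESS, TASK_DURATION, ExperimentDesign
from .thresholds import threshold_matrix

__all__ = [
    "FitOptions",
    "FitResult",
    "BootstrapBand",
    "condition_stats",
    "predict_conditions",
    "ssr_weighted",
    "fit",
    "joint_fit_across_experiments",
    "bootstrap_bands",
]

#: Objective value charged per saturated (infinite) predicted DL so the
#: simplex can retreat from parameter regions that saturate the population.
SATURATION_PENALTY = 1e12


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    The default multi-start grid takes 3 log-spaced values per parameter over
    lambda_max in [1e3, 1e6] Hz, K in [0.1, 1e4] cd/m^2, n in [0.3, 3],
    sigma2 in [1e-3, 1] (81 starts). ``var_mode`` selects the weight
    definition: "across" = across-participant variance per condition,
    "morey" = variance of within-subject-normalized scores with the k/(k-1)
    bias correction.
    """

    starts: tuple = ()
    grid_points: int = 3
    bounds_log10: tuple = ((3.0, 6.0), (-1.0, 4.0), (np.log10(0.3), np.log10(3.0)), (-3.0, 0.0))
    fatol: float = 1e-10
    xatol: float = 1e-8
    maxiter: int = 1600  # 400 * dim
    var_mode: str = "across"
    K_upper: float | None = None  # optional roof on the saturation constant

    def start_vectors(self) -> np.ndarray:
        """Starting points in natural-log parameter space."""
        if self.starts:
            return np.array(
                [np.log([p.lambda_max, p.K, p.n, p.sigma2]) for p in self.starts]
            )
        axes = [
            np.linspace(lo, hi, self.grid_points) * np.log(10.0)
            for lo, hi in self.bounds_log10
        ]
        return np.array(list(itertools.product(*axes)))


@dataclass(frozen=True)
class FitResult:
    """Best-fitting parameters with goodness of fit and predicted DL curves.

    ``predicted`` holds one row per condition (task, standard_value,
    observed mean/variance and the model DL in task units); predictions are
    recomputable from ``params`` via :mod:`tiup.model_core`.
    """

    params: ModelParams
    ssr_w: float
    predicted: pd.DataFrame
    converged: bool
    n_restarts_used: int


@dataclass(frozen=True)
class BootstrapBand:
    """Percentile band of bootstrapped model predictions per condition."""

    bands: pd.DataFrame  # task, standard_value, dl_lower, dl_upper
    n_resamples: int
    n_excluded: int


def condition_stats(
    thresholds: pd.DataFrame, experiment: int, var_mode: str = "across"
) -> pd.DataFrame:
    """Condition mean and variance of DLs for both tasks of one experiment.

    Returns columns ``task, standard_value, mean, var, n_participants``.
    """
    out = []
    for task in (TASK_DURATION, TASK_BRIGHTNESS):
        wide = threshold_matrix(thresholds, task, experiment)
        data = wide.to_numpy()
        N, k = data.shape
        if var_mode == "across":
            var = data.var(axis=0, ddof=1)
        elif var_mode == "morey":
            normalized = data - data.mean(axis=1, keepdims=True) + data.mean()
            var = normalized.var(axis=0, ddof=1) * k / (k - 1.0)
        else:
            raise ValueError(f"unknown var_mode {var_mode!r}")
        out.append(
            pd.DataFrame(
                {
                    "task": task,
                    "standard_value": wide.columns.to_numpy(dtype=float),
                    "mean": data.mean(axis=0),
                    "var": var,
                    "n_participants": N,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _design_stimuli(design: ExperimentDesign, task: str):
    """(standard_value, L, t) arrays for a task, ordered by standard value.

    Conditions are labeled by the experiment's manipulated standard axis,
    matching the keys produced by :func:`tiup.thresholds.dl_from_runs`.
    """
    sv = np.array([design.standard_value(s) for s in design.standards])
    L = np.array([s.luminance for s in design.standards])
    t = np.array([s.duration for s in design.standards])
    order = np.argsort(sv)
    return sv[order], L[order], t[order]


def _predict_task(params: ModelParams, task: str, L: np.ndarray, t: np.ndarray):
    """Model DL per condition in task units (ms or cd/m^2); inf if saturated."""
    if task == TASK_DURATION:
        return _dl_t_grid(params, L, t) * 1e3
    return _dl_L_grid(params, L, t)


def predict_conditions(params: ModelParams, design: ExperimentDesign) -> pd.DataFrame:
    """Predicted DLs for every condition of a design (task units)."""
    frames = []
    for task in (TASK_DURATION, TASK_BRIGHTNESS):
        sv, L, t = _design_stimuli(design, task)
        frames.append(
            pd.DataFrame(
                {"task": task, "standard_value": sv, "dl_pred": _predict_task(params, task, L, t)}
            )
        )
    return pd.concat(frames, ignore_index=True)


class _PreparedExperiment:
    """Observed stats aligned with design stimuli for fast objective evaluation."""

    def __init__(self, observed, design: ExperimentDesign, var_mode: str):
        if "participant" in observed.columns:
            experiment = int(observed["experiment"].iloc[0])
            stats_ = condition_stats(observed, experiment, var_mode)
        else:
            stats_ = observed  # precomputed: task, standard_value, mean, var
        self.design = design
        self.tasks = []
        for task in (TASK_DURATION, TASK_BRIGHTNESS):
            sv, L, t = _design_stimuli(design, task)
            sub = stats_[stats_["task"] == task].set_index("standard_value")
            # align observed conditions with design standards by value
            idx = sub.index.to_numpy(dtype=float)
            order = np.array([int(np.argmin(np.abs(idx - v))) for v in sv])
            if not np.allclose(idx[order], sv, rtol=1e-6):
                raise ValueError(
                    f"observed {task} conditions do not match the design standards"
                )
            O = sub["mean"].to_numpy()[order]
            V = sub["var"].to_numpy()[order]
            if np.any(V <= 0) or not np.all(np.isfinite(V)):
                raise ValueError(
                    "degenerate weights: every condition needs Var(O) > 0"
                )
            self.tasks.append((task, sv, L, t, O, V))

    def ssr(self, params: ModelParams) -> float:
        total = 0.0
        with np.errstate(over="ignore"):
            for task, _sv, L, t, O, V in self.tasks:
                E = _predict_task(params, task, L, t)
                terms = (E - O) ** 2 / V
                bad = ~np.isfinite(terms)
                total += float(np.sum(terms[~bad]))
                total += SATURATION_PENALTY * int(bad.sum())
        return total


def ssr_weighted(
    params: ModelParams,
    observed: pd.DataFrame,
    design: ExperimentDesign,
    var_mode: str = "across",
) -> float:
    """Weighted sum of squared residuals over all conditions of one experiment.

    ``observed`` is either a per-participant threshold table (columns as
    produced by :func:`tiup.thresholds.dl_from_runs`) or precomputed
    condition stats (``task, standard_value, mean, var``). Saturated
    predictions contribute a large finite penalty instead of infinity.
    """
    return _PreparedExperiment(observed, design, var_mode).ssr(params)


def _params_from_log(x: np.ndarray, K_upper: float | None) -> ModelParams | None:
    with np.errstate(over="ignore"):
        v = np.exp(np.clip(x, -700, 700))
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        return None
    if K_upper is not None and v[1] > K_upper:
        return None
    return ModelParams(lambda_max=v[0], K=v[1], n=v[2], sigma2=v[3])


def _minimize_ssr(prepared_list, options: FitOptions, x0_list) -> tuple:
    """Nelder-Mead from each start; returns (best_x, best_ssr, converged, n_starts)."""

    def objective(x):
        p = _params_from_log(x, options.K_upper)
        if p is None:
            return SATURATION_PENALTY * 32
        return sum(prep.ssr(p) for prep in prepared_list)

    best_x, best_val, converged = None, np.inf, False
    for x0 in x0_list:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "fatol": options.fatol,
                "xatol": options.xatol,
                "maxiter": options.maxiter,
            },
        )
        if res.fun < best_val:
            best_x, best_val, converged = res.x, float(res.fun), bool(res.success)
    return best_x, best_val, converged, len(x0_list)


def _finish(prepared, design, options, x, val, converged, n_starts) -> FitResult:
    params = _params_from_log(x, None)
    pred = predict_conditions(params, design)
    obs = []
    for task, sv, _L, _t, O, V in prepared.tasks:
        obs.append(pd.DataFrame({"task": task, "standard_value": sv, "dl_obs": O, "var_obs": V}))
    pred = pred.merge(pd.concat(obs, ignore_index=True), on=["task", "standard_value"])
    if not converged:
        warnings.warn("optimizer did not converge; best-so-far returned", stacklevel=3)
    return FitResult(
        params=params, ssr_w=val, predicted=pred, converged=converged,
        n_restarts_used=n_starts,
    )


def fit(
    observed: pd.DataFrame,
    design: ExperimentDesign,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the four-parameter model to one experiment's thresholds.

    Nelder-Mead on log parameters (positivity by construction) from a
    multi-start grid; the best objective value wins. Deterministic for fixed
    inputs and options.
    """
    options = options or FitOptions()
    prepared = _PreparedExperiment(observed, design, options.var_mode)
    x, val, conv, n = _minimize_ssr([prepared], options, options.start_vectors())
    return _finish(prepared, design, options, x, val, conv, n)


def joint_fit_across_experiments(
    observed1: pd.DataFrame,
    observed2: pd.DataFrame,
    designs: tuple,
    options: FitOptions | None = None,
) -> FitResult:
    """Single parameter vector minimizing the summed SSR_w of both experiments.

    The returned ``predicted``/``ssr_w`` refer to the pooled objective; the
    per-experiment curves can be recomputed from ``params``. The constrained
    optimum can never beat the sum of the separately minimized objectives.
    """
    options = options or FitOptions()
    p1 = _PreparedExperiment(observed1, designs[0], options.var_mode)
    p2 = _PreparedExperiment(observed2, designs[1], options.var_mode)
    x, val, conv, n = _minimize_ssr([p1, p2], options, options.start_vectors())
    params = _params_from_log(x, None)
    pred = pd.concat(
        [
            predict_conditions(params, designs[0]).assign(experiment=designs[0].experiment_id),
            predict_conditions(params, designs[1]).assign(experiment=designs[1].experiment_id),
        ],
        ignore_index=True,
    )
    if not conv:
        warnings.warn("optimizer did not converge; best-so-far returned", stacklevel=2)
    return FitResult(params=params, ssr_w=val, predicted=pred, converged=conv, n_restarts_used=n)


def bootstrap_bands(
    thresholds: pd.DataFrame,
    design: ExperimentDesign,
    reps: int,
    rng: np.random.Generator,
    options: FitOptions | None = None,
    point_fit: FitResult | None = None,
) -> BootstrapBand:
    """Participant-level bootstrap confidence band for the model's DL curves.

    Two stages: resample participants with replacement, then refit the full
    model to each resample and collect its predicted DLs; the band is the
    2.5/97.5 percentile envelope per condition. Refits warm-start from the
    point fit (a single simplex run each); resamples whose refit fails are
    excluded and counted. Reproducible under the supplied generator's seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    options = options or FitOptions()
    if point_fit is None:
        point_fit = fit(thresholds, design, options)
    x0 = np.log(
        [
            point_fit.params.lambda_max,
            point_fit.params.K,
            point_fit.params.n,
            point_fit.params.sigma2,
        ]
    )
    experiment = int(thresholds["experiment"].iloc[0])
    participants = thresholds["participant"].unique()
    by_participant = dict(tuple(thresholds.groupby("participant")))
    preds, n_excluded = [], 0
    for _ in range(reps):
        chosen = rng.choice(participants, size=len(participants), replace=True)
        resample = pd.concat(
            [
                by_participant[p].assign(participant=i)
                for i, p in enumerate(chosen, start=1)
            ],
            ignore_index=True,
        )
        try:
            stats_ = condition_stats(resample, experiment, options.var_mode)
            prepared = _PreparedExperiment(stats_, design, options.var_mode)
            x, val, _conv, _n = _minimize_ssr([prepared], options, [x0])
            params = _params_from_log(x, None)
            if params is None or not np.isfinite(val):
                raise RuntimeError("refit failed")
            preds.append(predict_conditions(params, design)["dl_pred"].to_numpy())
        except (ValueError, RuntimeError):
            n_excluded += 1
    if not preds:
        raise RuntimeError("all bootstrap refits failed")
    stacked = np.vstack(preds)
    template = predict_conditions(point_fit.params, design)
    bands = pd.DataFrame(
        {
            "task": template["task"],
            "standard_value": template["standard_value"],
            "dl_lower": np.nanpercentile(stacked, 2.5, axis=0),
            "dl_upper": np.nanpercentile(stacked, 97.5, axis=0),
        }
    )
    return BootstrapBand(bands=bands, n_resamples=len(preds), n_excluded=n_excluded)
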