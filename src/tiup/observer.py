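"""Synthetic observer: 2IFC reminder task with Kaernbach weighted staircases.

Emulates the two discrimination experiments trial for trial. On each trial a
standard and a comparison flash are presented; the simulated observer draws an
independent population spike count for each interval (via :mod:`tiup.spiking`)
and reports the comparison as greater whenever its count is larger, flipping a
fair coin on ties. Comparison values evolve under the weighted up-down rule
targeting X.75 (upper run) or X.25 (lower run): at target quantile p, the two
step sizes satisfy p * (step after "greater") = (1-p) * (step after "not
greater"), giving a 3:1 ratio for the .25/.75 targets.

Experiment 1 varies the standard duration (10-1280 ms at fixed luminance);
Experiment 2 varies the standard luminance (0.04-3.63 cd/m^2 at fixed 240 ms).
Each participant contributes 2 tasks x 8 standards x 2 runs x 50 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ModelParams, Stimulus
from .spiking import sample_spike_count

__all__ = [
    "TASK_DURATION",
    "TASK_BRIGHTNESS",
    "TaskRule",
    "StaircaseSpec",
    "ExperimentDesign",
    "experiment_design",
    "StaircaseRun",
    "simulate_trial",
    "psychometric_mc",
    "quantile_from_psychometric",
    "kaernbach_update",
    "run_staircase",
    "generate_experiment",
    "TRIAL_COLUMNS",
]

TASK_DURATION = "duration"
TASK_BRIGHTNESS = "brightness"

#: Canonical column order of the trial-level table.
TRIAL_COLUMNS = [
    "participant",
    "experiment",
    "task",
    "standard_L_cd_m2",
    "standard_t_ms",
    "run_type",
    "trial_index",
    "comparison_value",
    "response",
    "is_reversal",
]


@dataclass(frozen=True)
class TaskRule:
    """Staircase start/step rule for one task.

    ``relative`` rules scale with the standard's value on the varied
    dimension (starts as multiplicative factors, step as a fraction);
    ``absolute`` rules are fixed task units (ms or cd/m^2).
    """

    mode: str  # "relative" | "absolute"
    start_lower: float
    start_upper: float
    step: float

    def resolve(self, standard_value: float) -> "StaircaseSpec":
        if self.mode == "relative":
            return StaircaseSpec(
                start_lower=self.start_lower * standard_value,
                start_upper=self.start_upper * standard_value,
                base_step=self.step * standard_value,
            )
        return StaircaseSpec(
            start_lower=self.start_lower,
            start_upper=self.start_upper,
            base_step=self.step,
        )


@dataclass(frozen=True)
class StaircaseSpec:
    """Resolved starting values and base step, in task units."""

    start_lower: float
    start_upper: float
    base_step: float


@dataclass(frozen=True)
class ExperimentDesign:
    """Standards and staircase rules for one experiment.

    ``standards`` are canonical-unit stimuli (cd/m^2, seconds); ``rules``
    maps task name to its :class:`TaskRule`. ``standard_axis`` names the
    dimension manipulated across standards — it labels the conditions of
    both tasks (duration in ms for Experiment 1, luminance in cd/m^2 for
    Experiment 2).
    """

    experiment_id: int
    standards: tuple
    rules: dict
    standard_axis: str  # "duration" | "luminance"
    trials_per_staircase: int = 50

    def task_value(self, task: str, standard: Stimulus) -> float:
        """The standard's value on the task's varied dimension (ms or cd/m^2)."""
        if task == TASK_DURATION:
            return standard.duration * 1e3
        if task == TASK_BRIGHTNESS:
            return standard.luminance
        raise ValueError(f"unknown task {task!r}")

    def standard_value(self, standard: Stimulus) -> float:
        """Condition label: the standard's value on the manipulated axis."""
        if self.standard_axis == TASK_DURATION:
            return standard.duration * 1e3
        return standard.luminance

    def staircase_spec(self, task: str, standard: Stimulus) -> StaircaseSpec:
        return self.rules[task].resolve(self.task_value(task, standard))


#: Experiment 1 standard durations, ms.
EXP1_STANDARD_DURATIONS_MS = (10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0, 1280.0)
#: Experiment 1 fixed standard intensity, cd/m^2 (reported as 3.31 in Results).
EXP1_STANDARD_LUMINANCE = 3.31
#: Experiment 2 standard intensities, cd/m^2.
EXP2_STANDARD_LUMINANCES = (0.04, 0.07, 0.13, 0.24, 0.47, 0.92, 1.82, 3.63)
#: Experiment 2 fixed standard duration, ms.
EXP2_STANDARD_DURATION_MS = 240.0


def experiment_design(
    experiment_id: int,
    *,
    standard_luminance: float = EXP1_STANDARD_LUMINANCE,
    trials_per_staircase: int = 50,
) -> ExperimentDesign:
    """Build the design of Experiment 1 or 2 with the published defaults.

    Experiment 1 (duration varied): comparison durations start at 0.6/1.4x
    the standard and step by 1/40 of it; comparison intensities start at
    1.7/4.9 cd/m^2 with a 0.1 cd/m^2 step. Experiment 2 (luminance varied):
    comparison intensities start at 0.5/1.5x the standard and step by 1/25 of
    it; comparison durations start at 192/288 ms with a 16 ms step.
    """
    if experiment_id == 1:
        standards = tuple(
            Stimulus(luminance=standard_luminance, duration=t_ms / 1e3)
            for t_ms in EXP1_STANDARD_DURATIONS_MS
        )
        rules = {
            TASK_DURATION: TaskRule("relative", 0.6, 1.4, 1.0 / 40.0),
            TASK_BRIGHTNESS: TaskRule("absolute", 1.7, 4.9, 0.1),
        }
        axis = TASK_DURATION
    elif experiment_id == 2:
        standards = tuple(
            Stimulus(luminance=L, duration=EXP2_STANDARD_DURATION_MS / 1e3)
            for L in EXP2_STANDARD_LUMINANCES
        )
        rules = {
            TASK_DURATION: TaskRule("absolute", 192.0, 288.0, 16.0),
            TASK_BRIGHTNESS: TaskRule("relative", 0.5, 1.5, 1.0 / 25.0),
        }
        axis = TASK_BRIGHTNESS
    else:
        raise ValueError(f"experiment_id must be 1 or 2, got {experiment_id!r}")
    return ExperimentDesign(
        experiment_id=experiment_id,
        standards=standards,
        rules=rules,
        standard_axis=axis,
        trials_per_staircase=trials_per_staircase,
    )


@dataclass
class StaircaseRun:
    """One adaptive track: 50 comparison values, responses and reversal flags.

    ``run_type`` is "upper" (targets X.75) or "lower" (targets X.25);
    ``comparison_values`` are task units (ms or cd/m^2). The reversal flag on
    trial i (i >= 1) marks a sign change of the movement direction taken
    after trial i relative to the previous trial; the first trial never
    carries a flag.
    """

    run_type: str
    target_quantile: float
    base_step: float
    comparison_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    responses: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    is_reversal: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def reversal_values(self) -> np.ndarray:
        return self.comparison_values[self.is_reversal]


def simulate_trial(
    params: ModelParams,
    standard: Stimulus,
    comparison: Stimulus,
    rng: np.random.Generator,
) -> bool:
    """One 2IFC trial: True iff the comparison is judged greater.

    Independent spike counts are drawn for the two intervals (independent
    gains); ties are broken by a fair coin. Standard and comparison must
    differ in at most one dimension.
    """
    differs_L = standard.luminance != comparison.luminance
    differs_t = standard.duration != comparison.duration
    if differs_L and differs_t:
        raise ValueError("standard and comparison must differ in exactly one dimension")
    n_s = sample_spike_count(params, standard, rng)
    n_c = sample_spike_count(params, comparison, rng)
    if n_c == n_s:
        return bool(rng.integers(2))
    return n_c > n_s


def _comparison_stimulus(standard: Stimulus, task: str, value: float) -> Stimulus:
    """Comparison stimulus from a task-unit value (ms or cd/m^2)."""
    if task == TASK_DURATION:
        return Stimulus(luminance=standard.luminance, duration=value / 1e3)
    if task == TASK_BRIGHTNESS:
        return Stimulus(luminance=value, duration=standard.duration)
    raise ValueError(f"unknown task {task!r}")


def psychometric_mc(
    params: ModelParams,
    standard: Stimulus,
    task: str,
    comparison_values,
    reps: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Monte-Carlo psychometric function P(comparison judged greater).

    Returns a frame with columns ``comparison_value``, ``p_greater`` and the
    binomial standard error ``se``. Tie trials contribute 1/2 (the expected
    value of the fair coin).
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a usable estimate")
    values = np.asarray(comparison_values, dtype=float)
    p = np.empty(values.size)
    for i, v in enumerate(values):
        comp = _comparison_stimulus(standard, task, v)
        n_s = sample_spike_count(params, standard, rng, size=reps)
        n_c = sample_spike_count(params, comp, rng, size=reps)
        p[i] = np.mean(n_c > n_s) + 0.5 * np.mean(n_c == n_s)
    return pd.DataFrame(
        {
            "comparison_value": values,
            "p_greater": p,
            "se": np.sqrt(p * (1 - p) / reps),
        }
    )


def quantile_from_psychometric(psychometric: pd.DataFrame, q: float) -> float:
    """Comparison value at which the psychometric crosses probability ``q``.

    Linear interpolation on the isotonic regression of ``p_greater`` against
    ``comparison_value`` (monotonicity holds up to Monte-Carlo noise).
    """
    from scipy.optimize import isotonic_regression

    frame = psychometric.sort_values("comparison_value")
    p = isotonic_regression(frame["p_greater"].to_numpy()).x
    v = frame["comparison_value"].to_numpy()
    if q < p[0] or q > p[-1]:
        raise ValueError(f"quantile {q} outside the sampled psychometric range")
    return float(np.interp(q, p, v))


def kaernbach_update(
    current_value: float,
    response: bool,
    run_type: str,
    base_step: float,
    min_value: float | None = None,
) -> float:
    """Next comparison value under the weighted up-down rule.

    Upper run (targets X.75): "greater" moves down one base step, "not
    greater" moves up three. Lower run (targets X.25): mirrored. Values are
    floored at ``min_value`` (default: one base step above zero).
    """
    if run_type == "upper":
        delta = -base_step if response else 3.0 * base_step
    elif run_type == "lower":
        delta = -3.0 * base_step if response else base_step
    else:
        raise ValueError(f"run_type must be 'upper' or 'lower', got {run_type!r}")
    floor = base_step if min_value is None else min_value
    return max(current_value + delta, floor)


def run_staircase(
    params: ModelParams,
    design: ExperimentDesign,
    standard: Stimulus,
    task: str,
    run_type: str,
    rng: np.random.Generator,
) -> StaircaseRun:
    """Simulate one 50-trial weighted staircase for a standard/task/run."""
    spec = design.staircase_spec(task, standard)
    n = design.trials_per_staircase
    value = spec.start_upper if run_type == "upper" else spec.start_lower
    values = np.empty(n)
    responses = np.empty(n, dtype=bool)
    directions = np.empty(n, dtype=int)
    for i in range(n):
        values[i] = value
        comp = _comparison_stimulus(standard, task, value)
        resp = simulate_trial(params, standard, comp, rng)
        responses[i] = resp
        next_value = kaernbach_update(value, resp, run_type, spec.base_step)
        directions[i] = 1 if next_value >= value else -1
        value = next_value
    is_reversal = np.zeros(n, dtype=bool)
    is_reversal[1:] = directions[1:] != directions[:-1]
    return StaircaseRun(
        run_type=run_type,
        target_quantile=0.75 if run_type == "upper" else 0.25,
        base_step=spec.base_step,
        comparison_values=values,
        responses=responses,
        is_reversal=is_reversal,
    )


def _perturbed_params(
    params: ModelParams, sd: float, rng: np.random.Generator
) -> ModelParams:
    """Per-participant lognormal jitter (median at the population values)."""
    factors = np.exp(rng.normal(0.0, sd, size=4))
    return ModelParams(
        lambda_max=params.lambda_max * factors[0],
        K=params.K * factors[1],
        n=params.n * factors[2],
        sigma2=params.sigma2 * factors[3],
    )


def generate_experiment(
    params: ModelParams,
    experiment_id: int,
    n_participants: int,
    rng: np.random.Generator,
    between_participant_variability: float | None = None,
    design: ExperimentDesign | None = None,
) -> pd.DataFrame:
    """Full trial-level dataset for both tasks of one experiment.

    Returns one row per trial in the canonical schema (``TRIAL_COLUMNS``),
    n_participants x 2 tasks x 8 standards x 2 runs x 50 trials rows.
    ``between_participant_variability``, if given, is the log-space SD of a
    lognormal perturbation applied independently to each model parameter per
    participant, emulating individual differences. Deterministic under the
    supplied generator's seed. Staircases are generated independently (the
    random interleaving of the 16 tracks within a session induces no
    dependence in this observer).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if design is None:
        design = experiment_design(experiment_id)
    rows = []
    for p in range(1, n_participants + 1):
        if between_participant_variability:
            p_params = _perturbed_params(params, between_participant_variability, rng)
        else:
            p_params = params
        for task in (TASK_DURATION, TASK_BRIGHTNESS):
            for standard in design.standards:
                for run_type in ("upper", "lower"):
                    run = run_staircase(p_params, design, standard, task, run_type, rng)
                    for i in range(design.trials_per_staircase):
                        rows.append(
                            (
                                p,
                                design.experiment_id,
                                task,
                                standard.luminance,
                                standard.duration * 1e3,
                                run_type,
                                i,
                                run.comparison_values[i],
                                int(run.responses[i]),
                                int(run.is_reversal[i]),
                            )
                        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
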