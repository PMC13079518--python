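"""Readers, writers, configuration and the end-to-end pipeline.

On-disk units are human-facing (durations in ms, luminance in cd/m^2),
matching the canonical trial schema; model-level computation in
:mod:`tiup.model_core` uses seconds. Every artifact written by
:func:`run_pipeline` is stamped with the config hash and seed so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fitting, observer, thresholds as th
from .model_core import ModelParams, predict_dl_grid

__all__ = [
    "PipelineConfig",
    "read_trials",
    "write_trials",
    "read_params",
    "write_params",
    "run_pipeline",
]

_REQUIRED = list(observer.TRIAL_COLUMNS)


def read_params(path) -> ModelParams:
    """Load a JSON parameter vector {lambda_max, K, n, sigma2}."""
    with open(path) as fh:
        d = json.load(fh)
    return ModelParams(
        lambda_max=float(d["lambda_max"]),
        K=float(d["K"]),
        n=float(d["n"]),
        sigma2=float(d["sigma2"]),
    )


def write_params(params: ModelParams, path, **extra) -> None:
    with open(path, "w") as fh:
        json.dump({**dataclasses.asdict(params), **extra}, fh, indent=2)
        fh.write("\n")


def read_trials(
    path,
    column_mapping: dict | None = None,
    duration_unit: str = "ms",
) -> pd.DataFrame:
    """Read a delimited trial-level file into the canonical schema.

    ``column_mapping`` maps external header names to canonical ones (for
    ingesting deposits with different headers); ``duration_unit`` declares
    the unit of the file's duration columns ("ms" or "s"), converted to the
    canonical ms. Malformed rows (non-binary response, non-numeric values)
    are rejected with line-numbered diagnostics; a missing required column is
    a configuration error.
    """
    frame = pd.read_csv(path, comment="#")
    if column_mapping:
        frame = frame.rename(columns=column_mapping)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"unmappable required column(s): {missing}")
    frame = frame[_REQUIRED].copy()
    numeric = ["standard_L_cd_m2", "standard_t_ms", "trial_index",
               "comparison_value", "response", "is_reversal"]
    for col in numeric:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    bad = frame[numeric].isna().any(axis=1) | ~frame["response"].isin([0, 1])
    if bad.any():
        lines = (frame.index[bad] + 2).tolist()  # 1-based + header line
        warnings.warn(
            f"rejected {int(bad.sum())} malformed row(s) at file line(s) "
            f"{lines[:20]}{'...' if len(lines) > 20 else ''}",
            stacklevel=2,
        )
        frame = frame[~bad]
    if duration_unit == "s":
        frame["standard_t_ms"] = frame["standard_t_ms"] * 1e3
        is_dur = frame["task"] == observer.TASK_DURATION
        frame.loc[is_dur, "comparison_value"] *= 1e3
    elif duration_unit != "ms":
        raise ValueError(f"duration_unit must be 'ms' or 's', got {duration_unit!r}")
    frame["response"] = frame["response"].astype(int)
    frame["is_reversal"] = frame["is_reversal"].astype(int)
    frame["trial_index"] = frame["trial_index"].astype(int)
    return frame.reset_index(drop=True)


def _write_csv(frame: pd.DataFrame, path, stamp: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (stamp or {}).items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, index=False)


def write_trials(frame: pd.DataFrame, path, stamp: dict | None = None) -> None:
    _write_csv(frame[_REQUIRED], path, stamp)


@dataclass
class PipelineConfig:
    """Everything needed for a full seeded run.

    Defaults reproduce the published experiment designs; any override is
    echoed in the config artifact. ``trials_path`` switches the pipeline
    from simulation to ingestion.
    """

    experiment: int = 1
    params: ModelParams = field(
        default_factory=lambda: ModelParams(5.02e4, 4.80e2, 1.06, 8.58e-2)
    )
    n_participants: int = 20
    seed: int = 0
    between_participant_variability: float | None = None
    trials_path: str | None = None
    column_mapping: dict | None = None
    duration_unit: str = "ms"
    standard_luminance: float = observer.EXP1_STANDARD_LUMINANCE
    bootstrap_reps: int = 10000
    discard_reversals: int = 0
    var_mode: str = "across"
    grid_luminances: tuple = (0.4, 0.8, 1.6, 3.2, 6.4)
    grid_durations_ms: tuple = (40.0, 80.0, 160.0, 320.0, 640.0)
    out_dir: str = "tiup_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        return d

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate/ingest -> thresholds -> stats -> fit -> bootstrap -> predict.

    Writes trials.csv, thresholds.csv, stats.json, fit.json, bands.csv,
    predictions.csv and config_echo.json under ``config.out_dir``; every
    artifact carries the config hash and seed. Returns the artifact paths.
    Reruns with identical config produce byte-identical numeric artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed}
    artifacts = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    design = observer.experiment_design(
        config.experiment, standard_luminance=config.standard_luminance
    )
    rng = np.random.default_rng(config.seed)

    def _trials():
        if config.trials_path:
            return read_trials(
                config.trials_path, config.column_mapping, config.duration_unit
            )
        return observer.generate_experiment(
            config.params,
            config.experiment,
            config.n_participants,
            rng,
            between_participant_variability=config.between_participant_variability,
            design=design,
        )

    trials = _stage("simulate/ingest", _trials)
    write_trials(trials, out / "trials.csv", stamp)
    artifacts["trials"] = out / "trials.csv"

    dls = _stage("thresholds", lambda: th.dl_from_runs(trials, config.discard_reversals))
    _write_csv(dls, out / "thresholds.csv", stamp)
    artifacts["thresholds"] = out / "thresholds.csv"

    def _stats():
        res = {}
        for task in (observer.TASK_DURATION, observer.TASK_BRIGHTNESS):
            anova = th.rm_anova_gg(dls, task, config.experiment)
            ci = th.morey_ci(dls, task, config.experiment)
            res[task] = {
                "anova": dataclasses.asdict(anova),
                "morey_ci": ci.to_dict(orient="list"),
            }
        return res

    stats_res = _stage("stats", _stats)
    with open(out / "stats.json", "w") as fh:
        json.dump({**stamp, **stats_res}, fh, indent=2)
        fh.write("\n")
    artifacts["stats"] = out / "stats.json"

    options = fitting.FitOptions(var_mode=config.var_mode)
    fit_res = _stage("fit", lambda: fitting.fit(dls, design, options))
    with open(out / "fit.json", "w") as fh:
        json.dump(
            {
                **stamp,
                "params": dataclasses.asdict(fit_res.params),
                "ssr_w": fit_res.ssr_w,
                "converged": fit_res.converged,
                "n_restarts_used": fit_res.n_restarts_used,
                "predicted": fit_res.predicted.to_dict(orient="list"),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    artifacts["fit"] = out / "fit.json"

    band = _stage(
        "bootstrap",
        lambda: fitting.bootstrap_bands(
            dls, design, config.bootstrap_reps,
            np.random.default_rng(config.seed + 1),
            options, point_fit=fit_res,
        ),
    )
    _write_csv(band.bands, out / "bands.csv",
               {**stamp, "n_resamples": band.n_resamples, "n_excluded": band.n_excluded})
    artifacts["bands"] = out / "bands.csv"

    def _predict():
        grid = predict_dl_grid(
            fit_res.params,
            np.asarray(config.grid_luminances, dtype=float),
            np.asarray(config.grid_durations_ms, dtype=float) / 1e3,
        )
        return grid.to_frame()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saturation flags are in the CSV as inf
        grid_frame = _stage("predict", _predict)
    _write_csv(grid_frame, out / "predictions.csv", stamp)
    artifacts["predictions"] = out / "predictions.csv"

    with open(out / "config_echo.json", "w") as fh:
        json.dump({**stamp, "config": config.to_dict()}, fh, indent=2)
        fh.write("\n")
    artifacts["config"] = out / "config_echo.json"
    return artifacts
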