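"""From trial-level staircase records to difference limens and their statistics.

The empirical difference limen of a condition is half the spread between the
two staircase endpoints: X.75 is the mean of all reversal values of the upper
run, X.25 the mean of all reversal values of the lower run, and
DL = (X.75 - X.25)/2. Condition effects are assessed with one-way
repeated-measures ANOVAs (Greenhouse-Geisser corrected, generalized eta
squared) and summarized graphically with Morey bias-corrected within-subject
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dl_from_runs",
    "threshold_matrix",
    "AnovaResult",
    "rm_anova_gg",
    "morey_ci",
]


def dl_from_runs(trials: pd.DataFrame, discard_reversals: int = 0) -> pd.DataFrame:
    """Per-participant, per-condition threshold table from trial records.

    Parameters
    ----------
    trials : DataFrame
        Canonical trial schema (see :data:`tiup.observer.TRIAL_COLUMNS`).
    discard_reversals : int
        Number of initial reversals to drop from each run before averaging.
        Default 0: all reversal points enter the estimate.

    Returns
    -------
    DataFrame
        Columns ``participant, experiment, task, standard_value, x25, x75,
        dl``. ``standard_value`` labels the condition by the experiment's
        manipulated standard axis — the standard column that varies across
        conditions (duration in ms when standards differ in duration,
        luminance in cd/m^2 when they differ in luminance); x25/x75/dl are
        always in the task's comparison units. A run without usable
        reversals leaves its condition's estimates NaN with a warning.
        Negative DLs (possible in noisy short staircases) are retained.
    """
    t = trials.copy()
    t["standard_value"] = np.nan
    for _exp, idx in t.groupby("experiment").groups.items():
        grp = t.loc[idx]
        t_varies = grp["standard_t_ms"].nunique() > 1
        L_varies = grp["standard_L_cd_m2"].nunique() > 1
        if t_varies and not L_varies:
            t.loc[idx, "standard_value"] = grp["standard_t_ms"]
        elif L_varies and not t_varies:
            t.loc[idx, "standard_value"] = grp["standard_L_cd_m2"]
        else:  # degenerate or fully crossed: key by the task's own dimension
            t.loc[idx, "standard_value"] = np.where(
                grp["task"] == "duration",
                grp["standard_t_ms"],
                grp["standard_L_cd_m2"],
            )
    keys = ["participant", "experiment", "task", "standard_value"]

    def _run_mean(group: pd.DataFrame) -> float:
        rev = group.loc[group["is_reversal"] == 1, "comparison_value"]
        rev = rev.iloc[discard_reversals:]
        return rev.mean() if len(rev) else np.nan

    means = (
        t.sort_values("trial_index")
        .groupby(keys + ["run_type"], sort=True)
        .apply(_run_mean, include_groups=False)
        .unstack("run_type")
    )
    for col in ("upper", "lower"):
        if col not in means:
            means[col] = np.nan
    out = means.rename(columns={"lower": "x25", "upper": "x75"}).reset_index()
    out["dl"] = (out["x75"] - out["x25"]) / 2.0
    n_missing = int(out[["x25", "x75"]].isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} condition(s) have a run with no usable reversals; "
            "their thresholds are NaN",
            stacklevel=2,
        )
    return out[["participant", "experiment", "task", "standard_value", "x25", "x75", "dl"]]


def threshold_matrix(
    thresholds: pd.DataFrame, task: str, experiment: int
) -> pd.DataFrame:
    """Participant x condition DL matrix for one task of one experiment.

    Participants with any missing condition are dropped (listwise deletion)
    with a warning; condition columns are sorted by standard value.
    """
    sub = thresholds[
        (thresholds["task"] == task) & (thresholds["experiment"] == experiment)
    ]
    wide = sub.pivot(index="participant", columns="standard_value", values="dl")
    wide = wide.sort_index(axis=1)
    complete = wide.dropna()
    if len(complete) < len(wide):
        warnings.warn(
            f"dropped {len(wide) - len(complete)} participant(s) with missing "
            "conditions (listwise deletion)",
            stacklevel=2,
        )
    return complete


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``df1 = epsilon*(k-1)`` and ``df2 = epsilon*(k-1)*(N-1)`` are the
    corrected degrees of freedom; ``eta_g2`` is generalized eta squared
    SS_effect / (SS_effect + SS_subject + SS_error).
    """

    F: float
    df1: float
    df2: float
    epsilon: float
    eta_g2: float
    p: float


def _rm_anova_gg_matrix(data: np.ndarray) -> AnovaResult:
    """RM ANOVA on an N x k matrix (participants x conditions)."""
    N, k = data.shape
    if N < 2 or k < 2:
        raise ValueError(f"need >= 2 participants and >= 2 conditions, got {N}x{k}")
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_effect = N * np.sum((cond_means - grand) ** 2)
    ss_subject = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_effect - ss_subject
    df_effect = k - 1
    df_error = (k - 1) * (N - 1)
    tiny = 1e-12 * max(ss_total, 1.0)
    if ss_error <= tiny:  # degenerate: no within-subject noise at all
        F = 0.0 if ss_effect <= tiny else np.inf
    else:
        F = (ss_effect / df_effect) / (ss_error / df_error)
    # Greenhouse-Geisser epsilon from the double-centered condition covariance
    S = np.cov(data, rowvar=False, ddof=1)
    C = np.eye(k) - np.ones((k, k)) / k
    S_dc = C @ S @ C
    denom = df_effect * np.sum(S_dc * S_dc)
    eps = np.trace(S_dc) ** 2 / denom if denom > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / df_effect, 1.0))
    eta_g2 = ss_effect / (ss_effect + ss_subject + ss_error)
    df1 = eps * df_effect
    df2 = eps * df_error
    p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(
        F=float(F), df1=float(df1), df2=float(df2), epsilon=eps,
        eta_g2=float(eta_g2), p=p,
    )


def rm_anova_gg(thresholds: pd.DataFrame, task: str, experiment: int) -> AnovaResult:
    """Effect of the standard level on DLs, within subjects.

    One-way repeated-measures F with Greenhouse-Geisser-corrected degrees of
    freedom and generalized eta squared; p from the corrected F distribution.
    """
    return _rm_anova_gg_matrix(threshold_matrix(thresholds, task, experiment).to_numpy())


def morey_ci(
    thresholds: pd.DataFrame, task: str, experiment: int, level: float = 0.95
) -> pd.DataFrame:
    """Within-subject confidence intervals for condition-mean DLs.

    Scores are normalized by removing each participant's mean and adding the
    grand mean; the half-width is t_{(1+level)/2, N-1} * SD/sqrt(N) *
    sqrt(k/(k-1)), the Morey bias correction for k conditions. Invariant to
    adding a constant to any single participant's scores.

    Returns a frame with columns ``standard_value, mean, half_width``.
    """
    wide = threshold_matrix(thresholds, task, experiment)
    data = wide.to_numpy()
    N, k = data.shape
    if N < 2:
        raise ValueError("need >= 2 participants")
    normalized = data - data.mean(axis=1, keepdims=True) + data.mean()
    sd = normalized.std(axis=0, ddof=1)
    correction = np.sqrt(k / (k - 1.0))
    tcrit = stats.t.ppf(0.5 + level / 2.0, N - 1)
    return pd.DataFrame(
        {
            "standard_value": wide.columns.to_numpy(dtype=float),
            "mean": data.mean(axis=0),
            "half_width": tcrit * sd / np.sqrt(N) * correction,
        }
    )
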