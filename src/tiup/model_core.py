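"""Closed-form population-code model of visual duration and brightness thresholds.

A population of luminance-sensitive neurons fires at a summed rate given by a
Naka-Rushton transducer of luminance L,

    lambda(L) = lambda_max * L**n / (L**n + K**n),

and a trial-wise multiplicative gain g ~ Gamma(mean 1, variance sigma2),
shared across the population, makes the spike count N over a window of
duration t negative-binomial with

    E[N]   = lambda(L) * t
    Var[N] = E[N] + sigma2 * E[N]**2.

The Weber fraction is the coefficient of variation of N; difference limens
(DLs) in stimulus units follow from it: DL_t = W*t for duration, and for
luminance either a first-order (transducer-slope) linearization or the exact
half-width obtained by inverting the transducer at the upper/lower threshold
rates lambda(L)*(1 +/- W).

All durations are seconds and rates Hz internally; luminance is cd/m^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "Stimulus",
    "SpikeCountMoments",
    "SaturationError",
    "SaturationWarning",
    "population_rate",
    "population_rate_slope",
    "spike_count_moments",
    "weber_fraction",
    "dl_duration",
    "dl_luminance_linear",
    "naka_rushton_inverse",
    "dl_luminance_exact",
    "predict_dl_grid",
    "DLGrid",
]


class SaturationError(ValueError):
    """The requested spike rate is at or above the population ceiling."""


class SaturationWarning(UserWarning):
    """A grid cell's upper threshold rate exceeds lambda_max; DL_L set to inf."""


@dataclass(frozen=True)
class ModelParams:
    """The four quantities parameterizing the population code.

    Attributes
    ----------
    lambda_max : float
        Maximum population firing rate, Hz. Product of population size and
        single-neuron ceiling rate; the two factors are not separately
        identifiable and are not stored separately.
    K : float
        Semi-saturation constant of the transducer, cd/m^2.
    n : float
        Transducer exponent (dimensionless).
    sigma2 : float
        Variance of the unit-mean multiplicative gain (dimensionless).
        ``sigma2 = 0`` is the pure-Poisson limit.
    """

    lambda_max: float
    K: float
    n: float
    sigma2: float

    def __post_init__(self) -> None:
        for name in ("lambda_max", "K", "n"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not np.isfinite(self.sigma2) or self.sigma2 < 0:
            raise ValueError(f"sigma2 must be finite and >= 0, got {self.sigma2!r}")


@dataclass(frozen=True)
class Stimulus:
    """A luminance/duration pair: ``luminance`` in cd/m^2, ``duration`` in seconds."""

    luminance: float
    duration: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.luminance) or self.luminance <= 0:
            raise ValueError(f"luminance must be finite and > 0, got {self.luminance!r}")
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError(f"duration must be finite and > 0, got {self.duration!r}")


@dataclass(frozen=True)
class SpikeCountMoments:
    """First two moments of the population spike count (spikes, spikes^2)."""

    mean: float
    variance: float


def population_rate(params: ModelParams, luminance):
    """Summed population firing rate lambda(L) in Hz.

    Accepts a scalar or array luminance (cd/m^2, >= 0); strictly increasing
    in L and bounded above by ``params.lambda_max``.
    """
    L = np.asarray(luminance, dtype=float)
    if np.any(L < 0):
        raise ValueError("luminance must be >= 0")
    Ln = np.power(L, params.n)
    out = params.lambda_max * Ln / (Ln + params.K**params.n)
    return out if out.ndim else float(out)


def population_rate_slope(params: ModelParams, luminance):
    """Analytic derivative d lambda / dL = lambda_max * n * K**n * L**(n-1) / (L**n + K**n)**2."""
    L = np.asarray(luminance, dtype=float)
    if np.any(L <= 0):
        raise ValueError("luminance must be > 0 for the slope")
    Kn = params.K**params.n
    Ln = np.power(L, params.n)
    out = params.lambda_max * params.n * Kn * np.power(L, params.n - 1.0) / (Ln + Kn) ** 2
    return out if out.ndim else float(out)


def spike_count_moments(params: ModelParams, stim: Stimulus) -> SpikeCountMoments:
    """Mean and variance of the negative-binomial population spike count."""
    mean = population_rate(params, stim.luminance) * stim.duration
    variance = mean + params.sigma2 * mean**2
    return SpikeCountMoments(mean=float(mean), variance=float(variance))


def _weber(params: ModelParams, L, t):
    """Vectorized Weber fraction sqrt((L^n + K^n)/(lambda_max L^n t) + sigma2).

    Overflow in extreme parameter regions (optimizer excursions) yields
    inf/nan rather than warnings; callers treat non-finite values as invalid.
    """
    L = np.asarray(L, dtype=float)
    t = np.asarray(t, dtype=float)
    with np.errstate(all="ignore"):
        Ln = np.power(L, params.n)
        Kn = params.K**params.n
        return np.sqrt((Ln + Kn) / (params.lambda_max * Ln * t) + params.sigma2)


def weber_fraction(params: ModelParams, stim: Stimulus) -> float:
    """Coefficient of variation of the spike count (dimensionless).

    Strictly decreasing in luminance and duration, with asymptote
    ``sqrt(sigma2)`` as the expected count grows.
    """
    if spike_count_moments(params, stim).mean <= 0:
        raise ValueError("Weber fraction undefined: expected spike count is zero")
    return float(_weber(params, stim.luminance, stim.duration))


def dl_duration(params: ModelParams, stim: Stimulus) -> float:
    """Duration difference limen DL_t = W * t, in seconds."""
    return weber_fraction(params, stim) * stim.duration


def dl_luminance_linear(params: ModelParams, stim: Stimulus) -> float:
    """Linearized luminance difference limen, cd/m^2.

    First-order form W * lambda(L) / lambda'(L)
    = L * (L^n + K^n) * W / (n * K^n); accurate for small W.
    """
    W = weber_fraction(params, stim)
    L = stim.luminance
    Ln = L**params.n
    Kn = params.K**params.n
    return L * (Ln + Kn) * W / (params.n * Kn)


def naka_rushton_inverse(params: ModelParams, rate) -> float:
    """Luminance at which the population fires at ``rate`` Hz.

    Closed form K * (r / (lambda_max - r))**(1/n). Raises
    :class:`SaturationError` for rates at or above ``lambda_max`` (no finite
    luminance attains them) and ``ValueError`` for rates <= 0.
    """
    r = np.asarray(rate, dtype=float)
    if np.any(r <= 0):
        raise ValueError("rate must be > 0")
    if np.any(r >= params.lambda_max):
        raise SaturationError(
            f"rate {np.max(r):g} Hz is at or above lambda_max={params.lambda_max:g} Hz"
        )
    out = params.K * np.power(r / (params.lambda_max - r), 1.0 / params.n)
    return out if out.ndim else float(out)


def dl_luminance_exact(params: ModelParams, stim: Stimulus) -> float:
    """Exact luminance difference limen by transducer inversion, cd/m^2.

    Maps the threshold rates lambda(L)*(1 +/- W) back to luminances L_u, L_l
    and returns the half-width (L_u - L_l)/2, mirroring the empirical DL
    definition (X.75 - X.25)/2. Converges to :func:`dl_luminance_linear` as
    W -> 0. Raises :class:`SaturationError` when the upper threshold rate
    reaches the population ceiling (an unattainable brightness increment).
    """
    W = weber_fraction(params, stim)
    lam = population_rate(params, stim.luminance)
    upper = lam * (1.0 + W)
    lower = lam * (1.0 - W)
    if upper >= params.lambda_max:
        raise SaturationError(
            f"upper threshold rate {upper:g} Hz >= lambda_max={params.lambda_max:g} Hz"
        )
    if lower <= 0:
        raise SaturationError("lower threshold rate is non-positive (W >= 1)")
    L_u = naka_rushton_inverse(params, upper)
    L_l = naka_rushton_inverse(params, lower)
    return 0.5 * (L_u - L_l)


def _dl_t_grid(params: ModelParams, L, t):
    """Vectorized DL_t (seconds) over broadcastable L, t arrays."""
    t = np.asarray(t, dtype=float)
    return _weber(params, L, t) * t


def _dl_L_grid(params: ModelParams, L, t):
    """Vectorized exact DL_L (cd/m^2); saturated cells become +inf (no raise)."""
    L = np.asarray(L, dtype=float)
    with np.errstate(all="ignore"):
        W = _weber(params, L, t)
        lam = params.lambda_max * np.power(L, params.n) / (
            np.power(L, params.n) + params.K**params.n
        )
        upper = lam * (1.0 + W)
        lower = lam * (1.0 - W)
        ok = (
            np.isfinite(upper) & np.isfinite(lower)
            & (upper < params.lambda_max) & (lower > 0)
        )
        out = np.full(np.broadcast(L, W).shape, np.inf)
        if np.any(ok):
            L_u = params.K * np.power(
                upper[ok] / (params.lambda_max - upper[ok]), 1.0 / params.n
            )
            L_l = params.K * np.power(
                lower[ok] / (params.lambda_max - lower[ok]), 1.0 / params.n
            )
            out[ok] = 0.5 * (L_u - L_l)
    return out


@dataclass(frozen=True)
class DLGrid:
    """Difference-limen surfaces over a luminance x duration grid.

    Arrays are shaped ``(len(luminances), len(durations))``; ``dl_t`` in
    seconds, ``dl_L`` in cd/m^2 (``inf`` where the brightness increment
    saturates the population), and the two Weber fractions DL/stimulus.
    """

    luminances: np.ndarray
    durations: np.ndarray
    dl_t: np.ndarray
    dl_L: np.ndarray
    weber_t: np.ndarray
    weber_L: np.ndarray

    def to_frame(self):
        """Long-format table with durations reported in ms (human-facing units)."""
        import pandas as pd

        Lg, tg = np.meshgrid(self.luminances, self.durations, indexing="ij")
        return pd.DataFrame(
            {
                "luminance_cd_m2": Lg.ravel(),
                "duration_ms": tg.ravel() * 1e3,
                "dl_t_ms": self.dl_t.ravel() * 1e3,
                "dl_L_cd_m2": self.dl_L.ravel(),
                "weber_t": self.weber_t.ravel(),
                "weber_L": self.weber_L.ravel(),
            }
        )


def predict_dl_grid(params: ModelParams, luminances, durations) -> DLGrid:
    """Evaluate DL_t, DL_L and both Weber fractions on a stimulus grid.

    Luminances in cd/m^2, durations in seconds, both strictly positive.
    Saturated brightness cells are flagged with ``inf`` and a
    :class:`SaturationWarning` rather than aborting the grid.
    """
    L = np.asarray(luminances, dtype=float)
    t = np.asarray(durations, dtype=float)
    if np.any(L <= 0) or np.any(t <= 0):
        raise ValueError("grid luminances and durations must be > 0")
    Lg, tg = np.meshgrid(L, t, indexing="ij")
    dl_t = _dl_t_grid(params, Lg, tg)
    dl_L = _dl_L_grid(params, Lg, tg)
    n_sat = int(np.sum(np.isinf(dl_L)))
    if n_sat:
        warnings.warn(
            f"{n_sat} grid cell(s) saturate the population rate; DL_L set to inf",
            SaturationWarning,
            stacklevel=2,
        )
    return DLGrid(
        luminances=L,
        durations=t,
        dl_t=dl_t,
        dl_L=dl_L,
        weber_t=dl_t / tg,
        weber_L=dl_L / Lg,
    )
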