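"""Doubly stochastic Poisson-gamma spike-count sampler.

Two-stage generative process for one stimulus presentation: draw a global
gain g ~ Gamma(shape 1/sigma2, scale sigma2) (unit mean, variance sigma2),
then a Poisson count with mean g * lambda(L) * t. Marginally the count is
negative binomial with mean lambda(L)*t and variance mean + sigma2*mean^2.
Serves as the noise engine for the simulated observer and as the Monte-Carlo
oracle for the closed-form moments in :mod:`tiup.model_core`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .model_core import ModelParams, Stimulus, spike_count_moments

__all__ = ["sample_gain", "sample_spike_count", "nb_pmf"]


def sample_gain(sigma2: float, rng: np.random.Generator, size=None):
    """Draw unit-mean gamma gain factor(s) with variance ``sigma2``.

    ``sigma2 = 0`` returns exactly 1 (degenerate gain, pure Poisson limit).
    """
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2!r}")
    if sigma2 == 0:
        return 1.0 if size is None else np.ones(size)
    shape = 1.0 / sigma2
    g = rng.gamma(shape=shape, scale=sigma2, size=size)
    return float(g) if size is None else g


def sample_spike_count(
    params: ModelParams, stim: Stimulus, rng: np.random.Generator, size=None
):
    """Sample population spike count(s) for one stimulus presentation.

    Each draw uses an independent gain: marginal law is the negative binomial
    of the model. Returns an int for ``size=None``, else an int array.
    """
    mean = spike_count_moments(params, stim).mean
    g = sample_gain(params.sigma2, rng, size=size)
    counts = rng.poisson(g * mean, size=size)
    return int(counts) if size is None else counts


def nb_pmf(params: ModelParams, stim: Stimulus, k):
    """Probability mass of the marginal spike-count law at count(s) ``k``.

    Negative binomial with dispersion r = 1/sigma2 and success probability
    p = r/(r + mean), so that Var = mean + mean^2/r; delegates to the Poisson
    pmf when ``sigma2 = 0``.
    """
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    mean = spike_count_moments(params, stim).mean
    if params.sigma2 == 0:
        out = stats.poisson.pmf(k, mean)
    else:
        r = 1.0 / params.sigma2
        p = r / (r + mean)
        out = stats.nbinom.pmf(k, r, p)
    return out if out.ndim else float(out)
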