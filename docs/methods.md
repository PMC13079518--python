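# Methods

## Model

The package models early-visual encoding of a luminous flash as a
homogeneous population of Poisson neurons whose summed rate follows a
Naka–Rushton transducer, λ(L) = λ_max·Lⁿ/(Lⁿ+Kⁿ), modulated by a single
trial-wise gain g shared across the population. The gain is gamma
distributed with unit mean and variance σ², so the population spike count
over an observation window of duration t is marginally negative binomial
with mean λ(L)·t and variance mean + σ²·mean². Four parameters fully
describe the code:

| parameter | meaning | units | typical fitted range |
|---|---|---|---|
| λ_max | maximum population rate | Hz | 10⁴–10⁶ (only λ_max/Kⁿ identified) |
| K | transducer semi-saturation | cd/m² | above the tested range |
| n | transducer exponent | — | 0.7–1.1 (population-level, shallower than single units) |
| σ² | gain variance | — | 0.05–0.10 |

Durations are seconds and rates Hz internally; file formats and the CLI
report durations in ms, matching how such experiments are usually described.

Thresholds derive from the count's coefficient of variation
W = √(1/E[N] + σ²): the duration difference limen is DL_t = W·t (the count
is linear in t), and the luminance difference limen is obtained exactly by
inverting the transducer at the threshold rates λ(L)·(1 ± W) and taking the
half-width (L_u − L_l)/2 — mirroring the empirical definition
DL = (X.75 − X.25)/2. A first-order alternative, W·λ(L)/λ′(L) with the
analytic slope λ′(L) = λ_max·n·Kⁿ·Lⁿ⁻¹/(Lⁿ+Kⁿ)², is provided and agrees
with the exact form to O(W) as W → 0; the exact form is used everywhere in
fitting. When λ(L)(1+W) ≥ λ_max no finite luminance can produce the upper
threshold rate: scalar calls raise a saturation error, grid prediction
flags the cell with +inf and a warning, and the fitting objective charges a
large finite penalty (10¹²) so the simplex can retreat.

## Synthetic observer

The generator emulates the two discrimination experiments trial for trial,
at the designs' published values, which are its defaults:

- Experiment 1: 8 standard durations (10–1280 ms, octave spaced) at a fixed
  3.31 cd/m² standard; duration comparisons start at 0.6×/1.4× the standard
  and step by 1/40 of it; brightness comparisons start at 1.7/4.9 cd/m²
  with a 0.1 cd/m² step.
- Experiment 2: 8 standard intensities (0.04–3.63 cd/m²) at a fixed 240 ms
  standard; brightness comparisons start at 0.5×/1.5× the standard stepping
  by 1/25 of it; duration comparisons start at 192/288 ms with a 16 ms step.
- 20 participants per experiment, 2 tasks × 8 standards × 2 runs × 50
  trials each.

The standard intensity of Experiment 1 appears in the source designs as
both 3.3 and 3.31 cd/m²; 3.31 is the default and either is accepted in
configuration.

On each two-interval trial the observer draws independent spike counts for
the standard and the comparison (independent gains per interval) and
reports the comparison as greater whenever its count is larger, flipping a
fair coin on ties — the minimal decoder consistent with both percepts being
read from the same count. Comparison values evolve under the Kaernbach
weighted up-down rule: for target quantile p the step sizes obey
p·(step after "greater") = (1−p)·(step after "not greater"), so the upper
run (X.75) moves down one base step after "greater" and up three after "not
greater", and the lower run mirrors this. "Single step size" in the designs
is read as the base (smaller) step. Values are floored at one base step
above zero; no device ceiling is modeled. The 16 staircases of a session
are generated independently — the observer has no sequential state, so the
experiment's random interleaving would not change the statistics.
Thresholds average *all* reversal values (a configuration option can
discard initial reversals but defaults to 0), X.75 and X.25 are the upper-
and lower-run reversal means, and DL is their half-difference.

Two estimands should not be conflated. The analytic DL is a coefficient-of-
variation criterion on a single count; the staircase DL is a quantile of
the two-interval psychometric function, whose difference-of-counts noise
puts it at roughly z₀.₇₅·√2 ≈ 0.95 of the analytic value, plus adaptive-
procedure bias. The test suite therefore asserts rank agreement and
convergence of staircase tracks to the observer's own Monte-Carlo
psychometric quantiles (within two base steps), not equality with the
analytic forms; parameter recovery absorbs the small systematic factor well
inside its tolerance bands. Bootstrap-coverage calibration is checked on
parametric synthetic thresholds (participant DLs scattered around the
analytic curves), where the band's estimand coincides with the generating
predictions; for staircase data the band is validated as covering the point
fit and shrinking with the number of participants.

What the generator does not emulate: lapses, response times, practice or
session-order effects, sequential dependencies, device quantization, and
heterogeneous neural tuning. Passing tests therefore certify the pipeline's
internal consistency and its behavior under the model's own assumptions,
not the full variability structure of human staircase data.

## Statistics

Condition effects on DLs use a one-way repeated-measures ANOVA with the
Greenhouse–Geisser correction: ε is computed from the double-centered
condition covariance matrix, degrees of freedom are ε(k−1) and ε(k−1)(N−1),
and the effect size is generalized eta squared
SS_effect/(SS_effect+SS_subject+SS_error). Degenerate inputs with no
within-subject variance return F = 0 (no effect) rather than 0/0. Within-
subject 95% CIs follow the Cousineau normalization (remove each
participant's mean, add the grand mean) with Morey's √(k/(k−1)) bias
correction. Participants missing any condition are dropped listwise with a
warning.

## Fitting

The four parameters are fitted per experiment by minimizing
SSR_w = Σ (E−O)²/Var(O) over all 16 conditions (8 per task), with E the
model DL (duration closed form; luminance by exact inversion), O the
condition-mean DL and Var(O) its across-participant variance. The
across-participant variance is the default reading of the weights — it is
well defined for every condition and matches the participant-level
resampling of the bootstrap; a within-subject-normalized (Morey) variant is
available via `FitOptions(var_mode="morey")`. Any zero variance is a
configuration error rather than an infinite weight.

Optimization is Nelder–Mead on log-transformed parameters (positivity by
construction) with objective tolerance 1e-10 and 400·dim iterations per
start, multi-started from a 3×3×3×3 log grid over λ_max ∈ [10³, 10⁶] Hz,
K ∈ [0.1, 10⁴] cd/m², n ∈ [0.3, 3], σ² ∈ [10⁻³, 1]; the best objective
wins and the procedure is deterministic. A joint fit constrains one
parameter vector across both experiments by summing the two objectives. An
optional roof on K (`FitOptions(K_upper=...)`) supports constrained refits.

When every tested luminance lies far below K — the regime the fitted
estimates occupy — λ_max and K trade off along a ridge and only n, σ² and
the composite λ_max/Kⁿ are recoverable. The recovery suite asserts exactly
this: n within ±0.15, σ² and λ_max/Kⁿ within ±30% at 20 simulated
participants, and a flat SSR profile for λ_max (under 5% change over a
hundredfold increase, re-optimizing the rest) against a severalfold rise
when n is mis-set by 0.15. The profile is only flat upward: lowering λ_max
forces K toward the tested luminance range, which genuinely degrades fit.

Model uncertainty uses a two-stage participant-level bootstrap: resample
participants with replacement, recompute condition means and variances,
refit (warm-started from the point fit with a single simplex run), and take
the 2.5/97.5 percentile envelope of the predicted DL curves per condition.
Failed refits are excluded and counted. The CLI default of 10,000 resamples
matches standard practice; tests and examples use a few hundred.

## Problem sizes and reproducibility

Simulated studies in the tests and acceptance script use the full design
(20 participants, 32,000 trials per experiment); Monte-Carlo oracles use
10⁵–10⁶ draws; staircase-convergence checks average 200 replicate tracks;
bootstrap examples use 100–500 resamples. All randomness flows through
numpy Generators seeded explicitly; identical seeds give bit-identical
trial tables, fits and bands, and the full pipeline stamps every artifact
with a hash of the scientific configuration plus the seed so reruns are
byte-identical.

## Known limitations

- The homogeneous-population and stimulus-independent-gain assumptions are
  simplifications; heterogeneous tuning, supersaturating transducers,
  temporally structured gain and optimal decoding are out of scope.
- λ_max and K are reported as fitted but should be interpreted only through
  the composite λ_max/Kⁿ unless the stimulus range approaches K.
- The observer's decision rule and the within-trial gain independence are
  modeling choices the underlying threshold theory does not pin down;
  alternative decoders would rescale staircase DLs by a near-constant
  factor without changing the trade-off structure.
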