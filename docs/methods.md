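# Methods

## The task and its encoding

Each trial presents a vibration whose mean speed `sp` is one of nine
linearly spaced values; the signed step distance from the category
boundary, Δspeed, is the working stimulus scale (−4…+4 for a centered
boundary; for off-center boundaries the labels shift, e.g. −5…+3, keeping
Δspeed = 0 at the boundary). The sign of Δspeed determines the rewarded
choice; boundary stimuli are rewarded at probability 0.5 regardless of the
choice. Vibration waveforms are zero-mean Gaussian velocity noise sampled
at 10 kHz and low-passed (Butterworth, 150 Hz default); since filtering
shrinks the realized standard deviation, traces are rescaled after
filtering so the empirical SD equals the nominal σ, preserving the
`sp = σ·√(2/π)` relation between the generating distribution and the mean
absolute velocity.

The extraction scheme is uniform (1/9 per level) by default. The
category-balanced scheme keeps the boundary stimulus at its configured
probability (1/9 by default) and splits the remaining mass equally between
the strictly-weak and strictly-strong categories, uniformly within each;
with a centered boundary this reduces exactly to the uniform scheme. The
per-level split of the balanced scheme is a design choice (only its
category totals are externally constrained) and is configurable.

## Psychometric model

Choice probabilities follow a lapse-augmented probit,

    p(strong) = γ + (1 − γ − λ) · ½ [1 + erf((Δspeed − μ) / (σ√2))],

with midpoint μ, underlying-Gaussian SD σ and lower/upper lapse rates
γ, λ. The PSE is `μ + σ·Φ⁻¹((0.5 − γ)/(1 − γ − λ))` (equal to μ for
symmetric lapses) and the slope at the inflection is `(1 − γ − λ)/(σ√(2π))`.

Fitting maximizes the Bernoulli log-likelihood of single-trial choices
with L-BFGS-B under box bounds, from 5 jittered moment-based starts (best
likelihood wins; ties broken toward smaller σ). Lapse rates are bounded in
[0, 0.35] by default: unconstrained lapses absorb history effects and
destabilize σ. A constrained mode fixes (γ, λ) — e.g. to a subject's
whole-data average — and fits only (μ, σ); the ITI-conditioned analyses
use this mode implicitly through their per-group fits when requested.
Degenerate inputs (one stimulus level, or all-identical choices) raise
rather than returning meaningless parameters. Bootstrap uncertainty is by
per-trial case resampling with percentile intervals; failed replicate fits
are counted, not fatal.

## Criterion-updating models

The observer compares the percept of Δspeed against a decision criterion μ
that is attracted toward recent stimuli; τ is the single free parameter.

**Discrete model** (τ in trials): one exponential step per trial,
`μ_n = μ_{n−1}·e^{−1/τ} + Δspeed_{n−1}·(1 − e^{−1/τ})`.

**Continuous model** (τ in seconds): after trial *n−1* the criterion and a
short-term memory trace of Δspeed_{n−1} relax toward *each other's current
value*. The two defining relations are mutually referential at the same
time point, so they are resolved as a simultaneous 2×2 linear system.
With `E = e^{−t/τ}`:

    μ(t)     = [μ(t₀)     + trace(t₀) · (1 − E)] / (2 − E)
    trace(t) = [trace(t₀) + μ(t₀)     · (1 − E)] / (2 − E)

This closed form satisfies three checkable identities, all enforced to
≤1e−10 in the tests: `μ + trace` is conserved for all t; the gap
`|μ − trace|` contracts by the factor `E/(2−E)`; and as t → ∞ both settle
at the midpoint `(μ(t₀) + trace(t₀))/2`. An iterative small-step
integration of the same pair converges to the same asymptote; the closed
form is adopted for exactness and speed. With a constant inter-trial
interval Δt, the continuous model is algebraically a discrete model with
retention weight `e^{−1/τ_disc} = 1/(2 − e^{−Δt/τ_cont})` — also enforced
at 1e−10.

Sequential application: the criterion starts each session at μ₀ = 0 (no
carryover across sessions); after each stimulus the trace is overwritten
with that trial's Δspeed (the 500-ms stimulus epoch treated as
instantaneous next to multi-second ITIs); the elapsed time used for the
continuous update is the recorded nose-poke-to-nose-poke ITI. Choices are
Bernoulli draws from the probit evaluated at the current criterion,
`p(strong)_n = γ + (1 − γ − λ)·½[1 + erf((Δspeed_n − μ_n)/(σ√2))]`.
Because the criterion moves *toward* past stimuli and enters the probit
with a minus sign, the observable effect is repulsive: a strong previous
stimulus makes a "strong" report less likely.

## Synthetic data generator

Defaults emulate the rat study's structure: ~300 trials per session, the
43–163 mm/s range with a centered boundary at 103 mm/s, uniform
extraction with at most 3 consecutive same-rewarded-category trials
(boundary trials counted by their randomly pre-assigned side), and
lognormal ITIs with median 7.6 s. The lognormal family was chosen as the
simplest positive-support distribution that is "roughly normal with a long
tail"; the log-SD default of 0.4 is a plausible, explicitly configurable
placeholder — no measured dispersion constrains it. The 1.5–3.5 s
post-error lockout is not modelled separately; it is absorbed into the ITI
distribution, consistent with the nose-poke-to-nose-poke ITI definition.
The default observer is the continuous model with τ = 30 s, σ = 1.2 (Δspeed
units) and symmetric 5% lapses — a sensitivity that yields realistic
(75–85%) accuracy on the nine-level scale. All randomness flows from one
seed through deterministically spawned per-session child streams, so any
dataset is byte-reproducible.

One consequence of the run-length constraint worth knowing when reading
results: it induces a mild negative serial correlation among stimuli at
short distances (≈ −0.1 at lags 1–3). The *marginal* PSE-bias slope at
lags ≥ 2 therefore decays somewhat faster than the pure geometric weight
embedded in the criterion, while the *multivariate* history GLM —
conditioning on all lags jointly — recovers the clean geometric decay.
Real sessions with the same constraint carry the same property.

What the generator does not emulate: session-level drifts in motivation or
sensitivity, reaction times, grooming/napping mechanics (only their
long-ITI footprint), asymmetric attraction between criterion and trace,
and any choice- or reward-history mechanism beyond what the criterion
dynamics imply. Passing tests therefore show that the analysis chain
recovers the known generative structure, not that real behavior contains
no other structure.

## History analyses

Conditioned curves group trial-*n* data by the stimulus, choice, or reward
of the trial `lag` back; lagged quantities are computed within session
only, so the first `lag` trials of each session never enter conditioning.
The bias measure is the PSE (the observed shift is predominantly
horizontal); the bias regression is the OLS line of per-group PSE against
the conditioning previous Δspeed, requiring ≥3 fitted groups. For
isolating choice effects, the previous stimulus can be fixed at the
boundary with rewarded-only filtering and balanced subsampling of the
previous-choice groups. The history GLM is a binomial probit regression of
choice on current and lagged Δspeed (raw integer scale; z-scoring would
only rescale the coefficients), with optional previous-reward × previous-
Δspeed and ITI × previous-Δspeed interaction terms, fitted with
statsmodels.

ITI-conditioned bias first drops the longest 20% of ITIs (retaining
exactly ⌈0.8·n⌉ rows, ties at the cut resolved by stable original order),
then bins the remaining ITIs by within-subject quantiles (median split by
default, quartiles available; a pooled grand-median mode supports the
human-style analysis) and runs the bias regression per bin. For observers
with a strong choice-repetition bias, condition-wise PSEs can be
residualized on the previous-choice indicator (OLS residuals plus grand
mean) before the stimulus-bias regression.

Per-lag slope significance uses two-tailed t-tests and is reported
unadjusted across lags (an optional Bonferroni correction is a trivial
post hoc on the returned p-values).

## Model evaluation

Predictions are scored by the Brier score (mean squared deviation of the
predicted probability from the binary choice) and AUROC (midrank tie
handling, via scikit-learn). τ is fitted by minimizing the training Brier
score; because the objective is one-dimensional and smooth, the default
optimizer is a deterministic coarse log-grid (25 points over 0.5–50 trials
or 0.5–500 s) followed by bounded Brent refinement, with a seeded
simulated-annealing backend available that lands on the same optimum. A
fit at the search boundary is flagged (memoryless data drive τ to the
upper bound).

Cross-validation partitions *sessions* (not trials) 80/20 at random per
round; τ (or the static psychometric curve of the no-history model) is
fitted on the training sessions and scored on the held-out test trials,
overall and per current-Δspeed level. The probit shape parameters
(σ, γ, λ) entering the history models are, by convention, fitted once on
the full dataset per subject before cross-validation; a leakage-free
per-fold mode is available and flagged as a deviation from that
convention. Paired per-round metrics are compared with the corrected
resampled t-test: the paired-difference variance is inflated by
`1/J + n_test/n_train` (J rounds) to account for overlapping training
sets, with J−1 degrees of freedom; Cohen's d is mean(diff)/sd(diff).

## Problem sizes and numerical choices

The test suite's standard datasets are 60 sessions × 300 trials (history
observers), 20 × 300 (memoryless control) and ~50k trials for psychometric
parameter recovery; cross-validation tests use 6–8 rounds. These sizes give
comfortable statistical margins for every directional check while keeping
the full suite around one to two minutes. Tolerances: model algebra at
1e−10; psychometric recovery within ±0.1 (μ, σ) and ±0.02 (lapses) at 50k
trials; τ recovery within ±30% at 60 sessions. Likelihood evaluations clip
probabilities to [1e−12, 1−1e−12]; the PSE is undefined (raised) when
either lapse rate reaches 0.5.

## Known limitations

- The balanced extraction scheme's within-category split is uniform by
  construction; other splits consistent with equal category totals exist.
- The attraction between criterion and trace is symmetric; asymmetric
  attraction (plausible for working-memory variants) is out of scope.
- The GLM treats ITI linearly in the interaction term.
- Real-data adapters validate schema only; no subject-level exclusion
  heuristics beyond the ITI outlier rule are provided.
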