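# vibrohist

Analysis toolkit for **history-dependent perceptual judgment** in
two-alternative vibrotactile categorization. In this task an observer (rat
or human) judges each vibration, in a long self-paced series, as "strong"
or "weak" according to whether its mean speed lies above or below a
category boundary. Judgments are not memoryless: the previous stimulus
exerts a *repulsive* bias on the current one — after a high-speed stimulus
the next is more likely to be called "weak", and vice versa — and this bias
grows with the time elapsed between trials.

`vibrohist` packages the full analysis chain for quantifying and modelling
this effect:

- **Task design** — nine-level linearly spaced stimulus sets with a category
  boundary, signed step-distance labels (Δspeed ∈ −4…+4 for the centered
  set), uniform or category-balanced extraction schemes, and synthesis of
  the Gaussian-noise vibration waveforms (mean speed `sp = σ·√(2/π)`).
- **Synthetic sessions** — complete simulated datasets (stimulus sequences
  under the ≤3 same-category-run rule, lognormal inter-trial intervals,
  model-driven choices and rewards) with the same tabular structure as real
  behavioral logs.
- **Psychometrics** — maximum-likelihood fitting of the lapse-augmented
  probit

  ```
  p(strong) = γ + (1 − γ − λ) · ½ [1 + erf((Δspeed − μ) / (σ√2))]
  ```

  with PSE, maximum slope, and case-resampled bootstrap uncertainty.
- **History analysis** — psychometric curves conditioned on previous
  stimulus/choice/reward, the PSE-vs-previous-Δspeed bias regression across
  lags, a lagged-stimulus probit GLM, and the ITI-conditioned bias with 20%
  outlier exclusion and quantile binning.
- **Criterion-updating models** — the one-parameter *discrete* model
  (`μ_n = μ_{n−1}·e^{−1/τ} + Δspeed_{n−1}·(1 − e^{−1/τ})`, τ in trials) and
  the *continuous* model, in which the criterion and a memory trace of the
  last stimulus mutually attract over the inter-trial interval with time
  constant τ in seconds, conserving `μ + trace` and converging to their
  midpoint.
- **Model evaluation** — Brier score and AUROC, τ fitting by Brier
  minimization, 80/20 session-level cross-validation of history vs.
  no-history models, and the corrected resampled t-test for paired
  per-round metrics.

## Worked example

```python
import numpy as np
from vibrohist import simulate_dataset, fit_psychometric
from vibrohist.synthetic_data import ObserverParams
from vibrohist.history_analysis import bias_vs_previous_delta, history_glm
from vibrohist.model_evaluation import fit_tau

trials = simulate_dataset(n_sessions=20, trials_per_session=300,
                          params=ObserverParams(model_type="continuous", tau=30.0),
                          seed=42)
fit = fit_psychometric(trials)
print(f"psychometric fit: mu={fit.mu:.3f} sigma={fit.sigma:.3f} "
      f"gamma={fit.gamma:.3f} lambda={fit.lam:.3f} PSE={fit.pse:.3f}")
b1 = bias_vs_previous_delta(trials, lag=1, min_group_trials=200)
b4 = bias_vs_previous_delta(trials, lag=4, min_group_trials=200)
print(f"PSE bias slope: lag1={b1.slope:.3f} (r={b1.r:.2f}), lag4={b4.slope:.3f}")
glm = history_glm(trials, n_lags=4)
print("GLM lagged betas:", np.round(glm.lagged_coefficients(), 3))
tau_hat, brier, _ = fit_tau(trials, "continuous", fit.sigma, fit.gamma, fit.lam)
print(f"fitted tau = {tau_hat:.1f} s  (training Brier {brier:.4f})")
```

Output:

```
psychometric fit: mu=0.063 sigma=1.214 gamma=0.065 lambda=0.055 PSE=0.045
PSE bias slope: lag1=0.160 (r=0.98), lag4=0.005
GLM lagged betas: [-0.095 -0.071 -0.049 -0.021]
fitted tau = 27.4 s  (training Brier 0.1064)
```

Reading the numbers: the pooled psychometric curve recovers the generating
sensory parameters (σ ≈ 1.2, lapses ≈ 0.05). The positive lag-1 bias slope
(0.160) means the psychometric midpoint is pulled ~0.16 Δspeed steps toward
the previous stimulus per step of its Δspeed — i.e. judgments are repelled
from it — and the effect has largely decayed by lag 4. The lagged GLM
coefficients are negative (repulsion on the choice scale) and decay over
lags. Refitting the single free time constant from the choices alone
recovers τ ≈ 27 s against a generating value of 30 s.

## Command line

The same pipeline is scriptable:

```bash
vibrohist simulate --seed 7 --out-dir out
vibrohist fit-psychometric out/trials.csv --out-dir out
vibrohist analyze-history out/trials.csv --lags 8 --out-dir out
vibrohist fit-model out/trials.csv --model continuous --out-dir out
vibrohist crossval out/trials.csv --rounds 100 --seed 7 --out-dir out
vibrohist report --out-dir out
```

Each stage writes CSV/JSON artifacts plus a log of parameters and seeds;
every artifact is a pure function of (inputs, config, seed). Real deposited
trial logs can be mapped onto the canonical table schema with
`vibrohist.io.read_external_table` and a column-name mapping.

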