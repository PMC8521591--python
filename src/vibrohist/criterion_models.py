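"""Criterion-updating observer models.

The observer categorizes each stimulus by comparing its percept of
``delta_speed`` against an internal decision criterion ``mu`` that is
attracted toward recently presented stimuli. Two variants share a single
free time constant ``tau``:

* **discrete** — the criterion takes one exponential step per trial:
  ``mu_n = mu_{n-1} * e^(-1/tau) + delta_{n-1} * (1 - e^(-1/tau))``,
  with ``tau`` in units of trials.

* **continuous** — between trials the criterion and a short-term memory
  trace of the last stimulus converge toward each other over real time.
  Each quantity relaxes exponentially toward the other's current value;
  resolving the mutual dependence as a simultaneous linear system gives,
  with ``E = e^(-t/tau)``::

      mu(t)    = [mu(t0)    + trace(t0) * (1 - E)] / (2 - E)
      trace(t) = [trace(t0) + mu(t0)    * (1 - E)] / (2 - E)

  The pair conserves ``mu + trace`` exactly and contracts the gap
  ``|mu - trace|`` by ``E / (2 - E)``, so as ``t -> inf`` both settle at
  the midpoint ``(mu(t0) + trace(t0)) / 2``. ``tau`` here is in seconds
  and the elapsed time is the recorded inter-trial interval.

Because the criterion never fully reaches the previous stimulus, the
observed effect on the *next* trial is repulsive: a strong previous
stimulus raises the criterion, making "strong" judgments less likely.

A ``no-history`` variant keeps the criterion fixed at its initial value,
reducing the observer to a static psychometric function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "CriterionState",
    "discrete_update",
    "continuous_update",
    "choice_probability",
    "run_observer_model",
    "equivalent_discrete_weight",
    "MODEL_TYPES",
]

MODEL_TYPES = ("discrete", "continuous", "no-history")


@dataclass
class CriterionState:
    """Criterion ``mu`` and memory trace, both in delta-speed units."""

    mu: float
    trace: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def discrete_update(mu_prev: float, delta_prev: float, tau_trials: float) -> float:
    """One trial-indexed criterion step toward the previous stimulus."""
    if tau_trials <= 0:
        raise ValueError("tau must be positive")
    w = np.exp(-1.0 / tau_trials)
    return mu_prev * w + delta_prev * (1.0 - w)


def continuous_update(
    mu_t0: float, trace_t0: float, elapsed_t: float, tau_s: float
) -> tuple[float, float]:
    """Evolve criterion and memory trace over ``elapsed_t`` seconds.

    Closed-form simultaneous solution of the mutual-attraction pair (see
    module docstring). At ``t = 0`` both are unchanged; as ``t -> inf``
    both converge to their common midpoint.
    """
    if elapsed_t < 0:
        raise ValueError("elapsed time must be nonnegative")
    if tau_s <= 0:
        raise ValueError("tau must be positive")
    e = np.exp(-elapsed_t / tau_s)
    denom = 2.0 - e
    mu_t = (mu_t0 + trace_t0 * (1.0 - e)) / denom
    trace_t = (trace_t0 + mu_t0 * (1.0 - e)) / denom
    return float(mu_t), float(trace_t)


def equivalent_discrete_weight(iti_s: float, tau_cont_s: float) -> float:
    """Per-trial retention weight of the continuous model at a fixed ITI.

    With a constant inter-trial interval ``dt``, the continuous model is
    algebraically identical to a discrete model whose retention weight
    ``e^(-1/tau_disc)`` equals ``1 / (2 - e^(-dt/tau_cont))``.
    """
    return 1.0 / (2.0 - np.exp(-iti_s / tau_cont_s))


def choice_probability(
    delta_n: np.ndarray | float,
    mu_n: np.ndarray | float,
    sigma: float,
    gamma: float,
    lam: float,
) -> np.ndarray | float:
    """Probability of a "strong" judgment given the current criterion.

    The lapse-augmented probit with the dynamic criterion as midpoint:
    ``p = gamma + (1 - gamma - lam) * 0.5 * [1 + erf((delta - mu) / (sigma*sqrt(2)))]``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if gamma < 0 or lam < 0 or gamma + lam >= 1:
        raise ValueError("lapse rates must be nonnegative with gamma + lambda < 1")
    z = (np.asarray(delta_n, dtype=float) - np.asarray(mu_n, dtype=float)) / (
        sigma * np.sqrt(2.0)
    )
    p = gamma + (1.0 - gamma - lam) * 0.5 * (1.0 + erf(z))
    return float(p) if np.isscalar(delta_n) and np.isscalar(mu_n) else p


def run_observer_model(
    deltas: Sequence[float],
    itis: Sequence[float] | None,
    model_type: str,
    tau: float,
    sigma: float,
    gamma: float,
    lam: float,
    mu0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential pass over one session: criterion and choice probability per trial.

    The criterion starts at ``mu0``. After each stimulus the memory trace is
    set to that trial's delta-speed; before the next trial the criterion is
    advanced one discrete step (``discrete``) or evolved over the recorded
    ITI (``continuous``). Returns ``(mu_at_stimulus, p_strong)`` arrays.

    Parameters
    ----------
    itis : sequence of float or None
        ``iti[i]`` is the interval preceding trial ``i``; the first entry is
        ignored (may be NaN). Required for the continuous model.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    if model_type == "continuous":
        if itis is None:
            raise ValueError("continuous model requires inter-trial intervals")
        itis = np.asarray(itis, dtype=float)
        if len(itis) != n:
            raise ValueError("itis must align with trials (first entry ignored)")
        if n > 1 and not np.all(itis[1:] > 0):
            raise ValueError("inter-trial intervals must be positive")
    mus = np.empty(n)
    mu = float(mu0)
    trace = float(mu0)
    for i in range(n):
        if i > 0:
            if model_type == "discrete":
                mu = discrete_update(mu, deltas[i - 1], tau)
            elif model_type == "continuous":
                mu, trace = continuous_update(mu, trace, float(itis[i]), tau)
        mus[i] = mu
        trace = deltas[i]
    p = choice_probability(deltas, mus, sigma, gamma, lam)
    return mus, np.asarray(p)
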