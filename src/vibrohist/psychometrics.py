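"""Lapse-augmented probit psychometric function: evaluation, ML fitting, bootstrap.

The probability of a "strong" judgment as a function of the signed stimulus
distance from the category boundary (delta-speed, -4..+4) is modelled as

    p(strong) = gamma + (1 - gamma - lambda) * 0.5 * [1 + erf((x - mu) / (sigma*sqrt(2)))]

with midpoint ``mu``, underlying-Gaussian SD ``sigma`` and lower/upper lapse
rates ``gamma``/``lambda``. Parameters are estimated by maximizing the
Bernoulli log-likelihood of single-trial choices with a bounded multi-start
quasi-Newton search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import erf, ndtri

__all__ = [
    "PsychometricFit",
    "psychometric_probability",
    "fit_psychometric",
    "pse_of",
    "max_slope_of",
    "bootstrap_psychometric",
    "DegenerateDataError",
    "UndefinedPSEError",
]

DEFAULT_LAPSE_BOUND = 0.35
DEFAULT_SIGMA_BOUNDS = (1e-3, 50.0)
DEFAULT_MU_BOUNDS = (-20.0, 20.0)
_EPS = 1e-12


class DegenerateDataError(ValueError):
    """Trial data carry no information about the psychometric curve."""


class UndefinedPSEError(ValueError):
    """p = 0.5 is not attained between the lapse asymptotes."""


@dataclass
class PsychometricFit:
    mu: float
    sigma: float
    gamma: float
    lam: float
    log_likelihood: float = np.nan
    n_trials: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.gamma < 0 or self.lam < 0 or self.gamma + self.lam >= 1:
            raise ValueError("lapse rates must satisfy 0 <= gamma, lambda, gamma+lambda < 1")

    @property
    def pse(self) -> float:
        return pse_of(self)

    @property
    def max_slope(self) -> float:
        return max_slope_of(self)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def psychometric_probability(
    delta_speed: np.ndarray | float, fit: PsychometricFit
) -> np.ndarray | float:
    """Evaluate the fitted curve; bounded in [gamma, 1 - lambda], monotone."""
    x = np.asarray(delta_speed, dtype=float)
    z = (x - fit.mu) / (fit.sigma * np.sqrt(2.0))
    p = fit.gamma + (1.0 - fit.gamma - fit.lam) * 0.5 * (1.0 + erf(z))
    return float(p) if np.isscalar(delta_speed) else p


def pse_of(fit: PsychometricFit) -> float:
    """Point of subjective equality: the stimulus where p(strong) = 0.5.

    ``PSE = mu + sigma * Phi^{-1}((0.5 - gamma) / (1 - gamma - lambda))``;
    equal to ``mu`` when the lapses are symmetric.
    """
    if fit.gamma >= 0.5 or fit.lam >= 0.5:
        raise UndefinedPSEError("p = 0.5 lies outside the asymptotes [gamma, 1 - lambda]")
    q = (0.5 - fit.gamma) / (1.0 - fit.gamma - fit.lam)
    return float(fit.mu + fit.sigma * ndtri(q))


def max_slope_of(fit: PsychometricFit) -> float:
    """Slope at the inflection point: ``(1 - gamma - lambda) / (sigma * sqrt(2*pi))``."""
    return (1.0 - fit.gamma - fit.lam) / (fit.sigma * np.sqrt(2.0 * np.pi))


def _neg_log_likelihood(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    mu, sigma, gamma, lam = theta
    z = (x - mu) / (sigma * np.sqrt(2.0))
    p = gamma + (1.0 - gamma - lam) * 0.5 * (1.0 + erf(z))
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return -float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _moment_start(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # crude moment-based initialization: midpoint from the mean stimulus
    # weighted by choice, spread from the stimulus range
    mu0 = float(np.average(x)) if y.std() == 0 else float(
        np.interp(0.5, *_empirical_curve(x, y))
    )
    sigma0 = max((x.max() - x.min()) / 4.0, 0.5)
    return np.array([mu0, sigma0, 0.02, 0.02])


def _empirical_curve(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels = np.unique(x)
    rates = np.array([y[x == v].mean() for v in levels])
    order = np.argsort(rates)
    return rates[order], levels[order]


def fit_psychometric(
    trials: pd.DataFrame,
    lapse_bound: float = DEFAULT_LAPSE_BOUND,
    sigma_bounds: tuple[float, float] = DEFAULT_SIGMA_BOUNDS,
    mu_bounds: tuple[float, float] = DEFAULT_MU_BOUNDS,
    fixed_lapses: tuple[float, float] | None = None,
    n_starts: int = 5,
    seed: int | np.random.Generator | None = 0,
) -> PsychometricFit:
    """Maximum-likelihood fit of the lapse-probit to single-trial choices.

    ``trials`` needs columns ``delta_speed`` and ``choice`` (1 = "strong").
    The search runs L-BFGS-B from ``n_starts`` jittered moment-based initial
    values; the best likelihood wins, ties broken toward smaller sigma.
    ``fixed_lapses`` pins (gamma, lambda), e.g. to a subject's average, and
    fits only (mu, sigma).

    Raises
    ------
    DegenerateDataError
        If all choices are identical or fewer than two stimulus levels occur.
    """
    x = np.asarray(trials["delta_speed"], dtype=float)
    y = np.asarray(trials["choice"], dtype=float)
    if len(x) == 0 or len(np.unique(x)) < 2:
        raise DegenerateDataError("need trials spanning at least two stimulus levels")
    if y.min() == y.max():
        raise DegenerateDataError("all choices identical; curve parameters unidentifiable")

    rng = np.random.default_rng(seed)
    start = _moment_start(x, y)
    if fixed_lapses is not None:
        g0, l0 = fixed_lapses
        bounds = [mu_bounds, sigma_bounds]

        def nll(theta2: np.ndarray) -> float:
            return _neg_log_likelihood(
                np.array([theta2[0], theta2[1], g0, l0]), x, y
            )

        base = start[:2]
    else:
        bounds = [mu_bounds, sigma_bounds, (0.0, lapse_bound), (0.0, lapse_bound)]
        nll = lambda th: _neg_log_likelihood(th, x, y)  # noqa: E731
        base = start

    best = None
    for k in range(n_starts):
        th0 = base.copy()
        if k > 0:
            jitter = rng.normal(0, [0.5, 0.3, 0.01, 0.01][: len(base)])
            th0 = th0 + jitter
        th0 = np.clip(th0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(nll, th0, method="L-BFGS-B", bounds=bounds)
        cand = (res.fun, res.x[1], res)
        if best is None or cand[:2] < best[:2]:
            best = cand
    res = best[2]
    if fixed_lapses is not None:
        mu, sigma = res.x
        gamma, lam = fixed_lapses
    else:
        mu, sigma, gamma, lam = res.x
    return PsychometricFit(
        mu=float(mu),
        sigma=float(sigma),
        gamma=float(gamma),
        lam=float(lam),
        log_likelihood=-float(res.fun),
        n_trials=len(x),
        converged=bool(res.success),
    )


def bootstrap_psychometric(
    trials: pd.DataFrame,
    n_boot: int = 200,
    seed: int | None = 0,
    resample: bool = True,
    ci: float = 0.95,
    **fit_kwargs,
) -> dict:
    """Case-resampled bootstrap of the psychometric fit.

    Returns per-replicate arrays for (mu, sigma, gamma, lambda, PSE,
    max_slope, gamma - lambda) plus percentile confidence intervals; failed
    replicate fits are recorded under ``n_failed`` and excluded.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    rng = np.random.default_rng(seed)
    n = len(trials)
    rows = {k: [] for k in ("mu", "sigma", "gamma", "lam", "pse", "max_slope", "lapse_diff")}
    n_failed = 0
    for _ in range(n_boot):
        sample = (
            trials.iloc[rng.integers(0, n, n)] if resample else trials
        )
        try:
            f = fit_psychometric(sample, seed=rng, **fit_kwargs)
            rows["mu"].append(f.mu)
            rows["sigma"].append(f.sigma)
            rows["gamma"].append(f.gamma)
            rows["lam"].append(f.lam)
            rows["pse"].append(f.pse)
            rows["max_slope"].append(f.max_slope)
            rows["lapse_diff"].append(f.gamma - f.lam)
        except (DegenerateDataError, UndefinedPSEError):
            n_failed += 1
    out = {k: np.asarray(v) for k, v in rows.items()}
    alpha = (1.0 - ci) / 2.0
    out["ci"] = {
        k: (float(np.quantile(v, alpha)), float(np.quantile(v, 1 - alpha)))
        for k, v in out.items()
        if isinstance(v, np.ndarray) and len(v)
    }
    out["n_failed"] = n_failed
    return out
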