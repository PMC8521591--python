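"""Model scoring and session-level cross-validation.

Observer models are compared on held-out sessions: the single time constant
``tau`` is fitted on a random 80% of sessions by minimizing the Brier score
of the model's trial-by-trial choice probabilities, then the history model
and a static (no-history) psychometric model are scored on the remaining
20% by Brier score and AUROC. The partition/fit/score cycle is repeated
over many random rounds; because training sets overlap across rounds, the
paired comparison uses the corrected resampled t-test (variance inflated by
``1/J + n_test/n_train``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics import roc_auc_score

from .criterion_models import run_observer_model
from .psychometrics import fit_psychometric, psychometric_probability

__all__ = [
    "CrossValResult",
    "brier_score",
    "auroc",
    "predict_sessions",
    "fit_tau",
    "cross_validate",
    "corrected_resampled_ttest",
    "TAU_BOUNDS",
]

# search ranges for the time constant, per model type
TAU_BOUNDS = {"discrete": (0.5, 50.0), "continuous": (0.5, 500.0)}


@dataclass
class CrossValResult:
    """One cross-validation round for one model."""

    round_id: int
    model_type: str
    tau_hat: float
    brier_train: float
    brier_test: float
    auroc_test: float
    auroc_by_delta: dict[int, float]
    train_session_ids: tuple[str, ...]
    test_session_ids: tuple[str, ...]
    tau_at_bound: bool = False
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "round_id": self.round_id,
            "model_type": self.model_type,
            "tau_hat": self.tau_hat,
            "brier_train": self.brier_train,
            "brier_test": self.brier_test,
            "auroc_test": self.auroc_test,
            "tau_at_bound": self.tau_at_bound,
        }
        d.update({f"auroc_delta_{k}": v for k, v in self.auroc_by_delta.items()})
        return d


def brier_score(probs: np.ndarray, choices: np.ndarray) -> float:
    """Mean squared deviation between predicted probabilities and choices."""
    probs = np.asarray(probs, dtype=float)
    choices = np.asarray(choices, dtype=float)
    if probs.shape != choices.shape:
        raise ValueError("probs and choices must have equal length")
    if len(probs) == 0:
        raise ValueError("empty input")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((probs - choices) ** 2))


def auroc(probs: np.ndarray, choices: np.ndarray) -> float:
    """Probability a "strong"-choice trial outranks a "weak"-choice trial.

    Ties count one half (midrank convention).
    """
    choices = np.asarray(choices)
    if len(np.unique(choices)) < 2:
        raise ValueError("AUROC undefined with a single choice class")
    return float(roc_auc_score(choices, np.asarray(probs, dtype=float)))


def predict_sessions(
    sessions: pd.DataFrame,
    model_type: str,
    tau: float,
    sigma: float,
    gamma: float,
    lam: float,
    mu0: float = 0.0,
) -> np.ndarray:
    """Trial-by-trial model probabilities over a multi-session table.

    The criterion restarts at ``mu0`` in every session.
    """
    probs = np.empty(len(sessions))
    pos = 0
    for _, sess in sessions.groupby("session_id", sort=False):
        _, p = run_observer_model(
            sess["delta_speed"].to_numpy(dtype=float),
            sess["iti_s"].to_numpy(dtype=float) if model_type == "continuous" else None,
            model_type,
            tau,
            sigma,
            gamma,
            lam,
            mu0,
        )
        probs[pos : pos + len(sess)] = p
        pos += len(sess)
    return probs


def fit_tau(
    train: pd.DataFrame,
    model_type: str,
    sigma: float,
    gamma: float,
    lam: float,
    mu0: float = 0.0,
    bounds: tuple[float, float] | None = None,
    n_grid: int = 25,
    xtol: float = 1e-3,
    optimizer: str = "grid",
    seed: int | None = 0,
) -> tuple[float, float, bool]:
    """Fit the time constant by minimizing the training Brier score.

    The default ``optimizer="grid"`` is deterministic: a coarse log-spaced
    grid locates the basin, then bounded golden-section/Brent refinement
    polishes it. ``optimizer="anneal"`` runs simulated annealing over the
    same range (seeded, hence reproducible); on this smooth one-dimensional
    objective both land on the same optimum, so the deterministic search is
    the default.

    Returns ``(tau_hat, brier_train, at_bound)``; ``at_bound`` flags a flat
    objective pushed to the search boundary (e.g. memoryless data favor
    arbitrarily long time constants).
    """
    if bounds is None:
        bounds = TAU_BOUNDS[model_type]
    lo, hi = bounds
    choices = train["choice"].to_numpy(dtype=float)

    def objective(tau: float) -> float:
        return brier_score(
            predict_sessions(train, model_type, tau, sigma, gamma, lam, mu0), choices
        )

    if optimizer == "anneal":
        res = optimize.dual_annealing(
            lambda th: objective(float(th[0])),
            bounds=[(lo, hi)],
            maxiter=60,
            seed=seed,
        )
        tau_hat, brier = float(res.x[0]), float(res.fun)
    elif optimizer == "grid":
        grid = np.geomspace(lo, hi, n_grid)
        vals = np.array([objective(t) for t in grid])
        k = int(np.argmin(vals))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, n_grid - 1)]
        res = optimize.minimize_scalar(objective, bounds=(a, b), method="bounded",
                                       options={"xatol": xtol})
        tau_hat = float(res.x)
        brier = float(res.fun)
        # prefer the grid point if refinement did not improve (flat objective)
        if vals[k] < brier:
            tau_hat, brier = float(grid[k]), float(vals[k])
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    rel = (tau_hat - lo) / (hi - lo)
    at_bound = rel < 0.01 or rel > 0.99
    return tau_hat, brier, at_bound


def _auroc_by_delta(
    probs: np.ndarray, test: pd.DataFrame
) -> dict[int, float]:
    out: dict[int, float] = {}
    deltas = test["delta_speed"].to_numpy()
    choices = test["choice"].to_numpy()
    for d in np.unique(deltas):
        mask = deltas == d
        if len(np.unique(choices[mask])) < 2:
            continue
        out[int(d)] = auroc(probs[mask], choices[mask])
    return out


def cross_validate(
    sessions: pd.DataFrame,
    model_types: tuple[str, ...] = ("continuous", "no-history"),
    n_rounds: int = 100,
    train_frac: float = 0.8,
    seed: int | None = 0,
    psychometric_params: tuple[float, float, float] | None = None,
    mu0: float = 0.0,
    per_fold_params: bool = False,
) -> list[CrossValResult]:
    """Session-level cross-validation of history vs. static models.

    Per round, sessions are randomly partitioned into ``train_frac`` training
    and the complementary test set; history models get their ``tau`` fitted
    on the training sessions, the ``no-history`` model a static psychometric
    curve refitted on them. All models are then scored on the test trials.

    The psychometric shape parameters ``(sigma, gamma, lambda)`` entering
    the history models' choice-probability map are, by default, fitted once
    on the full dataset (mirroring a per-subject whole-data fit);
    ``per_fold_params=True`` instead refits them inside each training fold,
    trading fidelity to that convention for strict leakage freedom.
    """
    session_ids = sessions["session_id"].unique()
    n_sessions = len(session_ids)
    if n_sessions < 5:
        raise ValueError("need at least 5 sessions for a session-level split")
    n_train = int(round(train_frac * n_sessions))
    n_train = min(max(n_train, 1), n_sessions - 1)
    rng = np.random.default_rng(seed)

    if psychometric_params is None and not per_fold_params:
        full_fit = fit_psychometric(sessions)
        psychometric_params = (full_fit.sigma, full_fit.gamma, full_fit.lam)

    results: list[CrossValResult] = []
    for r in range(n_rounds):
        perm = rng.permutation(n_sessions)
        train_ids = tuple(sorted(session_ids[perm[:n_train]]))
        test_ids = tuple(sorted(session_ids[perm[n_train:]]))
        train = sessions[sessions["session_id"].isin(train_ids)]
        test = sessions[sessions["session_id"].isin(test_ids)]
        if per_fold_params:
            fold_fit = fit_psychometric(train)
            sig, gam, lam = fold_fit.sigma, fold_fit.gamma, fold_fit.lam
        else:
            sig, gam, lam = psychometric_params
        test_choices = test["choice"].to_numpy(dtype=float)
        for model_type in model_types:
            if model_type == "no-history":
                static = fit_psychometric(train)
                p_train = psychometric_probability(
                    train["delta_speed"].to_numpy(dtype=float), static
                )
                p_test = psychometric_probability(
                    test["delta_speed"].to_numpy(dtype=float), static
                )
                tau_hat, at_bound = np.nan, False
                brier_train = brier_score(p_train, train["choice"].to_numpy(dtype=float))
            else:
                tau_hat, brier_train, at_bound = fit_tau(
                    train, model_type, sig, gam, lam, mu0
                )
                p_test = predict_sessions(test, model_type, tau_hat, sig, gam, lam, mu0)
            results.append(
                CrossValResult(
                    round_id=r,
                    model_type=model_type,
                    tau_hat=float(tau_hat),
                    brier_train=float(brier_train),
                    brier_test=brier_score(p_test, test_choices),
                    auroc_test=auroc(p_test, test_choices),
                    auroc_by_delta=_auroc_by_delta(p_test, test),
                    train_session_ids=train_ids,
                    test_session_ids=test_ids,
                    tau_at_bound=at_bound,
                    seed=seed,
                )
            )
    return results


def corrected_resampled_ttest(
    metric_a: np.ndarray,
    metric_b: np.ndarray,
    train_frac: float = 0.8,
) -> tuple[float, float, float]:
    """Paired comparison of per-round metrics with overlap-corrected variance.

    Repeated random train/test splits reuse training data across rounds, so
    the naive paired t-test is anticonservative. The corrected variance is
    ``s^2 * (1/J + n_test/n_train)`` with ``J`` rounds (Nadeau-Bengio
    correction); degrees of freedom ``J - 1``.

    Returns ``(t, p, cohens_d)`` where ``d = mean(diff) / sd(diff)``.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need paired per-round metrics with at least 2 rounds")
    d = a - b
    J = len(d)
    mean = d.mean()
    s2 = d.var(ddof=1)
    if s2 == 0:
        if mean == 0:
            return 0.0, 1.0, 0.0
        return float(np.sign(mean) * np.inf), 0.0, float(np.sign(mean) * np.inf)
    ratio = (1.0 - train_frac) / train_frac
    t = mean / np.sqrt(s2 * (1.0 / J + ratio))
    p = 2.0 * stats.t.sf(abs(t), df=J - 1)
    cohens_d = mean / np.sqrt(s2)
    return float(t), float(p), float(cohens_d)
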