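"""Trial-history analyses: conditioned psychometric curves, bias regressions,
the lagged-stimulus GLM, and ITI-conditioned bias.

The central bias measure is the point of subjective equality (PSE) of the
trial-*n* psychometric curve, conditioned on events ``lag`` trials back.
Because the curve shift induced by the previous stimulus is mainly
horizontal, the slope of PSE against previous delta-speed quantifies the
history bias: positive slope = the psychometric midpoint is attracted
toward the previous stimulus, i.e. judgments are repelled from it.

All lagged quantities respect session boundaries: the first ``lag`` trials
of every session are never used as conditioned trials, and lagged
regressors never reach across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .psychometrics import (
    DegenerateDataError,
    PsychometricFit,
    fit_psychometric,
    pse_of,
)

__all__ = [
    "BiasRegressionResult",
    "HistoryGLMResult",
    "ITIBinSpec",
    "add_lagged_columns",
    "curves_by_history",
    "bias_vs_previous_delta",
    "history_glm",
    "exclude_iti_outliers",
    "iti_conditioned_bias",
    "residualize_previous_choice",
]


class InsufficientGroupsError(ValueError):
    """Fewer than three history groups could be fitted."""


@dataclass
class BiasRegressionResult:
    """OLS line of group PSE against the conditioning previous delta-speed."""

    lag: int
    slope: float
    intercept: float
    r: float
    p_value: float
    stderr: float
    n_groups: int
    ci: tuple[float, float] = (np.nan, np.nan)

    def to_dict(self) -> dict:
        return {
            "lag": self.lag,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "p_value": self.p_value,
            "stderr": self.stderr,
            "n_groups": self.n_groups,
        }


@dataclass
class HistoryGLMResult:
    """Probit-link GLM of choice on current and lagged delta-speed."""

    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    names: list[str]
    n_lags: int
    n_trials: int
    converged: bool = True

    def lagged_coefficients(self) -> np.ndarray:
        """Coefficients on delta-speed at lags 1..n_lags (history weights)."""
        idx = [self.names.index(f"delta_lag{k}") for k in range(1, self.n_lags + 1)]
        return self.beta[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.names, "beta": self.beta, "se": self.se, "p": self.p_values}
        )


@dataclass(frozen=True)
class ITIBinSpec:
    """How to bin inter-trial intervals for the ITI-conditioned bias.

    The longest ``outlier_fraction_excluded`` of ITIs (task-unrelated pauses
    such as grooming) are dropped first; the remainder is split into
    ``n_bins`` quantile bins, computed within subject by default.
    """

    outlier_fraction_excluded: float = 0.20
    n_bins: int = 2
    per_subject: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_fraction_excluded < 1:
            raise ValueError("outlier fraction must be in [0, 1)")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")


def add_lagged_columns(
    trials: pd.DataFrame, n_lags: int, columns: tuple[str, ...] = ("delta_speed",)
) -> pd.DataFrame:
    """Append ``<col>_lag<k>`` columns, shifting within each session only."""
    out = trials.copy()
    grouped = out.groupby("session_id", sort=False)
    for col in columns:
        for k in range(1, n_lags + 1):
            out[f"{col.replace('delta_speed', 'delta')}_lag{k}"] = grouped[col].shift(k)
    return out


def curves_by_history(
    trials: pd.DataFrame,
    lag: int = 1,
    condition_on: str = "stimulus",
    previous_correct_only: bool = False,
    previous_delta: int | None = None,
    balance_groups: bool = False,
    min_group_trials: int = 50,
    seed: int | None = 0,
    **fit_kwargs,
) -> dict[int, PsychometricFit]:
    """Fit the trial-*n* psychometric curve separately per history group.

    ``condition_on`` selects the grouping variable ``lag`` trials back:
    ``stimulus`` (delta-speed), ``choice`` or ``reward``. Optional filters
    restrict to previous-correct trials or to a fixed previous delta-speed
    (e.g. 0, isolating choice effects as in the balanced-choice analysis;
    ``balance_groups`` then subsamples groups to a common size). Groups too
    small or degenerate are skipped.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    key_col = {"stimulus": "delta_speed", "choice": "choice", "reward": "rewarded"}[
        condition_on
    ]
    df = trials.copy()
    g = df.groupby("session_id", sort=False)
    df["_cond"] = g[key_col].shift(lag)
    df["_prev_delta"] = g["delta_speed"].shift(lag)
    df["_prev_rew"] = g["rewarded"].shift(lag)
    df = df.dropna(subset=["_cond"])
    if previous_correct_only:
        df = df[df["_prev_rew"] == 1]
    if previous_delta is not None:
        df = df[df["_prev_delta"] == previous_delta]
    groups = {int(k): sub for k, sub in df.groupby("_cond")}
    if balance_groups and len(groups) > 1:
        rng = np.random.default_rng(seed)
        n_min = min(len(sub) for sub in groups.values())
        groups = {
            k: sub.iloc[rng.permutation(len(sub))[:n_min]] for k, sub in groups.items()
        }
    fits: dict[int, PsychometricFit] = {}
    for k, sub in sorted(groups.items()):
        if len(sub) < min_group_trials:
            continue
        try:
            fits[k] = fit_psychometric(sub, **fit_kwargs)
        except DegenerateDataError:
            continue
    return fits


def bias_vs_previous_delta(
    trials: pd.DataFrame,
    lag: int = 1,
    fits: dict[int, PsychometricFit] | None = None,
    **curve_kwargs,
) -> BiasRegressionResult:
    """Regress per-group PSE on the previous delta-speed value.

    The slope is the history-bias measure: zero for a memoryless observer,
    positive when the decision criterion is attracted to past stimuli.
    """
    if fits is None:
        fits = curves_by_history(trials, lag=lag, condition_on="stimulus", **curve_kwargs)
    xs, ys = [], []
    for k, f in sorted(fits.items()):
        try:
            ys.append(pse_of(f))
            xs.append(k)
        except Exception:
            continue
    if len(xs) < 3:
        raise InsufficientGroupsError(
            f"only {len(xs)} history groups available at lag {lag}; need >= 3"
        )
    reg = stats.linregress(xs, ys)
    # 95% CI on the slope from the t distribution
    tcrit = stats.t.ppf(0.975, len(xs) - 2)
    return BiasRegressionResult(
        lag=lag,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r=float(reg.rvalue),
        p_value=float(reg.pvalue),
        stderr=float(reg.stderr),
        n_groups=len(xs),
        ci=(float(reg.slope - tcrit * reg.stderr), float(reg.slope + tcrit * reg.stderr)),
    )


def history_glm(
    trials: pd.DataFrame,
    n_lags: int = 10,
    interactions: frozenset[str] | set[str] = frozenset(),
) -> HistoryGLMResult:
    """Binomial probit GLM of choice on current and lagged delta-speed.

    The linear predictor is ``beta_0 + beta_1 * delta_n + beta_2 *
    delta_{n-1} + ...``; optional ``interactions`` may include
    ``"prev_reward"`` (previous delta x previous reward) and ``"iti"``
    (previous delta x ITI). Regressors are left on the raw integer
    delta-speed scale. Rows with any missing lag (the first ``n_lags``
    trials of each session) are dropped.
    """
    if n_lags < 0:
        raise ValueError("n_lags must be nonnegative")
    df = add_lagged_columns(trials, n_lags)
    cols = ["delta_speed"] + [f"delta_lag{k}" for k in range(1, n_lags + 1)]
    names = ["intercept", "delta_lag0"] + [f"delta_lag{k}" for k in range(1, n_lags + 1)]
    X = [np.asarray(df[c], dtype=float) for c in cols]
    extra_mask = np.ones(len(df), dtype=bool)
    if "prev_reward" in interactions:
        prev_rew = df.groupby("session_id", sort=False)["rewarded"].shift(1)
        X.append(np.asarray(df["delta_lag1"], dtype=float) * np.asarray(prev_rew, dtype=float))
        names.append("delta_lag1_x_prev_reward")
        extra_mask &= ~prev_rew.isna().to_numpy()
    if "iti" in interactions:
        X.append(np.asarray(df["delta_lag1"], dtype=float) * np.asarray(df["iti_s"], dtype=float))
        names.append("delta_lag1_x_iti")
        extra_mask &= ~df["iti_s"].isna().to_numpy()
    design = np.column_stack(X)
    keep = ~np.any(np.isnan(design), axis=1) & extra_mask
    design = sm.add_constant(design[keep], has_constant="add")
    y = np.asarray(df["choice"], dtype=float)[keep]
    model = sm.GLM(y, design, family=sm.families.Binomial(link=sm.families.links.Probit()))
    try:
        res = model.fit()
        converged = bool(res.converged)
    except Exception as exc:  # separation / singular design
        raise RuntimeError(f"history GLM failed to fit: {exc}") from exc
    return HistoryGLMResult(
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        names=names,
        n_lags=n_lags,
        n_trials=int(keep.sum()),
        converged=converged,
    )


def exclude_iti_outliers(
    trials: pd.DataFrame, fraction: float = 0.20, per_subject: bool = True
) -> pd.DataFrame:
    """Drop the rows with the longest ``fraction`` of ITIs.

    Exactly ``ceil((1 - fraction) * n)`` of the ``n`` rows with a defined ITI
    are retained (ties at the cut resolved by stable original order);
    first-trial rows (ITI undefined) are kept untouched.
    """
    keep = pd.Series(True, index=trials.index)
    if per_subject and "subject_id" in trials:
        groups = [sub for _, sub in trials.groupby("subject_id", sort=False)]
    else:
        groups = [trials]
    for df in groups:
        has_iti = df["iti_s"].notna()
        n = int(has_iti.sum())
        n_keep = int(np.ceil((1.0 - fraction) * n))
        order = np.argsort(df.loc[has_iti, "iti_s"].to_numpy(), kind="stable")
        drop_idx = df.loc[has_iti].index[order[n_keep:]]
        keep.loc[drop_idx] = False
    return trials.loc[keep]


def iti_conditioned_bias(
    trials: pd.DataFrame,
    spec: ITIBinSpec | None = None,
    lag: int = 1,
    **curve_kwargs,
) -> dict[int, BiasRegressionResult]:
    """History-bias regression computed separately per ITI quantile bin.

    ITI outliers are excluded first; remaining trials are assigned to
    quantile bins of their *preceding* interval (within subject by default)
    and :func:`bias_vs_previous_delta` runs per bin. For a continuous
    criterion-updating observer the long-ITI bins show the steeper slope;
    a discrete (trial-counting) observer shows no bin dependence.
    """
    if spec is None:
        spec = ITIBinSpec()
    df = exclude_iti_outliers(trials, spec.outlier_fraction_excluded, spec.per_subject).copy()

    def _bins(s: pd.Series) -> pd.Series:
        return pd.qcut(s, spec.n_bins, labels=False, duplicates="drop")

    valid = df["iti_s"].notna()
    if spec.per_subject and "subject_id" in df:
        df.loc[valid, "_iti_bin"] = (
            df.loc[valid].groupby("subject_id", sort=False)["iti_s"].transform(_bins)
        )
    else:
        df.loc[valid, "_iti_bin"] = _bins(df.loc[valid, "iti_s"])
    results: dict[int, BiasRegressionResult] = {}
    for b, sub in df.groupby("_iti_bin"):
        if not len(sub):
            raise ValueError(f"empty ITI bin {b}")
        results[int(b)] = bias_vs_previous_delta(sub, lag=lag, **curve_kwargs)
    return results


def residualize_previous_choice(
    pses: np.ndarray, previous_choice: np.ndarray
) -> np.ndarray:
    """Remove the additive previous-choice effect from condition-wise PSEs.

    Regresses the PSEs on the binary previous-choice indicator and returns
    residuals re-centered on the grand mean, isolating the stimulus-history
    component (used for observers with a strong choice-repetition bias).
    If only one previous-choice level is present the PSEs are returned
    unchanged.
    """
    pses = np.asarray(pses, dtype=float)
    prev = np.asarray(previous_choice, dtype=float)
    if len(np.unique(prev)) < 2:
        import warnings

        warnings.warn("single previous-choice level; residualization is a no-op")
        return pses.copy()
    X = sm.add_constant(prev)
    res = sm.OLS(pses, X).fit()
    return np.asarray(res.resid) + float(pses.mean())
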