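"""Synthetic vibrotactile categorization sessions.

Generates complete sessions — stimulus sequences under the category-run
constraint, self-paced inter-trial intervals from a right-skewed (lognormal)
distribution, and choices from a criterion-updating observer — with the same
tabular structure as real behavioral data, so every downstream analysis can
be exercised and validated without the deposited datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .criterion_models import MODEL_TYPES, run_observer_model
from .task_design import ExtractionScheme, StimulusSet, category_of

__all__ = [
    "ObserverParams",
    "ITIModel",
    "generate_stimulus_sequence",
    "sample_itis",
    "assign_reward",
    "simulate_session",
    "simulate_dataset",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "subject_id",
    "session_id",
    "trial_index",
    "sp_mm_per_s",
    "delta_speed",
    "choice",
    "rewarded",
    "iti_s",
]

# Median ITI reported for the rats is ~7.6 s; the log-SD sets the heaviness
# of the right tail and is configurable (not pinned down by any measurement).
DEFAULT_ITI_MEDIAN_S = 7.6
DEFAULT_ITI_LOG_SD = 0.4


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the simulated observer.

    ``tau`` is in trials for the discrete model and seconds for the
    continuous model; it is ignored by the no-history observer. ``sigma``
    is the sensory noise SD on the delta-speed scale; ``gamma``/``lam``
    are lower/upper lapse rates; ``mu0`` the criterion at session start.
    """

    tau: float = 30.0
    sigma: float = 1.2
    gamma: float = 0.05
    lam: float = 0.05
    mu0: float = 0.0
    model_type: str = "continuous"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.gamma < 0 or self.lam < 0 or self.gamma + self.lam >= 1:
            raise ValueError("invalid lapse rates")
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}")


@dataclass(frozen=True)
class ITIModel:
    """Right-skewed inter-trial interval distribution (lognormal by median)."""

    family: str = "lognormal"
    median_s: float = DEFAULT_ITI_MEDIAN_S
    dispersion: float = DEFAULT_ITI_LOG_SD

    def __post_init__(self) -> None:
        if self.family != "lognormal":
            raise ValueError("only the lognormal family is implemented")
        if self.median_s <= 0 or self.dispersion < 0:
            raise ValueError("median must be positive and dispersion nonnegative")


def generate_stimulus_sequence(
    scheme: ExtractionScheme,
    stim_set: StimulusSet,
    n_trials: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw delta-speed values i.i.d. from the scheme, capped at 3-in-a-row.

    Any draw that would create a run of ``scheme.max_category_run + 1``
    consecutive trials of one rewarded category is rejected and redrawn.
    Boundary stimuli count toward the run as their randomly pre-assigned
    rewarded side.

    Returns
    -------
    deltas : int array of delta-speed values
    boundary_sides : int array; for boundary trials the pre-assigned rewarded
        side (1 = strong, 0 = weak), -1 elsewhere.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be nonnegative")
    if len(scheme.probabilities) != len(stim_set.delta_scale):
        raise ValueError("scheme and stimulus set sizes differ")
    rng = np.random.default_rng(seed)
    deltas_grid = np.asarray(stim_set.delta_scale)
    probs = np.asarray(scheme.probabilities)
    max_run = scheme.max_category_run

    deltas = np.empty(n_trials, dtype=int)
    sides = np.full(n_trials, -1, dtype=int)
    run_cat = 0  # +1 strong, -1 weak
    run_len = 0
    for i in range(n_trials):
        while True:
            d = int(rng.choice(deltas_grid, p=probs))
            side = -1
            if d > 0:
                cat = 1
            elif d < 0:
                cat = -1
            else:
                side = int(rng.integers(0, 2))
                cat = 1 if side == 1 else -1
            if cat == run_cat and run_len >= max_run:
                continue  # would make a (max_run+1)-th same-category trial
            break
        deltas[i] = d
        sides[i] = side
        if cat == run_cat:
            run_len += 1
        else:
            run_cat = cat
            run_len = 1
    return deltas, sides


def sample_itis(
    model: ITIModel, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Sample ``n`` positive inter-trial intervals (seconds)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=math.log(model.median_s), sigma=model.dispersion, size=n)


def assign_reward(
    choice: int,
    delta_speed: int,
    seed: int | np.random.Generator | None = None,
    boundary_side: int | None = None,
) -> int:
    """Reward rule: correct-category choices are rewarded; boundary trials
    are rewarded with probability 0.5 irrespective of the choice.

    If ``boundary_side`` (1 = strong, 0 = weak) is given, a boundary trial is
    rewarded when the choice matches that pre-assigned side — marginally the
    same coin flip, but consistent with the sequence generator's bookkeeping.
    """
    cat = category_of(delta_speed)
    if cat == "strong":
        return int(choice == 1)
    if cat == "weak":
        return int(choice == 0)
    if boundary_side is not None and boundary_side >= 0:
        return int(choice == boundary_side)
    rng = np.random.default_rng(seed)
    return int(rng.integers(0, 2))


def simulate_session(
    deltas: np.ndarray,
    itis: np.ndarray,
    params: ObserverParams,
    seed: int | np.random.Generator | None = None,
    stim_set: StimulusSet | None = None,
    session_id: str = "s001",
    subject_id: str = "sim01",
    boundary_sides: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate one session of choices from the criterion-updating observer.

    ``itis`` holds one interval per gap, so ``len(itis) == len(deltas) - 1``
    (empty for sessions of one trial or fewer). Choices are Bernoulli draws
    from the observer's trial-by-trial choice probability; rewards follow
    :func:`assign_reward`. The criterion starts at ``params.mu0`` — no state
    carries over from any previous session.
    """
    deltas = np.asarray(deltas, dtype=int)
    n = len(deltas)
    itis = np.asarray(itis, dtype=float)
    if n > 0 and len(itis) != n - 1:
        raise ValueError("need exactly one ITI per between-trial gap")
    rng = np.random.default_rng(seed)

    iti_col = np.concatenate([[np.nan], itis]) if n else np.array([])
    _, p_strong = run_observer_model(
        deltas,
        iti_col if params.model_type == "continuous" else None,
        params.model_type,
        params.tau,
        params.sigma,
        params.gamma,
        params.lam,
        params.mu0,
    )
    choices = (rng.random(n) < p_strong).astype(int)
    if boundary_sides is None:
        boundary_sides = np.full(n, -1, dtype=int)
    rewards = np.array(
        [
            assign_reward(choices[i], deltas[i], rng, int(boundary_sides[i]))
            for i in range(n)
        ],
        dtype=int,
    )
    sp = (
        np.array([stim_set.sp_of_delta(int(d)) for d in deltas])
        if stim_set is not None
        else np.asarray(deltas, dtype=float)
    )
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "session_id": session_id,
            "trial_index": np.arange(1, n + 1),
            "sp_mm_per_s": sp,
            "delta_speed": deltas,
            "choice": choices,
            "rewarded": rewards,
            "iti_s": iti_col,
        }
    )


def simulate_dataset(
    n_sessions: int = 40,
    trials_per_session: int = 300,
    params: ObserverParams | None = None,
    scheme: ExtractionScheme | None = None,
    stim_set: StimulusSet | None = None,
    iti_model: ITIModel | None = None,
    seed: int | None = 0,
    subject_id: str = "sim01",
) -> pd.DataFrame:
    """Simulate a full multi-session dataset as one tidy trial table.

    Defaults mirror the rat study's structure: ~300 self-paced trials per
    session, nine uniform stimulus levels on the 43-163 mm/s range with the
    boundary centered at 103 mm/s, lognormal ITIs with median 7.6 s, and a
    continuous criterion-updating observer (tau = 30 s). Per-session child
    seeds are derived deterministically from ``seed``.
    """
    from .task_design import build_stimulus_set, extraction_probabilities

    if params is None:
        params = ObserverParams()
    if stim_set is None:
        stim_set = build_stimulus_set(43.0, 163.0, 103.0)
    if scheme is None:
        scheme = extraction_probabilities(stim_set, "uniform")
    if iti_model is None:
        iti_model = ITIModel()
    ss = np.random.SeedSequence(seed)
    frames = []
    for k, child in enumerate(ss.spawn(n_sessions)):
        rng = np.random.default_rng(child)
        deltas, sides = generate_stimulus_sequence(scheme, stim_set, trials_per_session, rng)
        itis = sample_itis(iti_model, max(trials_per_session - 1, 0), rng)
        frames.append(
            simulate_session(
                deltas,
                itis,
                params,
                rng,
                stim_set=stim_set,
                session_id=f"s{k + 1:03d}",
                subject_id=subject_id,
                boundary_sides=sides,
            )
        )
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)
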