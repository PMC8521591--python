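"""Stimulus-set construction and vibration synthesis for the speed-categorization task.

A session presents vibrations drawn from nine linearly spaced mean speeds
(``sp``, mm/s). Each stimulus is labelled by its signed step distance from the
category boundary (``delta_speed``); the sign of ``delta_speed`` determines
which choice is rewarded. Vibrations themselves are zero-mean Gaussian
velocity noise, low-pass filtered, whose mean absolute velocity (the "mean
speed") relates to the generating standard deviation by ``sp = sigma *
sqrt(2/pi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

N_LEVELS = 9

__all__ = [
    "StimulusSet",
    "ExtractionScheme",
    "VibrationTrace",
    "build_stimulus_set",
    "category_of",
    "extraction_probabilities",
    "synthesize_vibration",
    "nominal_mean_speed",
    "sigma_for_mean_speed",
]


class InvalidBoundaryError(ValueError):
    """The requested category boundary does not lie on the stimulus grid."""


class InvalidSchemeError(ValueError):
    """An extraction scheme cannot be formed (e.g. an empty category)."""


@dataclass(frozen=True)
class StimulusSet:
    """Nine linearly spaced mean speeds with a category boundary.

    Attributes
    ----------
    sp_values : tuple of float
        The nine mean speeds in mm/s, strictly increasing, constant step.
    boundary_sp : float
        The mean speed at the category boundary; must be one of ``sp_values``.
    delta_scale : tuple of int
        Signed step distance of each ``sp`` from the boundary. For the
        centered default set this is -4..+4; for off-center boundaries the
        range shifts accordingly (e.g. -5..+3).
    """

    sp_values: tuple[float, ...]
    boundary_sp: float
    delta_scale: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.sp_values) != N_LEVELS:
            raise ValueError(f"expected {N_LEVELS} sp values, got {len(self.sp_values)}")
        diffs = np.diff(self.sp_values)
        if not np.all(diffs > 0):
            raise ValueError("sp values must be strictly increasing")
        if not np.allclose(diffs, diffs[0]):
            raise ValueError("sp values must be linearly spaced")
        if not self.delta_scale:
            object.__setattr__(self, "delta_scale", self._compute_deltas())
        if self.delta_scale[self.boundary_index] != 0:
            raise InvalidBoundaryError("delta scale inconsistent with boundary")

    def _compute_deltas(self) -> tuple[int, ...]:
        step = (self.sp_values[-1] - self.sp_values[0]) / (N_LEVELS - 1)
        deltas = [(sp - self.boundary_sp) / step for sp in self.sp_values]
        rounded = [round(d) for d in deltas]
        if not np.allclose(deltas, rounded, atol=1e-9):
            raise InvalidBoundaryError(
                f"boundary {self.boundary_sp} is not on the stimulus grid {self.sp_values}"
            )
        return tuple(int(d) for d in rounded)

    @property
    def boundary_index(self) -> int:
        idx = int(np.argmin(np.abs(np.asarray(self.sp_values) - self.boundary_sp)))
        if not math.isclose(self.sp_values[idx], self.boundary_sp, abs_tol=1e-9):
            raise InvalidBoundaryError(
                f"boundary {self.boundary_sp} is not one of the sp values"
            )
        return idx

    def sp_of_delta(self, delta: int) -> float:
        """Mean speed corresponding to a signed step distance from the boundary."""
        return self.sp_values[self.delta_scale.index(delta)]

    def to_dict(self) -> dict:
        return {
            "lowest_sp": self.sp_values[0],
            "highest_sp": self.sp_values[-1],
            "boundary_sp": self.boundary_sp,
        }


@dataclass(frozen=True)
class ExtractionScheme:
    """Per-stimulus selection probabilities and the category-run constraint.

    ``max_category_run`` caps the number of consecutive trials whose rewarded
    category is the same (boundary trials count as their randomly pre-assigned
    side); the task enforces at most 3 to discourage one-sided habits.
    """

    probabilities: tuple[float, ...]
    mode: str = "uniform"
    max_category_run: int = 3

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if len(p) != N_LEVELS:
            raise InvalidSchemeError(f"expected {N_LEVELS} probabilities")
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise InvalidSchemeError("probabilities must be nonnegative and sum to 1")


@dataclass(frozen=True)
class VibrationTrace:
    """A synthesized velocity time series (mm/s) at sampling rate ``fs`` (Hz)."""

    velocity_samples: np.ndarray
    fs: float
    duration_s: float
    nominal_sigma: float

    def __post_init__(self) -> None:
        expected = round(self.fs * self.duration_s)
        if len(self.velocity_samples) != expected:
            raise ValueError("sample count must equal round(fs * duration_s)")

    @property
    def mean_speed(self) -> float:
        """Empirical mean absolute velocity of the trace."""
        return float(np.mean(np.abs(self.velocity_samples)))


def build_stimulus_set(
    lowest_sp: float, highest_sp: float, boundary_sp: float
) -> StimulusSet:
    """Construct the nine-level stimulus set from its range and boundary.

    Raises
    ------
    InvalidBoundaryError
        If ``boundary_sp`` does not coincide with one of the nine grid values.
    """
    if not lowest_sp < highest_sp:
        raise ValueError("lowest_sp must be below highest_sp")
    values = tuple(np.linspace(lowest_sp, highest_sp, N_LEVELS).tolist())
    return StimulusSet(sp_values=values, boundary_sp=boundary_sp)


def category_of(delta_speed: int) -> str:
    """Rewarded category of a stimulus: 'strong' above the boundary, 'weak' below.

    A stimulus exactly on the boundary (``delta_speed == 0``) belongs to
    neither category; reward is then assigned at random.
    """
    if delta_speed > 0:
        return "strong"
    if delta_speed < 0:
        return "weak"
    return "boundary"


def extraction_probabilities(
    stim_set: StimulusSet,
    mode: str = "uniform",
    boundary_prob: float | None = None,
    max_category_run: int = 3,
) -> ExtractionScheme:
    """Build the per-stimulus selection probabilities.

    ``uniform`` assigns 1/9 to every value. ``category-balanced`` equalizes
    the total probability of the strictly-weak and strictly-strong categories
    (uniform within each); the boundary stimulus keeps ``boundary_prob``
    (default 1/9). With a centered boundary the balanced scheme coincides
    with the uniform one.
    """
    deltas = np.asarray(stim_set.delta_scale)
    if mode == "uniform":
        probs = np.full(N_LEVELS, 1.0 / N_LEVELS)
    elif mode == "category-balanced":
        n_weak = int(np.sum(deltas < 0))
        n_strong = int(np.sum(deltas > 0))
        if n_weak == 0 or n_strong == 0:
            raise InvalidSchemeError("balanced scheme needs members in both categories")
        has_boundary = bool(np.any(deltas == 0))
        p_boundary = (boundary_prob if boundary_prob is not None else 1.0 / N_LEVELS) if has_boundary else 0.0
        per_cat = (1.0 - p_boundary) / 2.0
        probs = np.empty(N_LEVELS)
        probs[deltas < 0] = per_cat / n_weak
        probs[deltas > 0] = per_cat / n_strong
        probs[deltas == 0] = p_boundary
    else:
        raise InvalidSchemeError(f"unknown mode {mode!r}")
    return ExtractionScheme(
        probabilities=tuple(probs.tolist()), mode=mode, max_category_run=max_category_run
    )


def nominal_mean_speed(sigma: float) -> float:
    """Mean speed of a zero-mean Gaussian velocity process: ``sigma * sqrt(2/pi)``."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    return sigma * math.sqrt(2.0 / math.pi)


def sigma_for_mean_speed(sp: float) -> float:
    """Inverse of :func:`nominal_mean_speed`."""
    if sp < 0:
        raise ValueError("sp must be nonnegative")
    return sp / math.sqrt(2.0 / math.pi)


def synthesize_vibration(
    sigma: float,
    duration_s: float = 0.5,
    fs: float = 10_000.0,
    cutoff: float = 150.0,
    seed: int | np.random.Generator | None = None,
    order: int = 4,
) -> VibrationTrace:
    """Synthesize a low-pass filtered Gaussian velocity trace.

    Velocity samples are drawn i.i.d. from N(0, sigma^2) at ``fs`` Hz and
    low-passed through a Butterworth filter with the given cutoff. Filtering
    shrinks the realized standard deviation, so the trace is rescaled post
    hoc to restore an empirical SD of ``sigma``, keeping the nominal
    ``sp = sigma * sqrt(2/pi)`` bookkeeping exact in expectation.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    n = round(fs * duration_s)
    rng = np.random.default_rng(seed)
    if sigma == 0:
        v = np.zeros(n)
    else:
        white = rng.normal(0.0, sigma, n)
        sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
        v = signal.sosfiltfilt(sos, white)
        v = v - v.mean()
        sd = v.std()
        if sd > 0:
            v = v * (sigma / sd)
    return VibrationTrace(velocity_samples=v, fs=fs, duration_s=duration_s, nominal_sigma=sigma)
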