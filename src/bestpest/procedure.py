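"""The modified Best-PEST adaptive acuity procedure.

Classic Best PEST places every trial at the current maximum-likelihood
threshold estimate under a fixed-slope psychometric model.  The variant
implemented here adds two modifications used in computerized acuity
testing:

* an initial descent: starting from an easy 1.0-LogMAR optotype the size
  is halved (0.3 LogMAR per step, matching the printed sequence
  1.0, 0.7, 0.4, 0.1, ...) until the first incorrect response, after which
  the ML placement takes over;
* periodic "easy" trials (by default every 6th trial from trial 12) where
  the optotype is enlarged by a fixed factor (3x, i.e. +log10(3) LogMAR)
  to keep the observer motivated.  Easy responses are real forced-choice
  trials and enter the likelihood at their actual presented level.

The estimator assumes a lapse-free model (lambda = 0) with a known guess
rate and slope; candidate thresholds live on a fixed LogMAR grid and ties
are broken toward the smallest candidate (best acuity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, log_expit

from .observers import PsychometricModel, simulate_response

__all__ = [
    "TrialRecord",
    "ProcedureSettings",
    "Run",
    "best_pest_estimate",
    "next_stimulus",
    "run_procedure",
    "final_outcome",
]


@dataclass(frozen=True)
class TrialRecord:
    """One presented optotype and its outcome.

    ``estimate_after`` is the ML threshold estimate over trials 1..i,
    always a grid candidate (and therefore inside the grid bounds).
    """

    trial_index: int  # 1-based
    presented: float  # LogMAR actually shown (includes any easy enlargement)
    correct: bool
    is_easy: bool
    estimate_after: float


@dataclass(frozen=True)
class ProcedureSettings:
    """Tunables of the adaptive procedure and its internal estimator.

    The estimator's assumed model is (guess_rate, assumed_slope, lambda=0);
    a slope differing from the simulated observer's is allowed for
    robustness experiments.
    """

    start_level: float = 1.0
    initial_step: float = 0.3
    easy_start: int = 12          # first easy trial index
    easy_interval: int = 6        # subsequent easy trials every this many
    easy_trial_indices: tuple[int, ...] | None = None  # explicit override
    easy_factor: float = 3.0
    grid_min: float = -1.5
    grid_max: float = 2.0
    grid_step: float = 0.01
    guess_rate: float = 0.125
    assumed_slope: float = 0.07
    run_length: int = 48

    def __post_init__(self) -> None:
        if not self.grid_step > 0:
            raise ValueError("grid_step must be > 0")
        if not self.grid_min <= self.start_level <= self.grid_max:
            raise ValueError("grid bounds must contain start_level")
        if not self.easy_factor > 1:
            raise ValueError("easy_factor must be > 1")
        if not 0 < self.guess_rate < 1:
            raise ValueError("guess_rate must be in (0, 1)")
        if not self.assumed_slope > 0:
            raise ValueError("assumed_slope must be > 0")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")

    def grid(self) -> np.ndarray:
        """Ascending threshold candidates, inclusive of both bounds."""
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)

    def is_easy_trial(self, trial_index: int) -> bool:
        """Whether the given 1-based trial index is an enlarged 'easy' trial."""
        if self.easy_trial_indices is not None:
            return trial_index in self.easy_trial_indices
        if trial_index < self.easy_start:
            return False
        return (trial_index - self.easy_start) % self.easy_interval == 0

    @property
    def easy_offset(self) -> float:
        """LogMAR increment of an easy trial (enlargement factor on a log scale)."""
        return math.log10(self.easy_factor)


def _grid_log_likelihood(
    levels: np.ndarray, corrects: np.ndarray, settings: ProcedureSettings
) -> np.ndarray:
    """Log-likelihood of the response history at every grid candidate.

    Uses the estimator's assumed lapse-free model:
    p(x; alpha) = gamma + (1 - gamma) * logistic((x - alpha) / sigma).
    gamma > 0 and p < 1 keep both log terms finite; the incorrect-response
    term is computed as log(1 - gamma) + log_expit(-z), which stays finite
    even where expit(z) rounds to 1.
    """
    grid = settings.grid()
    gamma = settings.guess_rate
    z = (levels[:, None] - grid[None, :]) / settings.assumed_slope
    ll_correct = np.log(gamma + (1.0 - gamma) * expit(z))
    ll_incorrect = np.log(1.0 - gamma) + log_expit(-z)
    ll = np.where(corrects[:, None], ll_correct, ll_incorrect)
    return ll.sum(axis=0)


def best_pest_estimate(
    history: Sequence[TrialRecord], settings: ProcedureSettings
) -> float:
    """ML threshold estimate: the grid candidate maximizing the likelihood.

    Ties are broken toward the smallest candidate (best acuity), which
    ``np.argmax`` gives for free on the ascending grid.

    Raises
    ------
    ValueError
        On an empty history or a non-finite presented level.
    """
    if not history:
        raise ValueError("history must be non-empty")
    levels = np.array([t.presented for t in history], dtype=float)
    if not np.all(np.isfinite(levels)):
        raise ValueError("presented levels must be finite")
    corrects = np.array([t.correct for t in history], dtype=bool)
    ll = _grid_log_likelihood(levels, corrects, settings)
    grid = settings.grid()
    return float(grid[int(np.argmax(ll))])


def _in_descent(history: Sequence[TrialRecord]) -> bool:
    """True while the initial halving phase is active (no error yet)."""
    return all(t.correct for t in history)


def _base_level(history: Sequence[TrialRecord], settings: ProcedureSettings) -> float:
    """Non-easy level the procedure would present after this history."""
    if _in_descent(history):
        # descent levels are exact decimals (1.0, 0.7, 0.4, 0.1, ...); rounding
        # removes the float error of start - k*step so the sequence is bit-exact
        level = round(settings.start_level - settings.initial_step * len(history), 10)
        return float(min(max(level, settings.grid_min), settings.grid_max))
    return best_pest_estimate(history, settings)


def next_stimulus(
    history: Sequence[TrialRecord], settings: ProcedureSettings
) -> tuple[float, bool]:
    """Level (LogMAR) and easy flag of the upcoming trial.

    While no error has occurred the levels follow the descending sequence
    start, start - step, ... (clipped to the grid bounds); afterwards each
    trial is placed at the current ML estimate.  If the upcoming 1-based
    index is an easy trial the level is raised by log10(easy_factor) and
    flagged.
    """
    if len(history) >= settings.run_length:
        raise ValueError("run already complete")
    level = _base_level(history, settings)
    upcoming = len(history) + 1
    if settings.is_easy_trial(upcoming):
        return level + settings.easy_offset, True
    return level, False


@dataclass(frozen=True)
class Run:
    """One completed adaptive session.

    ``checkpoint_outcomes`` maps intermediate run lengths (multiples of 6
    up to the run length) to the acuity outcome the procedure would have
    reported had it stopped there; populated by the study harness.
    """

    condition_key: str
    run_index: int
    trials: tuple[TrialRecord, ...]
    checkpoint_outcomes: dict[int, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)


def run_procedure(
    observer: PsychometricModel,
    settings: ProcedureSettings,
    rng: np.random.Generator,
    condition_key: str = "",
    run_index: int = 0,
) -> Run:
    """Execute one full adaptive run against a simulated observer.

    Deterministic given the rng state.  The per-trial ML estimate is
    maintained incrementally (one grid-sized update per trial).
    """
    grid = settings.grid()
    gamma = settings.guess_rate
    loglik = np.zeros_like(grid)
    trials: list[TrialRecord] = []
    for i in range(1, settings.run_length + 1):
        level, easy = next_stimulus(trials, settings)
        correct = simulate_response(observer, level, rng)
        z = (level - grid) / settings.assumed_slope
        if correct:
            loglik += np.log(gamma + (1.0 - gamma) * expit(z))
        else:
            loglik += np.log(1.0 - gamma) + log_expit(-z)
        estimate = float(grid[int(np.argmax(loglik))])
        trials.append(
            TrialRecord(
                trial_index=i,
                presented=float(level),
                correct=correct,
                is_easy=easy,
                estimate_after=estimate,
            )
        )
    return Run(condition_key=condition_key, run_index=run_index, trials=tuple(trials))


def final_outcome(run: Run, settings: ProcedureSettings | None = None) -> float:
    """The run's acuity outcome: the non-easy level that would be presented next.

    Once the descent phase has ended this equals the ML estimate after the
    last trial; an easy enlargement on the final trial never leaks into the
    outcome.  ``settings`` defaults to the standard procedure sized to the
    run.

    Raises
    ------
    ValueError
        If the run has no trials.
    """
    if not run.trials:
        raise ValueError("run is empty")
    if settings is None:
        settings = ProcedureSettings(run_length=len(run.trials))
    return _base_level(run.trials, settings)
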