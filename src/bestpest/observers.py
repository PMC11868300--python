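"""Simulated forced-choice observers and cohort generation.

An observer is a psychometric function mapping optotype size (in LogMAR,
larger = bigger = easier) to the probability of a correct response in an
n-alternative forced-choice task:

    P(correct | x) = gamma + (1 - gamma - lambda) * S((x - alpha) / sigma)

with guess rate ``gamma`` (1/n_alternatives), lapse rate ``lambda``,
threshold ``alpha`` at the inflection point, slope spread ``sigma`` and a
logistic inner sigmoid ``S``.  At ``x = alpha`` the probability is exactly
``gamma + (1 - gamma - lambda) / 2``.

A cohort is a set of such observers, one per test-retest condition
(participant x eye x blur state), with true thresholds drawn stratified
over 0.3-LogMAR bins so the whole configured acuity range is populated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "PsychometricModel",
    "CohortConfig",
    "ConditionSpec",
    "probability_correct",
    "simulate_response",
    "generate_cohort",
    "cohort_to_frame",
]


@dataclass(frozen=True)
class PsychometricModel:
    """Fixed-slope n-AFC psychometric function with threshold at the inflection point.

    Parameters
    ----------
    threshold : float
        Stimulus level alpha (LogMAR) at the inflection point of the inner
        sigmoid; this is the quantity the adaptive procedure estimates.
    slope_spread : float
        Dispersion sigma of the inner logistic, in LogMAR units.
    guess_rate : float
        Probability gamma of a correct response by pure guessing
        (1/n_alternatives for a forced-choice task).
    lapse_rate : float
        Probability lambda of a stimulus-independent error (attention slip).
    n_alternatives : int
        Number of response choices (8 for Landolt-C orientations).
    """

    threshold: float
    slope_spread: float = 0.07
    guess_rate: float = 0.125
    lapse_rate: float = 0.01
    n_alternatives: int = 8

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if not 0.0 < self.guess_rate < 1.0:
            raise ValueError(f"guess_rate must be in (0, 1), got {self.guess_rate}")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError(f"lapse_rate must be in [0, 0.5), got {self.lapse_rate}")
        if not self.slope_spread > 0.0:
            raise ValueError(f"slope_spread must be > 0, got {self.slope_spread}")
        if self.guess_rate + self.lapse_rate >= 1.0:
            # otherwise 1 - gamma - lambda < 0 and the function would decrease
            raise ValueError("guess_rate + lapse_rate must be < 1")
        if self.n_alternatives < 2:
            raise ValueError("n_alternatives must be >= 2")

    @classmethod
    def from_alternatives(cls, n_alternatives: int, threshold: float, **kwargs) -> "PsychometricModel":
        """Build a model with guess_rate derived as 1/n_alternatives."""
        return cls(
            threshold=threshold,
            guess_rate=1.0 / n_alternatives,
            n_alternatives=n_alternatives,
            **kwargs,
        )

    def with_threshold(self, threshold: float) -> "PsychometricModel":
        return replace(self, threshold=threshold)


def probability_correct(model: PsychometricModel, stimulus):
    """Probability of a correct response at a stimulus level (LogMAR).

    Vectorized over ``stimulus``.  Bounded in ``[guess_rate, 1 - lapse_rate]``
    and monotone non-decreasing in the stimulus (larger optotype = easier).

    Raises
    ------
    ValueError
        If any stimulus value is non-finite.
    """
    x = np.asarray(stimulus, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("stimulus must be finite")
    z = (x - model.threshold) / model.slope_spread
    p = model.guess_rate + (1.0 - model.guess_rate - model.lapse_rate) * expit(z)
    if np.ndim(stimulus) == 0:
        return float(p)
    return p


def simulate_response(model: PsychometricModel, stimulus: float, rng: np.random.Generator) -> bool:
    """Draw one Bernoulli correct/incorrect response from the observer.

    The caller owns and seeds ``rng``; identical streams yield identical
    response sequences.
    """
    p = probability_correct(model, stimulus)
    return bool(rng.random() < p)


@dataclass(frozen=True)
class ConditionSpec:
    """One test-retest condition: identifying labels plus the simulated observer."""

    key: str
    eye: str
    blur: str
    observer: PsychometricModel


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the simulated cohort.

    ``n_condition_pairs`` conditions are generated; true thresholds are
    drawn stratified-uniform over ``strat_bin_width``-wide bins spanning
    ``acuity_range`` (lower, upper, LogMAR).  Eye and blur labels are
    assigned cyclically over the cross product of the label sets.
    """

    n_condition_pairs: int = 78
    acuity_range: tuple[float, float] = (-0.6, 1.2)
    eye_conditions: tuple[str, ...] = ("OU", "OD", "OS")
    blur_levels: tuple[str, ...] = ("none", "mild", "strong")
    observer_defaults: PsychometricModel = field(
        default_factory=lambda: PsychometricModel(threshold=0.0)
    )
    run_length: int = 48
    strat_bin_width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_condition_pairs < 1:
            raise ValueError("n_condition_pairs must be >= 1")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        lo, hi = self.acuity_range
        if not lo < hi:
            raise ValueError(f"acuity_range lower must be < upper, got {self.acuity_range}")
        if not self.eye_conditions:
            raise ValueError("eye_conditions must be non-empty")
        if not self.blur_levels:
            raise ValueError("blur_levels must be non-empty")
        if not self.strat_bin_width > 0:
            raise ValueError("strat_bin_width must be > 0")


def _stratified_thresholds(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw thresholds stratified-uniform over bins covering the acuity range.

    Bins partition [lo, hi] into ceil(width / bin_width) slices (the last
    one possibly narrower).  Counts are spread as evenly as possible with
    the remainder going to the first bins, so every bin is non-empty once
    n_condition_pairs >= n_bins.
    """
    lo, hi = config.acuity_range
    width = hi - lo
    n_bins = max(1, int(math.ceil(width / config.strat_bin_width - 1e-9)))
    n = config.n_condition_pairs
    base, extra = divmod(n, n_bins)
    counts = [base + (1 if i < extra else 0) for i in range(n_bins)]
    draws = []
    for i, count in enumerate(counts):
        b_lo = lo + i * config.strat_bin_width
        b_hi = min(b_lo + config.strat_bin_width, hi)
        draws.append(rng.uniform(b_lo, b_hi, size=count))
    thresholds = np.concatenate(draws)
    # interleave bins so condition order does not correlate with acuity
    order = rng.permutation(n)
    return thresholds[order]


def generate_cohort(config: CohortConfig) -> list[ConditionSpec]:
    """Generate the cohort's condition specifications.

    Pure function of the config (including its seed): returns exactly
    ``n_condition_pairs`` specs, with true thresholds covering the
    configured acuity range via stratified sampling.
    """
    rng = np.random.default_rng(config.seed)
    thresholds = _stratified_thresholds(config, rng)
    labels = itertools.cycle(
        itertools.product(config.eye_conditions, config.blur_levels)
    )
    specs = []
    for i, (alpha, (eye, blur)) in enumerate(zip(thresholds, labels)):
        key = f"C{i + 1:03d}"
        observer = config.observer_defaults.with_threshold(float(alpha))
        specs.append(ConditionSpec(key=key, eye=eye, blur=blur, observer=observer))
    return specs


def cohort_to_frame(specs: list[ConditionSpec]):
    """Cohort as a table (one row per condition) for delimited-text export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "condition": [s.key for s in specs],
            "eye": [s.eye for s in specs],
            "blur": [s.blur for s in specs],
            "trueThreshold": [s.observer.threshold for s in specs],
            "slopeSpread": [s.observer.slope_spread for s in specs],
            "guessRate": [s.observer.guess_rate for s in specs],
            "lapseRate": [s.observer.lapse_rate for s in specs],
        }
    )
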