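"""Run-length behavior of the test-retest LoA: sqrt-n model, kink, efficiency.

If every trial past the initial descent contributed equal, independent
information, the LoA would shrink with the effective trial count as

    LoA(n) ~ 1 / sqrt(n - trialOffset)

where ``trialOffset`` (default 3) discounts the nearly-always-correct
descent trials that train the observer without informing the threshold.
The model is anchored so the prediction coincides with the observed LoA
at n = 6; its only free parameters are the offset and that scaling.

Two descriptive diagnostics accompany the model: a two-segment
("kink") fit that locates a change in slope of the LoA-vs-n curve, and
the precision-times-time product LoA(n) * n, whose extremum identifies a
pragmatic stopping length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import AgreementResult, agreement_summary
from .study import RunPair, checkpoint_lengths

__all__ = [
    "LoACurve",
    "RunLengthModel",
    "OffsetFit",
    "EfficiencyTable",
    "KinkFit",
    "loa_curve",
    "sqrt_n_prediction",
    "fit_trial_offset",
    "efficiency_product",
    "detect_slope_change",
    "loglog_slope",
]


@dataclass(frozen=True)
class LoACurve:
    """Mean LoA (and full agreement results) per checkpoint run length."""

    results: dict[int, AgreementResult]

    def __post_init__(self) -> None:
        if not self.results:
            raise ValueError("curve must contain at least one run length")

    @property
    def lengths(self) -> list[int]:
        return sorted(self.results)

    def mean_loa(self, n: int) -> float:
        return self.results[n].mean_loa

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.lengths:
            r = self.results[n]
            rows.append(
                {
                    "runLength": n,
                    "nPairs": r.n_pairs,
                    "bias": r.bias,
                    "sdDiff": r.sd_diff,
                    "loaLower": r.loa_lower,
                    "loaUpper": r.loa_upper,
                    "meanLoA": r.mean_loa,
                    "empiricalLoA": r.empirical_loa,
                    "biasCiLo": r.bias_ci[0],
                    "biasCiHi": r.bias_ci[1],
                    "bootLo": r.bootstrap_ci[0] if r.bootstrap_ci else np.nan,
                    "bootHi": r.bootstrap_ci[1] if r.bootstrap_ci else np.nan,
                }
            )
        return pd.DataFrame(rows)


def loa_curve(
    pairs: list[RunPair],
    run_lengths: list[int] | None = None,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> LoACurve:
    """Agreement summaries at every checkpoint length (default: 6, 12, ..., 48)."""
    if run_lengths is None:
        run_lengths = checkpoint_lengths(len(pairs[0].test.trials))
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    children = ss.spawn(len(run_lengths))
    results = {
        n: agreement_summary(pairs, n, n_reps=n_reps, seed=np.random.default_rng(child))
        for n, child in zip(run_lengths, children)
    }
    return LoACurve(results)


@dataclass(frozen=True)
class RunLengthModel:
    """sqrt(n - offset) predictions anchored at the observed LoA at n = 6."""

    trial_offset: int
    anchor_length: int
    anchor_loa: float
    predictions: dict[int, float]

    def __post_init__(self) -> None:
        if not self.trial_offset < self.anchor_length:
            raise ValueError("trial_offset must be < anchor_length")


def sqrt_n_prediction(curve: LoACurve, trial_offset: int = 3) -> RunLengthModel:
    """Model LoA(n) = LoA_obs(6) * sqrt((6 - offset) / (n - offset)).

    The prediction at the anchor length equals the observed value exactly,
    and predictions are strictly decreasing in n.
    """
    anchor_length = 6
    if anchor_length not in curve.results:
        raise ValueError("curve must contain the anchor length n=6")
    if trial_offset >= anchor_length:
        raise ValueError(f"trial_offset must be < {anchor_length}, got {trial_offset}")
    anchor = curve.mean_loa(anchor_length)
    predictions = {
        n: anchor * np.sqrt((anchor_length - trial_offset) / (n - trial_offset))
        for n in curve.lengths
    }
    return RunLengthModel(
        trial_offset=trial_offset,
        anchor_length=anchor_length,
        anchor_loa=anchor,
        predictions=predictions,
    )


@dataclass(frozen=True)
class OffsetFit:
    """Best integer trial offset and the per-candidate squared errors."""

    trial_offset: int
    sse: float
    candidate_sse: dict[int, float]


def fit_trial_offset(curve: LoACurve, candidates=range(0, 6)) -> OffsetFit:
    """Exhaustive least-squares choice of the integer trial offset.

    n = 6 is the anchor (the prediction there is exact by construction)
    and is excluded from the error; the offset minimizing the summed
    squared deviation over all longer checkpoints wins.
    """
    if len(curve.lengths) < 3 or 6 not in curve.results:
        raise ValueError("curve needs >= 3 points including n=6")
    errors: dict[int, float] = {}
    for offset in candidates:
        model = sqrt_n_prediction(curve, trial_offset=offset)
        sse = sum(
            (curve.mean_loa(n) - model.predictions[n]) ** 2
            for n in curve.lengths
            if n > model.anchor_length
        )
        errors[int(offset)] = float(sse)
    best = min(errors, key=lambda k: (errors[k], k))
    return OffsetFit(trial_offset=best, sse=errors[best], candidate_sse=errors)


@dataclass(frozen=True)
class EfficiencyTable:
    """LoA(n) * n per checkpoint and the extremal run lengths.

    Smaller LoA and fewer trials are both desirable, so the natural
    optimum of the product is its minimum; the maximum is reported
    alongside for completeness.
    """

    table: pd.DataFrame  # columns runLength, meanLoA, product
    argmin: int
    argmax: int


def efficiency_product(curve: LoACurve) -> EfficiencyTable:
    """Precision-times-time product LoA(n) * n over the checkpoints."""
    lengths = curve.lengths
    products = {n: curve.mean_loa(n) * n for n in lengths}
    table = pd.DataFrame(
        {
            "runLength": lengths,
            "meanLoA": [curve.mean_loa(n) for n in lengths],
            "product": [products[n] for n in lengths],
        }
    )
    argmin = min(lengths, key=lambda n: (products[n], n))
    argmax = max(lengths, key=lambda n: (products[n], -n))
    return EfficiencyTable(table=table, argmin=argmin, argmax=argmax)


@dataclass(frozen=True)
class KinkFit:
    """Two-segment (hinge) least-squares fit of meanLoA vs run length."""

    breakpoint: int
    slope_before: float
    slope_after: float
    sse: float
    candidate_sse: dict[int, float]
    degenerate: bool  # True when the two slopes are indistinguishable


def detect_slope_change(curve: LoACurve, slope_tol: float = 1e-8) -> KinkFit:
    """Locate a change in slope of the LoA-vs-n curve.

    Fits a continuous piecewise-linear function with a single knot at each
    candidate interior checkpoint (basis 1, n, max(0, n - b)) and returns
    the knot minimizing the total squared error, with the slopes of both
    segments.  Pure-linear input yields a degenerate fit (slopes equal
    within ``slope_tol``), which is flagged rather than interpreted.
    """
    lengths = curve.lengths
    if len(lengths) < 5:
        raise ValueError("need >= 5 points for a two-segment fit")
    x = np.asarray(lengths, dtype=float)
    y = np.asarray([curve.mean_loa(n) for n in lengths])
    best: tuple[float, int, float, float] | None = None
    candidate_sse: dict[int, float] = {}
    # interior knots: at least two points on each side of the hinge
    for b in lengths[1:-1]:
        design = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - b)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sse = float(resid @ resid)
        candidate_sse[b] = sse
        if best is None or sse < best[0] - 1e-15:
            best = (sse, b, float(coef[1]), float(coef[1] + coef[2]))
    sse, breakpoint, s1, s2 = best
    return KinkFit(
        breakpoint=breakpoint,
        slope_before=s1,
        slope_after=s2,
        sse=sse,
        candidate_sse=candidate_sse,
        degenerate=abs(s2 - s1) <= slope_tol * max(1.0, abs(s1)),
    )


def loglog_slope(curve: LoACurve, trial_offset: int = 3, min_length: int = 12) -> float:
    """Regression slope of ln(meanLoA) on ln(n - offset) over n >= min_length.

    A value near -0.5 indicates the square-root-of-n law.
    """
    ns = [n for n in curve.lengths if n >= min_length]
    if len(ns) < 2:
        raise ValueError("need >= 2 points for the log-log slope")
    lx = np.log(np.asarray(ns, dtype=float) - trial_offset)
    ly = np.log([curve.mean_loa(n) for n in ns])
    slope = np.polyfit(lx, ly, 1)[0]
    return float(slope)
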