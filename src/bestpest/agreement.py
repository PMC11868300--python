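"""Test-retest agreement: bias, Bland-Altman limits of agreement, bootstrap CIs.

Conventions used throughout (documented in every output header):

* difference = retest - test (run 2 minus run 1); a positive bias means
  the second run gave the numerically higher, i.e. *worse*, LogMAR.
* 95% Limits of Agreement: bias +/- 1.96 * SD of the differences (sample
  SD, n-1 denominator).  Because the bias here is tiny, the single summary
  figure is the *mean LoA*, the half-width 0.5 * (LoA_upper - LoA_lower)
  = 1.96 * SD, which holds as an exact identity.
* the empirical (non-parametric) LoA is the quantile half-width
  0.5 * (q_0.975 - q_0.025) with linear interpolation between order
  statistics — quantile conventions matter at n = 78, so the rule is fixed
  explicitly.
* bootstrap CIs resample whole pairs with replacement (equal size,
  10,000 replicates by default) and take the empirical 2.5% / 97.5%
  quantiles of the recomputed statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .study import RunPair

__all__ = [
    "AgreementResult",
    "AcuityGroupTable",
    "pair_differences",
    "bland_altman_loa",
    "empirical_loa",
    "bootstrap_mean_loa_ci",
    "bootstrap_loa_ci",
    "bias_t_test",
    "group_loa_by_acuity",
    "agreement_summary",
]

LOA_MULTIPLIER = 1.96  # 95% limits per Bland & Altman, not the rounded 2.0


@dataclass(frozen=True)
class AgreementResult:
    """Agreement summary for one set of test-retest differences (LogMAR)."""

    n_pairs: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    mean_loa: float
    bias_ci: tuple[float, float]
    empirical_loa: float | None = None
    bootstrap_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValueError("LoA bounds must bracket the bias")
        if self.mean_loa < 0:
            raise ValueError("mean_loa must be non-negative")


def pair_differences(pairs: list[RunPair], n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (mean, difference) of the two outcomes at run length ``n``.

    difference = retest - test; mean = (test + retest) / 2.

    Raises
    ------
    KeyError
        Naming the pair, if a run lacks the requested checkpoint.
    """
    means, diffs = [], []
    for pair in pairs:
        for run in (pair.test, pair.retest):
            if n not in run.checkpoint_outcomes:
                raise KeyError(
                    f"pair {pair.condition_key}: no checkpoint outcome at n={n}"
                )
        test = pair.test.checkpoint_outcomes[n]
        retest = pair.retest.checkpoint_outcomes[n]
        means.append(0.5 * (test + retest))
        diffs.append(retest - test)
    return np.asarray(means), np.asarray(diffs)


def bland_altman_loa(differences: np.ndarray) -> AgreementResult:
    """Bias, SD, 95% LoA bounds, mean LoA and t-based bias CI.

    Requires at least 3 differences (the SD and t-interval need df >= 2).
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError(f"need >= 3 differences, got {d.size}")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = LOA_MULTIPLIER * sd
    tcrit = stats.t.ppf(0.975, df=d.size - 1)
    sem = sd / np.sqrt(d.size)
    return AgreementResult(
        n_pairs=int(d.size),
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - half,
        loa_upper=bias + half,
        mean_loa=half,
        bias_ci=(bias - tcrit * sem, bias + tcrit * sem),
    )


def empirical_loa(differences: np.ndarray) -> float:
    """Non-parametric LoA half-width: 0.5 * (q_0.975 - q_0.025).

    Quantiles use linear interpolation between order statistics.  Warns
    below 40 differences, where extreme quantiles are poorly determined.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("differences must be non-empty")
    if d.size < 40:
        warnings.warn(
            f"empirical LoA from only {d.size} differences; extreme quantiles unstable",
            stacklevel=2,
        )
    lo, hi = np.quantile(d, [0.025, 0.975], method="linear")
    return float(0.5 * (hi - lo))


def bootstrap_mean_loa_ci(
    differences: np.ndarray,
    n_reps: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean LoA of a difference sample.

    Equal-size resamples with replacement; 2.5%/97.5% empirical quantiles
    of the 1.96*SD values.  Deterministic under a seeded rng.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("differences must be non-empty")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    idx = gen.integers(0, d.size, size=(n_reps, d.size))
    sds = d[idx].std(axis=1, ddof=1)
    lo, hi = np.quantile(LOA_MULTIPLIER * sds, [0.025, 0.975], method="linear")
    return float(lo), float(hi)


def bootstrap_loa_ci(
    pairs: list[RunPair],
    n: int,
    n_reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bootstrap CI for the mean LoA at run length ``n``, resampling pairs."""
    _, diffs = pair_differences(pairs, n)
    return bootstrap_mean_loa_ci(diffs, n_reps=n_reps, rng=seed)


def bias_t_test(differences: np.ndarray) -> tuple[float, float]:
    """One-sample two-sided t-test of the mean difference against zero.

    Raises
    ------
    ValueError
        If the differences have zero variance (p undefined).
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError(f"need >= 3 differences, got {d.size}")
    if np.all(d == d[0]):
        raise ValueError("zero variance in differences: t statistic undefined")
    res = stats.ttest_1samp(d, popmean=0.0)
    return float(res.statistic), float(res.pvalue)


def agreement_summary(
    pairs: list[RunPair],
    n: int,
    n_reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> AgreementResult:
    """Full agreement summary at one run length: LoA + empirical LoA + bootstrap CI."""
    _, diffs = pair_differences(pairs, n)
    base = bland_altman_loa(diffs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emp = empirical_loa(diffs)
    ci = bootstrap_mean_loa_ci(diffs, n_reps=n_reps, rng=seed)
    return AgreementResult(
        n_pairs=base.n_pairs,
        bias=base.bias,
        sd_diff=base.sd_diff,
        loa_lower=base.loa_lower,
        loa_upper=base.loa_upper,
        mean_loa=base.mean_loa,
        bias_ci=base.bias_ci,
        empirical_loa=emp,
        bootstrap_ci=ci,
    )


@dataclass(frozen=True)
class GroupRow:
    """One acuity bin at one run length."""

    run_length: int
    bin_lower: float
    bin_center: float
    n_pairs: int
    result: AgreementResult | None  # None when the bin is too sparse
    flagged: bool  # True when < 3 pairs fell in the bin


@dataclass(frozen=True)
class AcuityGroupTable:
    """Acuity-binned LoA: rows of (run length, bin, AgreementResult)."""

    bin_width: float
    rows: tuple[GroupRow, ...]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec = {
                "runLength": r.run_length,
                "binLower": r.bin_lower,
                "binCenter": r.bin_center,
                "nPairs": r.n_pairs,
                "flagged": int(r.flagged),
            }
            if r.result is not None:
                rec.update(
                    bias=r.result.bias,
                    meanLoA=r.result.mean_loa,
                    loaLower=r.result.loa_lower,
                    loaUpper=r.result.loa_upper,
                    bootLo=r.result.bootstrap_ci[0] if r.result.bootstrap_ci else np.nan,
                    bootHi=r.result.bootstrap_ci[1] if r.result.bootstrap_ci else np.nan,
                )
            records.append(rec)
        return pd.DataFrame(records)


def group_loa_by_acuity(
    pairs: list[RunPair],
    run_lengths: tuple[int, ...] = (18, 48),
    bin_width: float = 0.3,
    anchor: float = 0.0,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> AcuityGroupTable:
    """LoA per acuity bin for the given run lengths.

    Each pair is assigned to a bin by its test-retest mean outcome; bin
    edges are anchored at integer multiples of ``bin_width`` from
    ``anchor``.  Bins with fewer than 3 pairs are flagged and carry no
    LoA.  Every input pair lands in exactly one bin per run length.
    """
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    rows: list[GroupRow] = []
    for n in run_lengths:
        means, diffs = pair_differences(pairs, n)
        bin_idx = np.floor((means - anchor) / bin_width).astype(int)
        rng = np.random.default_rng(ss.spawn(1)[0])
        for b in sorted(set(bin_idx)):
            mask = bin_idx == b
            count = int(mask.sum())
            lower = anchor + b * bin_width
            center = lower + 0.5 * bin_width
            if count < 3:
                rows.append(GroupRow(n, lower, center, count, None, True))
                continue
            d = diffs[mask]
            base = bland_altman_loa(d)
            ci = bootstrap_mean_loa_ci(d, n_reps=n_reps, rng=rng)
            result = AgreementResult(
                n_pairs=base.n_pairs,
                bias=base.bias,
                sd_diff=base.sd_diff,
                loa_lower=base.loa_lower,
                loa_upper=base.loa_upper,
                mean_loa=base.mean_loa,
                bias_ci=base.bias_ci,
                bootstrap_ci=ci,
            )
            rows.append(GroupRow(n, lower, center, count, result, False))
    return AcuityGroupTable(bin_width=bin_width, rows=tuple(rows))
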