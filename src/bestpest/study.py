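"""Test-retest study execution, checkpoint outcomes, and trial-log I/O.

A study runs every cohort condition twice (test and retest) with
independent random streams split off one master seed.  Because each run
is recorded at full length (48 trials by default), the outcome for any
intermediate run length n is obtained by *recoding*: the acuity grade the
procedure would present at trial n+1 (a non-easy placement) is taken as
the outcome of a hypothetical n-trial run.  Checkpoints are the multiples
of 6 up to the run length.

Trial logs are plain delimited text, one row per presented optotype, with
a schema-version comment line; a column-mapping configuration lets the
loader ingest externally produced exports with different headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observers import ConditionSpec
from .procedure import ProcedureSettings, Run, TrialRecord, _base_level, run_procedure

__all__ = [
    "RunPair",
    "checkpoint_lengths",
    "checkpoint_outcome",
    "attach_checkpoints",
    "run_study",
    "export_trials",
    "load_trials",
    "TrialLogError",
]

logger = logging.getLogger(__name__)

SCHEMA_HEADER = "# bestpest trial log v1; difference convention: retest - test"

#: canonical trial-log columns
TRIAL_COLUMNS = [
    "condition",
    "eye",
    "blur",
    "runIndex",
    "trialIndex",
    "presentedLogMAR",
    "correct",
    "isEasy",
]


class TrialLogError(ValueError):
    """A trial-log table failed validation; message names the offending rows."""


@dataclass(frozen=True)
class RunPair:
    """Matched test/retest runs of one condition.

    ``true_threshold`` is only available for simulated cohorts; it is
    ``None`` for ingested real data.
    """

    condition_key: str
    eye: str
    blur: str
    test: Run
    retest: Run
    true_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.test.run_index != 1 or self.retest.run_index != 2:
            raise ValueError("test must have run_index 1 and retest run_index 2")
        if self.test.condition_key != self.retest.condition_key:
            raise ValueError("test and retest must share a condition key")


def checkpoint_lengths(run_length: int, step: int = 6) -> list[int]:
    """Intermediate run lengths at which outcomes are recoded: step, 2*step, ..."""
    return list(range(step, run_length + 1, step))


def checkpoint_outcome(run: Run, n: int, settings: ProcedureSettings | None = None) -> float:
    """Acuity outcome of the first ``n`` trials of a (longer) recorded run.

    Defined as the non-easy level the procedure would present at trial
    n+1 given trials 1..n: the descending level while the initial halving
    phase is still active, the ML estimate afterwards.  Easy-trial
    enlargement never enters an outcome.  At ``n = run length`` this is the
    run's final outcome.
    """
    if not 1 <= n <= len(run.trials):
        raise ValueError(f"checkpoint n={n} out of range for run of length {len(run.trials)}")
    if settings is None:
        settings = ProcedureSettings(run_length=len(run.trials))
    return _base_level(run.trials[:n], settings)


def attach_checkpoints(run: Run, settings: ProcedureSettings, step: int = 6) -> Run:
    """Return the run with its checkpoint_outcomes mapping populated."""
    outcomes = {
        n: checkpoint_outcome(run, n, settings)
        for n in checkpoint_lengths(len(run.trials), step)
    }
    return Run(
        condition_key=run.condition_key,
        run_index=run.run_index,
        trials=run.trials,
        checkpoint_outcomes=outcomes,
    )


def run_study(
    cohort: list[ConditionSpec],
    settings: ProcedureSettings,
    seed: int | np.random.SeedSequence,
) -> list[RunPair]:
    """Run every condition twice with independent streams; returns one pair each.

    A single master seed determines every response in every run: per-run
    generators are spawned from one SeedSequence, so test and retest are
    statistically independent yet the whole study is bit-reproducible.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(2 * len(cohort))
    pairs = []
    for i, spec in enumerate(cohort):
        runs = []
        for run_index in (1, 2):
            rng = np.random.default_rng(children[2 * i + run_index - 1])
            run = run_procedure(
                spec.observer, settings, rng, condition_key=spec.key, run_index=run_index
            )
            runs.append(attach_checkpoints(run, settings))
        pairs.append(
            RunPair(
                condition_key=spec.key,
                eye=spec.eye,
                blur=spec.blur,
                test=runs[0],
                retest=runs[1],
                true_threshold=spec.observer.threshold,
            )
        )
    logger.info("study complete: %d conditions, %d runs", len(pairs), 2 * len(pairs))
    return pairs


def trials_to_frame(pairs: list[RunPair]) -> pd.DataFrame:
    """Flatten pairs into the canonical one-row-per-trial table."""
    rows = []
    for pair in pairs:
        for run in (pair.test, pair.retest):
            for t in run.trials:
                rows.append(
                    (
                        pair.condition_key,
                        pair.eye,
                        pair.blur,
                        run.run_index,
                        t.trial_index,
                        t.presented,
                        int(t.correct),
                        int(t.is_easy),
                        pair.true_threshold,
                    )
                )
    frame = pd.DataFrame(rows, columns=TRIAL_COLUMNS + ["trueThreshold"])
    if frame["trueThreshold"].isna().all():
        frame = frame.drop(columns=["trueThreshold"])
    return frame


def export_trials(pairs: list[RunPair], path, delimiter: str = ",", decimal: str = ".") -> None:
    """Write the trial log as delimited text with a schema header line."""
    frame = trials_to_frame(pairs)
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        frame.to_csv(fh, sep=delimiter, decimal=decimal, index=False)
    logger.info("exported %d trial rows to %s", len(frame), path)


def _validate_trial_table(frame: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialLogError(f"missing required columns: {missing}")
    bad_codes = ~frame["correct"].isin([0, 1, True, False])
    if bad_codes.any():
        rows = frame.index[bad_codes].tolist()[:5]
        raise TrialLogError(f"unknown correctness codes at rows {rows}")
    dupes = frame.duplicated(subset=["condition", "runIndex", "trialIndex"], keep=False)
    if dupes.any():
        keys = (
            frame.loc[dupes, ["condition", "runIndex", "trialIndex"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()[:5]
        )
        raise TrialLogError(f"duplicated (condition, runIndex, trialIndex) rows: {keys}")
    for (cond, run_index), grp in frame.groupby(["condition", "runIndex"], sort=False):
        idx = grp["trialIndex"].to_numpy()
        expected = np.arange(1, len(idx) + 1)
        if not np.array_equal(np.sort(idx), expected):
            raise TrialLogError(
                f"run ({cond}, {run_index}): trialIndex must be 1..n without gaps, got {sorted(idx)[:10]}"
            )


def load_trials(
    path,
    settings: ProcedureSettings | None = None,
    column_map: dict[str, str] | None = None,
    delimiter: str = ",",
    decimal: str = ".",
) -> list[RunPair]:
    """Load a trial-log table back into RunPairs (inverse of export_trials).

    ``column_map`` maps canonical column names to the file's actual headers
    so externally produced exports can be ingested.  Per-trial ML estimates
    and checkpoint outcomes are recomputed from the presented levels and
    responses under ``settings`` (defaults to the standard procedure),
    which reproduces exported values exactly.
    """
    frame = pd.read_csv(
        path, sep=delimiter, decimal=decimal, comment="#", float_precision="round_trip"
    )
    if column_map:
        rename = {src: canonical for canonical, src in column_map.items()}
        frame = frame.rename(columns=rename)
    _validate_trial_table(frame)
    has_truth = "trueThreshold" in frame.columns

    pairs = []
    for cond, cond_grp in frame.groupby("condition", sort=False):
        run_indices = sorted(cond_grp["runIndex"].unique())
        if run_indices != [1, 2]:
            raise TrialLogError(f"condition {cond}: expected runIndex 1 and 2, got {run_indices}")
        run_length = int(cond_grp.groupby("runIndex")["trialIndex"].size().iloc[0])
        eff_settings = settings or ProcedureSettings(run_length=run_length)
        runs = {}
        for run_index, grp in cond_grp.groupby("runIndex", sort=True):
            grp = grp.sort_values("trialIndex")
            runs[run_index] = _rebuild_run(cond, int(run_index), grp, eff_settings)
        eye = str(cond_grp["eye"].iloc[0])
        blur = str(cond_grp["blur"].iloc[0])
        truth = float(cond_grp["trueThreshold"].iloc[0]) if has_truth else None
        pairs.append(
            RunPair(
                condition_key=str(cond),
                eye=eye,
                blur=blur,
                test=runs[1],
                retest=runs[2],
                true_threshold=truth,
            )
        )
    logger.info("loaded %d trial rows (%d pairs) from %s", len(frame), len(pairs), path)
    return pairs


def _rebuild_run(cond: str, run_index: int, grp: pd.DataFrame, settings: ProcedureSettings) -> Run:
    from scipy.special import expit, log_expit

    grid = settings.grid()
    gamma = settings.guess_rate
    loglik = np.zeros_like(grid)
    trials: list[TrialRecord] = []
    records = zip(
        grp["trialIndex"].to_numpy(),
        grp["presentedLogMAR"].to_numpy(dtype=float),
        grp["correct"].to_numpy(),
        grp["isEasy"].to_numpy(),
    )
    for trial_index, level, correct, easy in records:
        z = (level - grid) / settings.assumed_slope
        if correct:
            loglik += np.log(gamma + (1.0 - gamma) * expit(z))
        else:
            loglik += np.log(1.0 - gamma) + log_expit(-z)
        trials.append(
            TrialRecord(
                trial_index=int(trial_index),
                presented=float(level),
                correct=bool(correct),
                is_easy=bool(easy),
                estimate_after=float(grid[int(np.argmax(loglik))]),
            )
        )
    run = Run(condition_key=cond, run_index=run_index, trials=tuple(trials))
    return attach_checkpoints(run, settings)
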