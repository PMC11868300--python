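"""Simulate the test-retest study: 78 conditions x 2 adaptive 48-trial runs.

Writes the cohort table to results/ and the full trial log (one row per
presented optotype; ~7,500 rows) to scratch/, from which the later stages
can re-ingest the study.
"""

import argparse
from pathlib import Path

from bestpest import CohortConfig, ProcedureSettings, generate_cohort, run_study
from bestpest.observers import cohort_to_frame
from bestpest.study import export_trials

import numpy as np


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--pairs", type=int, default=78)
    args = parser.parse_args()

    cfg = CohortConfig(n_condition_pairs=args.pairs, seed=args.seed)
    cohort = generate_cohort(cfg)
    thresholds = [s.observer.threshold for s in cohort]
    print(
        f"cohort: {len(cohort)} conditions, true acuity "
        f"{min(thresholds):+.2f}..{max(thresholds):+.2f} LogMAR "
        f"(target range {cfg.acuity_range[0]:+.1f}..{cfg.acuity_range[1]:+.1f})"
    )

    settings = ProcedureSettings()
    study_seed = np.random.SeedSequence(args.seed).spawn(3)[0]
    pairs = run_study(cohort, settings, study_seed)

    Path("results").mkdir(exist_ok=True)
    Path("scratch").mkdir(exist_ok=True)
    cohort_to_frame(cohort).to_csv("results/cohort.csv", index=False)
    export_trials(pairs, "scratch/trial_log.csv")
    n_trials = sum(len(p.test.trials) + len(p.retest.trials) for p in pairs)
    print(f"wrote results/cohort.csv and scratch/trial_log.csv ({n_trials} trials)")


if __name__ == "__main__":
    main()
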