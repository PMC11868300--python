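"""Test-retest agreement at every checkpoint run length (6, 12, ..., 48 trials).

Ingests the trial log written by 01_simulate_study.py, computes bias and
the Bland-Altman mean LoA (with empirical LoA and 10,000-replicate
bootstrap CIs) per run length, and writes results/loa_vs_runlength.csv.
"""

import argparse
from pathlib import Path

from bestpest import ProcedureSettings, load_trials
from bestpest.agreement import bias_t_test, pair_differences
from bestpest.runlength import loa_curve


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--input", default="scratch/trial_log.csv")
    parser.add_argument("--bootstrap-reps", type=int, default=10_000)
    args = parser.parse_args()

    settings = ProcedureSettings()
    pairs = load_trials(args.input, settings=settings)
    curve = loa_curve(pairs, n_reps=args.bootstrap_reps, seed=args.seed)

    Path("results").mkdir(exist_ok=True)
    curve.to_frame().to_csv("results/loa_vs_runlength.csv", index=False)

    full = curve.lengths[-1]
    _, diffs = pair_differences(pairs, full)
    t, p = bias_t_test(diffs)
    r = curve.results[full]
    print(f"{len(pairs)} pairs; bias at n={full}: {r.bias:+.4f} LogMAR "
          f"(95% CI {r.bias_ci[0]:+.4f}..{r.bias_ci[1]:+.4f}; t-test p={p:.3f})")
    for n in curve.lengths:
        res = curve.results[n]
        print(f"  n={n:>2d}: mean LoA +/-{res.mean_loa:.3f} "
              f"[boot {res.bootstrap_ci[0]:.3f}..{res.bootstrap_ci[1]:.3f}], "
              f"empirical +/-{res.empirical_loa:.3f}")
    print("wrote results/loa_vs_runlength.csv")


if __name__ == "__main__":
    main()
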