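"""Fit the sqrt(n - trialOffset) model to the LoA curve; kink and efficiency.

Reads results/loa_vs_runlength.csv, fits the integer trial offset by
exhaustive least squares (anchored at n=6), locates a change in slope via
a two-segment fit, evaluates the precision-times-time product LoA*n, and
writes results/runlength_model.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from bestpest.agreement import AgreementResult
from bestpest.runlength import (
    LoACurve,
    detect_slope_change,
    efficiency_product,
    fit_trial_offset,
    loglog_slope,
    sqrt_n_prediction,
)


def curve_from_csv(path) -> LoACurve:
    frame = pd.read_csv(path, comment="#")
    results = {}
    for _, row in frame.iterrows():
        results[int(row["runLength"])] = AgreementResult(
            n_pairs=int(row["nPairs"]),
            bias=row["bias"],
            sd_diff=row["sdDiff"],
            loa_lower=row["loaLower"],
            loa_upper=row["loaUpper"],
            mean_loa=row["meanLoA"],
            bias_ci=(row["biasCiLo"], row["biasCiHi"]),
        )
    return LoACurve(results)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", default="results/loa_vs_runlength.csv")
    args = parser.parse_args()

    curve = curve_from_csv(args.input)
    fit = fit_trial_offset(curve)
    model = sqrt_n_prediction(curve, trial_offset=fit.trial_offset)
    kink = detect_slope_change(curve)
    eff = efficiency_product(curve)

    print(f"fitted trialOffset: {fit.trial_offset} "
          f"(candidate SSE: {dict(sorted(fit.candidate_sse.items()))})")
    print(f"log-log slope vs ln(n-3), n>=12: {loglog_slope(curve):.3f} "
          "(-0.5 would be the pure square-root law)")
    print(f"slope change at n={kink.breakpoint} "
          f"(slopes {kink.slope_before:.4f} -> {kink.slope_after:.4f}"
          f"{', degenerate' if kink.degenerate else ''})")
    print(f"efficiency product LoA*n: minimum at n={eff.argmin}, maximum at n={eff.argmax}")

    out = curve.to_frame()[["runLength", "meanLoA"]].assign(
        sqrtModel=[model.predictions[n] for n in curve.lengths],
        product=eff.table["product"],
    )
    Path("results").mkdir(exist_ok=True)
    out.to_csv("results/runlength_model.csv", index=False)
    print("wrote results/runlength_model.csv")


if __name__ == "__main__":
    main()
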