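"""End-to-end orchestration: simulate (or ingest) -> agreement -> run-length model.

Every random quantity in a pipeline execution traces back to the single
master seed: the cohort draw, each run's response stream and every
bootstrap all use generators spawned from one SeedSequence, so rerunning
with the same config and seed reproduces every output byte-for-byte.
Outputs are delimited text with a schema-version header line.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .agreement import AcuityGroupTable, group_loa_by_acuity
from .observers import CohortConfig, PsychometricModel, generate_cohort
from .procedure import ProcedureSettings
from .runlength import (
    EfficiencyTable,
    KinkFit,
    LoACurve,
    OffsetFit,
    detect_slope_change,
    efficiency_product,
    fit_trial_offset,
    loa_curve,
    sqrt_n_prediction,
)
from .study import RunPair, checkpoint_lengths, export_trials, load_trials, run_study

__all__ = ["PipelineConfig", "PipelineReport", "run_full_pipeline"]

logger = logging.getLogger(__name__)

SCHEMA_LINE = "# bestpest analysis table v1; differences are retest - test (LogMAR)"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full pipeline execution needs, minus the mode."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    procedure: ProcedureSettings = field(default_factory=ProcedureSettings)
    bootstrap_reps: int = 10_000
    bin_width: float = 0.3
    group_run_lengths: tuple[int, ...] = (18, 48)
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = dict(raw.get("cohort", {}))
        observer_raw = cohort_raw.pop("observer", None)
        if observer_raw is not None:
            cohort_raw["observer_defaults"] = PsychometricModel(**observer_raw)
        if "acuity_range" in cohort_raw:
            cohort_raw["acuity_range"] = tuple(cohort_raw["acuity_range"])
        for key in ("eye_conditions", "blur_levels"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        procedure_raw = dict(raw.get("procedure", {}))
        analysis = dict(raw.get("analysis", {}))
        if "group_run_lengths" in analysis:
            analysis["group_run_lengths"] = tuple(analysis["group_run_lengths"])
        return cls(
            cohort=CohortConfig(**cohort_raw),
            procedure=ProcedureSettings(**procedure_raw),
            out_dir=raw.get("out_dir", "results"),
            seed=int(raw.get("seed", 0)),
            **analysis,
        )

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PipelineReport:
    """In-memory bundle of everything a pipeline execution produced."""

    pairs: list[RunPair]
    curve: LoACurve
    groups: AcuityGroupTable
    offset_fit: OffsetFit
    efficiency: EfficiencyTable
    kink: KinkFit | None
    paths: dict[str, Path]


def _write_table(frame, path: Path, float_format: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(SCHEMA_LINE + "\n")
        frame.to_csv(fh, index=False, float_format=float_format)


def run_full_pipeline(
    config: PipelineConfig,
    mode: str = "simulate",
    input_path=None,
    column_map: dict[str, str] | None = None,
) -> PipelineReport:
    """Execute the whole study pipeline and write its report tables.

    ``mode='simulate'`` generates the cohort and runs the adaptive
    procedure; ``mode='ingest'`` loads an existing trial log instead
    (requiring ``input_path``).  Both then run the identical analysis:
    per-run-length agreement with bootstrap CIs, acuity-binned LoA, the
    sqrt(n - offset) model with fitted offset, kink detection and the
    efficiency product.
    """
    if mode not in ("simulate", "ingest"):
        raise ValueError(f"unknown mode {mode!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- stage 1: obtain run pairs -------------------------------------
    # seed layout: child 0 -> study responses, child 1 -> curve bootstraps,
    # child 2 -> group bootstraps (cohort draw uses the cohort's own seed).
    master = np.random.SeedSequence(config.seed)
    study_ss, curve_ss, group_ss = master.spawn(3)
    if mode == "simulate":
        cohort = generate_cohort(config.cohort)
        pairs = run_study(cohort, config.procedure, study_ss)
        paths["trial_log"] = out / "trial_log.csv"
        export_trials(pairs, paths["trial_log"])
    else:
        if input_path is None:
            raise ValueError("ingest mode requires input_path")
        pairs = load_trials(input_path, settings=config.procedure, column_map=column_map)
    logger.info("stage pairs: %d run pairs", len(pairs))

    # --- stage 2: agreement vs run length ------------------------------
    lengths = checkpoint_lengths(config.procedure.run_length)
    curve_seed = int(curve_ss.generate_state(1)[0] % (2**31))
    curve = loa_curve(pairs, lengths, n_reps=config.bootstrap_reps, seed=curve_seed)
    paths["loa_vs_runlength"] = out / "loa_vs_runlength.csv"
    _write_table(curve.to_frame(), paths["loa_vs_runlength"])
    logger.info("stage agreement: %d run lengths", len(lengths))

    # --- stage 3: acuity-binned LoA ------------------------------------
    group_seed = int(group_ss.generate_state(1)[0] % (2**31))
    group_lengths = tuple(n for n in config.group_run_lengths if n in curve.results)
    groups = group_loa_by_acuity(
        pairs,
        run_lengths=group_lengths,
        bin_width=config.bin_width,
        n_reps=config.bootstrap_reps,
        seed=group_seed,
    )
    paths["loa_by_acuity"] = out / "loa_by_acuity.csv"
    _write_table(groups.to_frame(), paths["loa_by_acuity"])
    logger.info("stage groups: %d bins", len(groups.rows))

    # --- stage 4: run-length model -------------------------------------
    offset_fit = fit_trial_offset(curve)
    model = sqrt_n_prediction(curve, trial_offset=offset_fit.trial_offset)
    efficiency = efficiency_product(curve)
    # a two-segment fit needs >= 5 checkpoints; shorter studies skip it
    kink = detect_slope_change(curve) if len(curve.lengths) >= 5 else None
    model_frame = curve.to_frame()[["runLength", "meanLoA"]].assign(
        sqrtModel=[model.predictions[n] for n in curve.lengths],
        product=efficiency.table["product"],
    )
    paths["runlength_model"] = out / "runlength_model.csv"
    _write_table(model_frame, paths["runlength_model"])

    paths["summary"] = out / "summary.txt"
    _write_summary(paths["summary"], config, mode, pairs, curve, offset_fit, efficiency, kink)
    logger.info("pipeline complete: outputs in %s", out)
    return PipelineReport(
        pairs=pairs,
        curve=curve,
        groups=groups,
        offset_fit=offset_fit,
        efficiency=efficiency,
        kink=kink,
        paths=paths,
    )


def _write_summary(path, config, mode, pairs, curve, offset_fit, efficiency, kink) -> None:
    full = curve.lengths[-1]
    r_full = curve.results[full]
    lines = [
        "bestpest pipeline summary v1",
        f"mode: {mode}; pairs: {len(pairs)}; run length: {config.procedure.run_length}; "
        f"bootstrap reps: {config.bootstrap_reps}; master seed: {config.seed}",
        "",
        "mean LoA (half-width of the 95% limits of agreement, LogMAR) by run length:",
    ]
    for n in curve.lengths:
        r = curve.results[n]
        lines.append(
            f"  n={n:>2d}: +/-{r.mean_loa:.3f}  (bootstrap 95% CI "
            f"{r.bootstrap_ci[0]:.3f}..{r.bootstrap_ci[1]:.3f}; empirical +/-{r.empirical_loa:.3f})"
        )
    lines += [
        "",
        f"bias at n={full} (retest - test): {r_full.bias:+.4f} LogMAR "
        f"(95% CI {r_full.bias_ci[0]:+.4f}..{r_full.bias_ci[1]:+.4f})",
        f"fitted trial offset: {offset_fit.trial_offset} (SSE {offset_fit.sse:.2e})",
        (
            f"slope-change breakpoint: {kink.breakpoint} trials "
            f"(slopes {kink.slope_before:.4f} -> {kink.slope_after:.4f}"
            f"{', degenerate' if kink.degenerate else ''})"
            if kink is not None
            else "slope-change breakpoint: not fitted (fewer than 5 checkpoints)"
        ),
        f"efficiency product LoA*n: minimum at n={efficiency.argmin}, "
        f"maximum at n={efficiency.argmax}",
        "",
    ]
    Path(path).write_text("\n".join(lines))
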