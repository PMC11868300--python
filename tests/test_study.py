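import numpy as np
import pandas as pd
import pytest

from bestpest import (
    CohortConfig,
    ProcedureSettings,
    checkpoint_outcome,
    export_trials,
    final_outcome,
    generate_cohort,
    load_trials,
    next_stimulus,
    run_study,
)
from bestpest.study import SCHEMA_HEADER, TrialLogError, trials_to_frame

from test_procedure import oracle_estimate


class TestCheckpoints:
    def test_keys_are_multiples_of_six(self, small_study):
        for pair in small_study:
            for run in (pair.test, pair.retest):
                assert sorted(run.checkpoint_outcomes) == [6, 12, 18, 24, 30, 36, 42, 48]

    def test_full_length_checkpoint_equals_final_outcome(self, small_study, default_settings):
        for pair in small_study:
            assert pair.test.checkpoint_outcomes[48] == final_outcome(pair.test, default_settings)

    def test_checkpoint_equals_level_presented_next(self, small_study, default_settings):
        # the recoding rule: outcome at n is the (non-easy) level of trial n+1
        for pair in small_study[:5]:
            run = pair.test
            for n in (6, 12, 18):
                level, easy = next_stimulus(list(run.trials[:n]), default_settings)
                expected = level - (default_settings.easy_offset if easy else 0.0)
                assert run.checkpoint_outcomes[n] == pytest.approx(expected)
                if n + 1 <= len(run.trials) and not run.trials[n].is_easy:
                    assert run.trials[n].presented == pytest.approx(
                        run.checkpoint_outcomes[n]
                    )

    def test_checkpoint_matches_likelihood_oracle(self, small_study, default_settings):
        run = small_study[0].test
        # past the descent phase the checkpoint is the ML estimate over trials 1..n
        assert any(not t.correct for t in run.trials[:12])
        assert run.checkpoint_outcomes[12] == pytest.approx(
            oracle_estimate(list(run.trials[:12]), default_settings), abs=1e-9
        )

    def test_outcomes_finite_and_within_grid(self, small_study, default_settings):
        for pair in small_study:
            for run in (pair.test, pair.retest):
                for v in run.checkpoint_outcomes.values():
                    assert np.isfinite(v)
                    assert default_settings.grid_min <= v <= default_settings.grid_max

    def test_out_of_range_checkpoint_rejected(self, small_study):
        with pytest.raises(ValueError):
            checkpoint_outcome(small_study[0].test, 49)
        with pytest.raises(ValueError):
            checkpoint_outcome(small_study[0].test, 0)


class TestRunStudy:
    def test_pair_and_run_cardinality(self, default_settings):
        cohort = generate_cohort(CohortConfig(n_condition_pairs=8, seed=5))
        pairs = run_study(cohort, default_settings, seed=5)
        assert len(pairs) == 8
        assert all(p.test.run_index == 1 and p.retest.run_index == 2 for p in pairs)

    def test_master_seed_reproduces_study_bit_for_bit(self, default_settings):
        cohort = generate_cohort(CohortConfig(n_condition_pairs=6, seed=5))
        s1 = run_study(cohort, default_settings, seed=42)
        s2 = run_study(cohort, default_settings, seed=42)
        assert s1 == s2

    def test_test_and_retest_streams_independent(self, small_study):
        # for a noisy observer the two runs essentially never coincide trial-for-trial
        differing = sum(
            any(a.correct != b.correct for a, b in zip(p.test.trials, p.retest.trials))
            for p in small_study
        )
        assert differing == len(small_study)

    def test_empty_cohort_rejected(self, default_settings):
        with pytest.raises(ValueError):
            run_study([], default_settings, seed=0)


class TestTrialLogRoundTrip:
    def test_export_load_identity(self, small_study, default_settings, tmp_path):
        path = tmp_path / "log.csv"
        export_trials(small_study, path)
        assert path.read_text().startswith(SCHEMA_HEADER)
        loaded = load_trials(path, settings=default_settings)
        assert loaded == small_study

    def test_ingest_with_column_mapping(self, small_study, default_settings, tmp_path):
        frame = trials_to_frame(small_study)
        renamed = frame.rename(
            columns={"presentedLogMAR": "acuity_grade", "correct": "resp_ok"}
        )
        path = tmp_path / "foreign.csv"
        renamed.to_csv(path, index=False)
        loaded = load_trials(
            path,
            settings=default_settings,
            column_map={"presentedLogMAR": "acuity_grade", "correct": "resp_ok"},
        )
        assert loaded == small_study

    def test_duplicate_row_rejected_with_row_named(self, small_study, tmp_path):
        frame = trials_to_frame(small_study)
        frame = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
        path = tmp_path / "dup.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(TrialLogError, match="duplicated"):
            load_trials(path)

    def test_missing_column_rejected(self, small_study, tmp_path):
        frame = trials_to_frame(small_study).drop(columns=["correct"])
        path = tmp_path / "missing.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(TrialLogError, match="correct"):
            load_trials(path)

    def test_gapped_trial_indices_rejected(self, small_study, tmp_path):
        frame = trials_to_frame(small_study)
        frame.loc[frame.index[2], "trialIndex"] = 99
        path = tmp_path / "gap.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(TrialLogError, match="trialIndex"):
            load_trials(path)

    def test_unknown_correctness_code_rejected(self, small_study, tmp_path):
        frame = trials_to_frame(small_study)
        frame["correct"] = frame["correct"].astype(object)
        frame.loc[frame.index[0], "correct"] = 7
        path = tmp_path / "badcode.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(TrialLogError, match="correctness"):
            load_trials(path)


class TestHandWrittenMinimalLog:
    def test_six_trial_pair_checkpoint_against_oracle(self, tmp_path):
        # one condition, two 6-trial runs written by hand; the second run has
        # its first error at trial 4, the first at trial 3
        rows = [
            # condition,eye,blur,runIndex,trialIndex,presentedLogMAR,correct,isEasy
            ("K1", "OU", "none", 1, 1, 1.0, 1, 0),
            ("K1", "OU", "none", 1, 2, 0.7, 1, 0),
            ("K1", "OU", "none", 1, 3, 0.4, 0, 0),
            ("K1", "OU", "none", 1, 4, 0.5, 1, 0),
            ("K1", "OU", "none", 1, 5, 0.45, 0, 0),
            ("K1", "OU", "none", 1, 6, 0.5, 1, 0),
            ("K1", "OU", "none", 2, 1, 1.0, 1, 0),
            ("K1", "OU", "none", 2, 2, 0.7, 1, 0),
            ("K1", "OU", "none", 2, 3, 0.4, 1, 0),
            ("K1", "OU", "none", 2, 4, 0.1, 0, 0),
            ("K1", "OU", "none", 2, 5, 0.3, 1, 0),
            ("K1", "OU", "none", 2, 6, 0.25, 1, 0),
        ]
        path = tmp_path / "mini.csv"
        path.write_text(
            "condition,eye,blur,runIndex,trialIndex,presentedLogMAR,correct,isEasy\n"
            + "\n".join(",".join(map(str, r)) for r in rows)
            + "\n"
        )
        settings = ProcedureSettings(run_length=6)
        pairs = load_trials(path, settings=settings)
        assert len(pairs) == 1
        pair = pairs[0]
        assert sorted(pair.test.checkpoint_outcomes) == [6]
        for run in (pair.test, pair.retest):
            assert run.checkpoint_outcomes[6] == pytest.approx(
                oracle_estimate(list(run.trials), settings), abs=1e-9
            )
        assert pair.true_threshold is None
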