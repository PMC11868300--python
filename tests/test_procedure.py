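import math

import numpy as np
import pytest

from bestpest import (
    ProcedureSettings,
    PsychometricModel,
    Run,
    TrialRecord,
    best_pest_estimate,
    final_outcome,
    next_stimulus,
    run_procedure,
)


def trial(i, level, correct, easy=False):
    return TrialRecord(trial_index=i, presented=level, correct=correct,
                       is_easy=easy, estimate_after=0.0)


def oracle_estimate(history, settings):
    """Independent exhaustive grid scan with the likelihood written out by hand.

    log(1 - p) is expanded analytically as log(1 - gamma) + log(1 - S(z))
    with log(1 - S(z)) = -z - log(1 + exp(-z)), so it stays finite where
    the sigmoid saturates.  Ties keep the smallest candidate.
    """
    gamma = settings.guess_rate
    sigma = settings.assumed_slope
    best_alpha, best_ll = None, -math.inf
    alpha = settings.grid_min
    while alpha <= settings.grid_max + 1e-12:
        ll = 0.0
        for t in history:
            z = (t.presented - alpha) / sigma
            if z >= 0:
                s = 1.0 / (1.0 + math.exp(-z))
                log_one_minus_s = -z - math.log1p(math.exp(-z))
            else:
                e = math.exp(z)
                s = e / (1.0 + e)
                log_one_minus_s = -math.log1p(e)
            if t.correct:
                ll += math.log(gamma + (1.0 - gamma) * s)
            else:
                ll += math.log(1.0 - gamma) + log_one_minus_s
        if ll > best_ll:
            best_alpha, best_ll = alpha, ll
        alpha = round(alpha + settings.grid_step, 10)
    return best_alpha


def random_history(rng, settings, max_len=8):
    n = rng.integers(1, max_len + 1)
    levels = rng.uniform(settings.grid_min, settings.grid_max, size=n)
    corrects = rng.random(n) < 0.6
    return [trial(i + 1, float(l), bool(c)) for i, (l, c) in enumerate(zip(levels, corrects))]


class TestBestPestEstimate:
    def test_single_candidate_grid(self):
        s = ProcedureSettings(grid_min=0.3, grid_max=0.3, grid_step=0.01, start_level=0.3)
        assert best_pest_estimate([trial(1, 1.0, True)], s) == 0.3

    def test_one_correct_one_incorrect_closed_form(self, default_settings):
        # argmax of p(1-p) sits where p = 0.5, i.e. alpha = x + sigma*ln(3/4)^-1-ish:
        # S = (0.5 - gamma)/(1 - gamma) = 3/7, alpha = x - sigma*ln(S/(1-S)) = x + 0.2877*sigma
        history = [trial(1, 0.0, True), trial(2, 0.0, False)]
        expected = 0.2877 * default_settings.assumed_slope
        est = best_pest_estimate(history, default_settings)
        assert est == pytest.approx(expected, abs=default_settings.grid_step)

    def test_matches_exhaustive_oracle_on_random_histories(self, default_settings):
        rng = np.random.default_rng(77)
        for _ in range(100):
            history = random_history(rng, default_settings)
            assert best_pest_estimate(history, default_settings) == pytest.approx(
                oracle_estimate(history, default_settings), abs=1e-9
            )

    def test_empty_history_rejected(self, default_settings):
        with pytest.raises(ValueError):
            best_pest_estimate([], default_settings)

    def test_non_finite_level_rejected(self, default_settings):
        with pytest.raises(ValueError):
            best_pest_estimate([trial(1, math.nan, True)], default_settings)


class TestNextStimulus:
    def test_first_trial_is_start_level(self, default_settings):
        assert next_stimulus([], default_settings) == (1.0, False)

    def test_descent_sequence(self, default_settings):
        history = [trial(1, 1.0, True), trial(2, 0.7, True), trial(3, 0.4, True)]
        level, easy = next_stimulus(history, default_settings)
        assert level == pytest.approx(0.1) and not easy

    def test_ml_placement_after_first_error(self, default_settings):
        history = [trial(1, 1.0, True), trial(2, 0.7, False)]
        level, easy = next_stimulus(history, default_settings)
        assert level == best_pest_estimate(history, default_settings)
        assert not easy

    def test_easy_trial_enlarged_threefold(self, default_settings):
        history = [trial(i + 1, 1.0 - 0.05 * i, i != 3) for i in range(11)]
        estimate = best_pest_estimate(history, default_settings)
        level, easy = next_stimulus(history, default_settings)  # upcoming index 12
        assert easy
        assert level == pytest.approx(estimate + math.log10(3))

    def test_descent_clipped_to_grid(self):
        s = ProcedureSettings(grid_min=-0.5, run_length=48)
        history = [trial(i + 1, 1.0 - 0.3 * i, True) for i in range(6)]
        level, _ = next_stimulus(history, s)
        assert level == -0.5

    def test_complete_run_rejected(self):
        s = ProcedureSettings(run_length=1)
        with pytest.raises(ValueError):
            next_stimulus([trial(1, 1.0, True)], s)


class TestRunProcedure:
    def test_run_has_exactly_run_length_trials(self, ideal_observer, default_settings):
        run = run_procedure(ideal_observer, default_settings, np.random.default_rng(0))
        assert len(run) == default_settings.run_length
        assert [t.trial_index for t in run.trials] == list(range(1, 49))

    def test_identical_seeds_identical_runs(self, ideal_observer, default_settings):
        r1 = run_procedure(ideal_observer, default_settings, np.random.default_rng(3))
        r2 = run_procedure(ideal_observer, default_settings, np.random.default_rng(3))
        assert r1 == r2

    def test_estimates_stay_on_grid(self, ideal_observer, default_settings):
        run = run_procedure(ideal_observer, default_settings, np.random.default_rng(8))
        grid = default_settings.grid()
        for t in run.trials:
            assert default_settings.grid_min <= t.estimate_after <= default_settings.grid_max
            assert np.isclose(grid, t.estimate_after).any()

    def test_easy_trials_follow_default_rule(self, ideal_observer, default_settings):
        run = run_procedure(ideal_observer, default_settings, np.random.default_rng(8))
        assert [t.trial_index for t in run.trials if t.is_easy] == [12, 18, 24, 30, 36, 42, 48]

    def test_deterministic_sharp_observer_converges(self, default_settings):
        # noiseless responder: correct iff the optotype is at least its threshold
        true_threshold = 0.23
        trials = []
        for i in range(1, default_settings.run_length + 1):
            level, easy = next_stimulus(trials, default_settings)
            trials.append(trial(i, level, level >= true_threshold, easy))
        run = Run("sharp", 1, tuple(trials))
        assert final_outcome(run, default_settings) == pytest.approx(true_threshold, abs=0.05)


class TestFinalOutcome:
    def test_equals_estimate_over_full_history(self, ideal_observer, default_settings):
        run = run_procedure(ideal_observer, default_settings, np.random.default_rng(5))
        assert final_outcome(run, default_settings) == best_pest_estimate(
            list(run.trials), default_settings
        )

    def test_easy_last_trial_does_not_inflate_outcome(self, ideal_observer, default_settings):
        run = run_procedure(ideal_observer, default_settings, np.random.default_rng(5))
        assert run.trials[-1].is_easy  # trial 48 is easy under the default rule
        outcome = final_outcome(run, default_settings)
        assert outcome < run.trials[-1].presented  # enlargement excluded
        assert outcome == run.trials[-1].estimate_after

    def test_empty_run_rejected(self):
        with pytest.raises(ValueError):
            final_outcome(Run("x", 1, ()))


class TestSettingsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(grid_step=0.0),
            dict(start_level=5.0),
            dict(easy_factor=1.0),
            dict(guess_rate=0.0),
            dict(assumed_slope=0.0),
            dict(run_length=0),
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ProcedureSettings(**kwargs)

    def test_explicit_easy_indices_override_rule(self):
        s = ProcedureSettings(easy_trial_indices=(5, 9))
        assert s.is_easy_trial(5) and s.is_easy_trial(9)
        assert not s.is_easy_trial(12)
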