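# Methods

## Observer model

Responses are Bernoulli draws from an n-alternative forced-choice
psychometric function

    P(correct | x) = gamma + (1 - gamma - lambda) * S((x - alpha) / sigma),

where `x` is the presented optotype size in LogMAR (larger = easier),
`alpha` the threshold (the inflection point of the inner sigmoid),
`sigma` the slope spread, `gamma` the guess rate and `lambda` the lapse
rate.  `S` is the logistic `S(z) = 1/(1 + e^-z)`: the functional form is
a modelling choice (probit or Weibull would serve equally), picked
because it is the conventional kernel for Best PEST and has closed forms
that the tests exploit.  Validity requires `gamma + lambda < 1`;
otherwise the function would decrease in `x`.  At `x = alpha` the
probability is exactly `gamma + (1 - gamma - lambda)/2`.

Defaults, with units and rationale:

| parameter | default | unit | why |
|---|---|---|---|
| `gamma` | 1/8 | probability | 8 Landolt-C gap orientations |
| `sigma` | 0.07 | LogMAR | gives psychometric widths typical of letter acuity; a free simulation parameter, configurable |
| `lambda` | 0.01 | probability | occasional attention slips produce the outlier-heavy difference distributions seen in real test-retest data; simulations can set 0 |
| `alpha` | per condition | LogMAR | drawn by the cohort generator |

## Cohort generator

A cohort is one observer per test-retest condition (participant x eye x
blur state).  The default emulates 78 condition pairs over a true-acuity
range of -0.6 to +1.2 LogMAR, two 48-trial runs per condition.  True
thresholds are drawn stratified-uniform over 0.3-LogMAR bins so every
acuity bin of the grouped analysis is populated (artificial blur in the
emulated study design exists precisely to cover a wide acuity range);
eye (OU/OD/OS) and blur labels are assigned cyclically and are carried
as metadata only — they do not alter the observer.  Generation is a pure
function of the config including its seed.

What the generator does *not* emulate: learning and fatigue across a
run, vigilance differences between test and retest, response-time
structure, optical details of blur, and any acuity dependence of `sigma`
or `lambda`.  Consequently, passing simulation tests demonstrates the
correctness of the procedure and statistics, not that human data will
show the same run-length curve; in particular a change of slope at a
specific run length (e.g. 18 trials) depends on human lapse/outlier
structure and is deliberately not asserted from simulation.

## Adaptive procedure

From 1.0 LogMAR the optotype shrinks by `initial_step` per trial until
the first error.  True halving is 0.30103 LogMAR; the step defaults to
exactly 0.3 so the canonical printed sequence 1.0, 0.7, 0.4, 0.1 is
reproduced bit-exactly (descent levels are rounded to 10 decimals to
remove float accumulation).  After the first error, each trial is placed
at the maximum-likelihood threshold: the candidate on a fixed grid
([-1.5, +2.0] LogMAR, step 0.01, covering clinically plausible acuity
with margin) maximizing

    sum_i [ c_i * ln p(x_i; a) + (1 - c_i) * ln(1 - p(x_i; a)) ],

where the estimator's model is lapse-free (`lambda = 0`, classic Best
PEST) with the true guess rate and, by default, the observer's slope; a
mismatched slope can be configured for robustness experiments.  The
lapse-free estimator facing a lapsing observer is intentional: it is one
source of outliers.  Ties in the likelihood are broken toward the
smallest candidate (best acuity); off the grid boundary ties have
measure zero.  The incorrect-response term is evaluated as
`ln(1 - gamma) + ln S(-z)` via `log_expit`, which stays finite where the
sigmoid saturates, so the likelihood is finite on the whole grid.

Easy trials: the run-length recoding design needs 48-trial runs, and an
18-trial illustration of the procedure shows enlarged trials at indices
12 and 18; the rule is extended as "every 6th trial starting at 12"
(12, 18, ..., 48), configurable via an explicit index set.  Easy trials
present the current estimate plus `log10(3)` (a 3x enlargement) and
enter the likelihood at their actual level — they are real forced-choice
trials.  Both the rule extension and their inclusion in the likelihood
are assumptions and are flagged as such.

## Checkpoint recoding

Runs are recorded at full length; the outcome for run length `n` is the
non-easy level the procedure would present at trial `n+1` given trials
1..n.  Past the descent phase this equals the ML estimate after `n`
trials, which extends the definition naturally to `n = 48` (where there
is no trial 49) and keeps easy-trial enlargement out of outcomes.  While
the descent is still active at trial `n` (possible at `n = 6` for very
poor acuity, where the ML estimate of an all-correct history would
degenerate to the grid minimum), the recoded outcome is the descending
level itself — exactly what an instrument exporting "the presented grade
of trial n+1" would record.

## Agreement statistics

* Differences are oriented retest - test (run 2 minus run 1); stated in
  every output header.
* Limits of agreement use the multiplier 1.96 (95% limits), not the
  rounded 2.0; SD uses the n-1 denominator.  The mean LoA
  `0.5*(LoA_upper - LoA_lower) = 1.96*SD` is the headline half-width.
* The empirical LoA is `0.5*(q_0.975 - q_0.025)` with linear
  interpolation between order statistics; the convention is fixed
  because quantile rules visibly change results at n = 78.  A warning is
  issued below 40 differences.
* Bootstrap CIs resample whole pairs with replacement (equal size),
  recompute the statistic 10,000 times and take the empirical 2.5%/97.5%
  quantiles.  Percentile intervals for an SD-based statistic are known
  to be slightly anticonservative at n = 78; the calibration test
  accepts coverage within five points of 95%.
* The bias CI is the standard t-interval; the bias test is a two-sided
  one-sample t-test (undefined, and signalled, for zero-variance input).
* Acuity grouping assigns each pair by its test-retest mean to
  0.3-LogMAR bins anchored at integer multiples of the width from 0
  (anchoring is configurable; the choice is arbitrary but must be fixed
  for bins to be comparable).  Bins with fewer than 3 pairs are flagged
  and excluded from LoA computation.

## Run-length model

`LoA(n) = LoA_obs(6) * sqrt((6 - trialOffset)/(n - trialOffset))`,
anchored so the n = 6 point is exact.  `trialOffset` (default 3)
discounts the descent trials, which are nearly always correct and carry
little threshold information.  The offset is fitted by exhaustive least
squares over the integers 0..5 on the checkpoints beyond the anchor —
the fitting rule is this package's choice, since "experimentation"
admits many readings.  Slope-change detection fits a continuous
two-segment (hinge) regression at every interior checkpoint knot and
keeps the knot with minimal squared error; no significance test is
attached, and pure-linear input is flagged degenerate rather than
interpreted.  The efficiency criterion multiplies LoA by the trial count
as a time proxy; since smaller LoA and fewer trials are both better, the
interior *minimum* of LoA*n is the natural optimum, and both extrema are
reported.

## Known limitations and observed behaviour

* Best PEST with a lapse-free internal model is vulnerable to early
  lapses: an error on the very first (easy) trial sends the ML estimate
  to the top of the grid, and because correct responses far above
  threshold are nearly uninformative the estimate walks back down only
  slowly, sometimes not reaching the true threshold within 48 trials.
  Such runs appear as extreme outliers in the difference distribution
  and can dominate the parametric (SD-based) LoA of a 78-pair study
  while barely moving the quantile-based empirical LoA — which is why
  both are always reported side by side.
* For an ideal observer (no lapses, matched slope) the simulated LoA
  curve falls *faster* than `1/sqrt(n - 3)` between 12 and 48 trials:
  the estimator has not reached its asymptotic information rate by 48
  trials, so its variance still decays super-linearly in effective
  trials.  The log-log slope the acceptance script reports quantifies
  this for the run at hand.  With the default lapsing cohort the curve
  flattens at long runs (lapse-driven outliers set a variance floor),
  moving the slope toward -0.5.
* Problem sizes: the default study is 78 pairs x 2 x 48 trials with
  10,000 bootstrap replicates; consistency checks in the test suite use
  500 runs / 500 pairs, sizes at which estimator bias below 0.01 LogMAR
  is resolvable.
* Real-data ingestion maps external column names through a configuration
  rather than a fixed parser; per-trial estimates are recomputed from
  the recorded levels and responses, which reproduces exported values
  exactly under the same settings.
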