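# Methods

## Data model and person-period expansion

The unit of analysis is a subject of a prospective high-risk cohort:
time-fixed covariates (sex at birth, parental lithium response, parental
onset age in years, childhood physical/sexual abuse as the three-level
factor yes/no/missing), first-onset ages for nine antecedent indicators
(subthreshold activation, depression, sleep, substance and anxiety
presentations; substance use, sleep, anxiety and neurodevelopmental
disorders), ages of antecedent major and minor mood episodes, and an
outcome age with an event flag (1 = diagnosis of major mood disorder,
0 = censored at the last follow-up visit). The time scale is age in
years, as a real number.

The age axis is partitioned into contiguous half-open intervals
`[b_k, b_{k+1})` of equal width (1, 3 or 5 years; any positive width is
accepted), anchored at the cohort's minimum enrolment age (default 5).
An age on a boundary belongs to the interval starting there. Expansion
emits one row per subject per at-risk interval:

* an **event** subject is at risk through the interval containing the
  event; `event_in_interval = 1` only in that last row;
* a **censored** subject is at risk only in intervals fully survived
  (`interval_end <= censoring age`); a partially observed final interval
  contributes no row. This is the standard discrete-survival treatment
  of within-interval censoring; the alternative (counting the partial
  interval as survived) is not implemented.

Time-varying covariates are **lagged by one interval**: the row for
interval `k` carries each indicator's status as of the end of interval
`k−1` (onset age strictly below `b_k`) and the cumulative episode counts
strictly below `b_k`. Onsets or episodes at or after the subject's
outcome age never contribute (antecedents only). The lag removes
reverse-causality by construction and makes every prediction a true
one-interval-ahead forecast; a perturbation test asserts that nothing at
or after a row's interval start can alter that row.

Abuse is encoded as two dummies (`abuse_yes`, `abuse_missing`) with
"no" as reference, keeping the explicitly tabulated missing category as
a level rather than dropping subjects. The interval midpoint age enters
as a `time_input` column; each model decides what to do with it.

## The two hazard models

Both estimate the discrete conditional hazard on person-period rows and
are trained on the same Bernoulli (cross-entropy) likelihood, so they
differ only in their functional form.

**Discrete-time logistic hazard (GLM).** One free intercept per age
interval (no smoothing across intervals) plus linear covariate effects
on the logit scale: proportional odds across intervals by construction.
`time_input` is excluded from its design because the interval dummies
span it exactly. Fitting is Newton–Raphson with step damping; a ridge
penalty (default 1e-6, on the standardized covariate coefficients, never
on the interval intercepts) guards against quasi-separation from rare
indicators. With a zero penalty, a parameter norm exceeding 20 at a
vanishing gradient is diagnosed as an MLE at infinity (separation, or an
interval whose rows are all events or all non-events) and raises a
convergence error advising a penalty rather than returning a drifting
estimate. Intervals with no at-risk rows get a NaN intercept flagged
inestimable; predicting such an interval errors unless NaN hazards are
explicitly allowed. Continuous covariates are standardized with
training-table statistics internally and coefficients reported on the
original scale.

**PLANN.** A feed-forward network with one hidden layer, sigmoid hidden
and output activations, whose scalar output is the hazard. Time enters
as an ordinary standardized input (`time_input`), which is what lets the
network express non-proportional hazards; there are no interval dummies.
Defaults: 8 hidden units, weight decay 0.01 on connection weights (not
biases) on the summed-likelihood scale — i.e. the objective is mean
cross-entropy plus `decay * ||W||^2 / n_rows`, the classical
penalized-deviance convention, so the default's strength is independent
of the table size. Training is full-batch quasi-Newton (L-BFGS with
analytic gradients, at most 500 iterations), with weights initialized
from a seeded normal draw of scale `0.5/sqrt(d+1)`; a 10% seeded
shuffle split provides early stopping (patience 25, best-on-validation
weights returned). Everything is deterministic given the seed. Large
decay provably collapses predictions to the marginal event rate, and
removing time variation freezes the hazard profile — both asserted in
tests. No inner hyperparameter search is performed by default; the
defaults were chosen once for desk-scale cohorts and a grid hook can be
layered on top by refitting with other `PlannHyperparams`.

Predicted survival for either model is
`S(k) = prod_{j<=k} (1 - h_j)` over the scheme's intervals.

## Evaluation battery

All metrics operate on a `PredictionSet`: per test subject, the
predicted hazard per scheme interval, the survival curve, and the
observed outcome. `S(t)` is evaluated as a step function that drops at
interval ends (survival through every interval ending at or before `t`).

* **Time-dependent c-index.** Over comparable pairs — `i` with an event
  at `t_i`, `j` observed beyond `t_i` — the fraction where
  `S_i(t_i) < S_j(t_i)`, ties at half credit. Undefined (error) without
  comparable pairs.
* **Brier score at an age.** Mean of `(S(t*) − event-free)^2`. The IPCW
  variant weights events before `t*` by `1/G(t_i−)` and survivors by
  `1/G(t*)`, with `G` the Kaplan–Meier estimate of the censoring
  distribution; subjects censored before `t*` carry zero weight and the
  average runs over all subjects (Graf's estimator). The unweighted
  variant averages over subjects of known status; with no censoring the
  two agree exactly. In cross-validation `G` is estimated on the
  training folds and applied to the test fold. Default ages 15, 20, 25;
  their arithmetic mean is the reported "mean Brier".
* **Interval AUC.** Incident/dynamic variant: among subjects at risk at
  the interval's start (those censored within it excluded), the rank-sum
  AUC of the predicted interval hazard against event-in-interval.
  Degenerate risk sets (no event or no non-event) are recorded as
  undefined and excluded from means, with exclusion counts reported —
  never imputed. The reported mean AUC averages per-interval values over
  folds first, then over intervals (SD across intervals alongside).
* **Confusion metrics.** Classify at-risk subjects by hazard ≥
  threshold over the grid {0.05, 0.10, 0.15, 0.20}; PPV with no
  predicted positives is reported as undefined, never 0. The "optimal"
  threshold maximizes Youden's J over observed hazards (ties to the
  smaller cut, midpoint to the next-lower observed value returned); it
  is computed per interval on test-fold predictions, which matches the
  per-interval reporting convention but is mildly optimistic, since the
  cut and the evaluation share data.
* **Cross-validation.** Event-stratified k-fold (default 10, seeded);
  per-fold event counts differ by at most one. Standardization
  constants, model weights and the censoring distribution are estimated
  on training folds only.
* **Descriptive tables.** Wald intervals, applied literally:
  `100(p ± 1.96 sqrt(p(1−p)/n))` for percentages (a clipped variant is
  behind a flag, since the literal formula can leave [0, 100]) and
  `m ± 1.96 sd/sqrt(n)` for means.

## Synthetic cohort generator

The generator emulates the study conditions: n = 292 subjects, ages 5 to
40 on annual at-risk intervals, last-visit (censoring) age uniform on
[5, 40]. Time-fixed marginals match the published descriptive table
(male 0.414, parental lithium response 0.442, abuse yes/missing
0.103/0.380 from one categorical draw, parental onset age normal with
mean 25.4; its SD 9.2 is recovered from the published CI of the mean,
draws clipped to [10, 60]). Indicator onsets follow per-indicator annual
hazards chosen once so that lifetime onset over a ~16-year mean at-risk
horizon matches the published prevalences (`h = 1 − (1−p)^{1/16}`);
episodes arrive as small Poisson streams (rate 0.012/year each) so
cumulative counts average ≈ 0.2 at outcome.

The outcome is drawn interval by interval from a logistic hazard using
the **same lag convention as the expansion**: at interval `k` the linear
predictor sees only onsets and episodes from intervals before `k`. The
default baseline is `logit h_k = −4.55 + 0.08 (age_k − 5)`, calibrated
once so the event fraction (≈ 0.38) and median event age (≈ 20) resemble
the study cohort; these are cosmetic targets, not test assertions. The
default covariate effects are invented, directionally consistent with
the published event-vs-full-sample contrasts. An `interactions` hook
(`"cov1*cov2"` keys) adds product terms to the true hazard for
nonlinear-truth experiments. Covariates are drawn independently — no
joint distribution is published, so all joint structure here is an
invention of the generator.

Event and onset ages are uniform within their interval; antecedents
drawn at or after the outcome are discarded. Every subject carries a
truth record (linear predictor, hazard, survival per at-risk interval)
that is exactly reproducible by re-applying the coefficients to the
expanded table — the round-trip is asserted in tests.

What the generator does **not** emulate: visit irregularity, diagnostic
misclassification, family clustering, covariate correlation, or
calendar effects. Passing recovery and calibration tests therefore shows
the estimators and metrics are correct under the stated generating
process, not that real cohorts satisfy that process.

## Problem sizes and numerical choices

Recovery and comparison experiments run at the sizes the checks
prescribe: GLM coefficient recovery at n = 5000 (a flat, denser-event
baseline, logit −3.0, keeps the coefficient standard errors near 0.04);
PLANN-vs-GLM comparisons at n = 3000 with a 2000/1000 split; null
calibration at n = 600 over three seeds, where 0.05 is roughly three
Monte-Carlo standard errors of the three-seed mean of either rank
statistic. The study-scale experiment in the acceptance script uses the
default n = 292 with tenfold CV over widths 1/3/5. Late intervals can be
absent from a training expansion (administrative censoring at 40 means
the last interval of a width that divides 35 contains only events);
model comparisons are then scored on rows whose interval both models can
predict, and undefined metric cells are excluded and counted.

Tolerances: Newton stops at gradient norm 1e-10; brute-force oracle
comparisons in the tests use 1e-10…1e-12 for closed-form quantities and
1e-6 against independent numeric optimizers.

## Known limitations

* The optimal-threshold search on test folds inherits the optimistic
  bias noted above.
* The GLM reports no standard errors or p-values; the package's aim is
  predictive comparison, not covariate inference.
* The c-index treats ties in observed times conservatively (pairs with
  equal observation times are not compared).
* With a zero ridge penalty the GLM refuses datasets whose MLE is at
  infinity rather than returning the limit of a drifting fit; use the
  default penalty for routine work.
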