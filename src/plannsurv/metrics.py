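"""Censoring-aware evaluation of discrete-time survival predictions.

Implements the assessment battery used to compare the hazard models:

* time-dependent concordance index (Antolini-style, over comparable
  pairs, half credit for ties);
* Brier score at fixed ages, unweighted or with inverse probability of
  censoring weighting (IPCW) from a Kaplan–Meier estimate of the
  censoring distribution;
* per-interval incident/dynamic AUC of the predicted hazard among the
  interval's risk set;
* confusion metrics (accuracy, sensitivity, specificity, PPV) at fixed
  probability thresholds, and the Youden-optimal threshold;
* stratified cross-validation folds and the Wald confidence-interval
  formulas used for descriptive tables.

Predictions live in a :class:`PredictionSet`: per test subject, the
predicted per-interval hazards (and survival curve) over a shared
interval scheme, next to the observed outcome age and event flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.model_selection import StratifiedKFold

from .cohort import IntervalScheme, Subject, survival_from_hazards

__all__ = [
    "PredictionSet",
    "CensoringDistribution",
    "ConfusionMetrics",
    "UndefinedMetricError",
    "td_c_index",
    "brier_score",
    "mean_brier",
    "interval_auc",
    "confusion_at_threshold",
    "optimal_threshold",
    "stratified_folds",
    "ci_proportion",
    "ci_mean",
]

DEFAULT_BRIER_AGES: tuple[float, ...] = (15.0, 20.0, 25.0)
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (e.g. no comparable pairs)."""


@dataclass
class PredictionSet:
    """Predicted hazard paths for a set of (test) subjects.

    ``hazards`` is ``(n_subjects, n_intervals)``; row ``i`` holds subject
    ``i``'s predicted conditional event probability for each interval of
    ``scheme``.  ``survival`` is its product-limit composition (computed
    if not supplied) and must be non-increasing per subject.
    """

    scheme: IntervalScheme
    subject_ids: list[str]
    hazards: np.ndarray
    outcome_age: np.ndarray
    event: np.ndarray
    survival: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hazards = np.atleast_2d(np.asarray(self.hazards, dtype=float))
        self.outcome_age = np.asarray(self.outcome_age, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n, m = self.hazards.shape
        if m != self.scheme.n_intervals:
            raise ValueError("hazards must have one column per scheme interval")
        if not (len(self.subject_ids) == len(self.outcome_age) == len(self.event) == n):
            raise ValueError("inconsistent PredictionSet lengths")
        if self.survival is None:
            with np.errstate(invalid="ignore"):
                self.survival = np.cumprod(1.0 - self.hazards, axis=1)
        else:
            self.survival = np.atleast_2d(np.asarray(self.survival, dtype=float))
            diffs = np.diff(self.survival, axis=1)
            if np.nanmax(diffs, initial=-np.inf) > 1e-12:
                raise ValueError("survival curves must be non-increasing")

    def __len__(self) -> int:
        return len(self.subject_ids)

    def survival_at(self, i: int, age: float) -> float:
        """Step-function survival of subject ``i`` evaluated at an age.

        ``S(age)`` is the probability of surviving every interval that ends
        at or before ``age`` (the curve drops at interval ends).
        """
        n_full = self.scheme.n_full_intervals(age)
        if n_full == 0:
            return 1.0
        return float(self.survival[i, n_full - 1])

    def event_interval(self, i: int) -> int:
        return self.scheme.interval_index(self.outcome_age[i])

    def risk_set(self, k: int) -> np.ndarray:
        """Subjects at risk at the start of interval ``k`` and not censored in it.

        At risk in ``k`` means observed beyond the interval's end, or having
        the event inside it; subjects censored within ``k`` are excluded.
        """
        start, end = self.scheme.start(k), self.scheme.end(k)
        beyond = self.outcome_age >= end
        event_in = (
            (self.event == 1) & (self.outcome_age >= start) & (self.outcome_age < end)
        )
        return np.flatnonzero(beyond | event_in)

    def event_in_interval(self, k: int) -> np.ndarray:
        start, end = self.scheme.start(k), self.scheme.end(k)
        return (
            (self.event == 1) & (self.outcome_age >= start) & (self.outcome_age < end)
        ).astype(int)


class CensoringDistribution:
    """Kaplan–Meier estimate of the censoring survival function G.

    Fitted on (time, 1-event): censorings are the "events" of this curve.
    Used for IPCW weights: an event at ``t`` is weighted by ``1/G(t-)``,
    a survivor at the evaluation age by ``1/G(age)``.
    """

    def __init__(self, times: np.ndarray, event: np.ndarray):
        times = np.asarray(times, dtype=float)
        event = np.asarray(event, dtype=int)
        self._km = KaplanMeierFitter()
        self._km.fit(times, event_observed=1 - event)
        sf = self._km.survival_function_
        self._grid = sf.index.to_numpy(dtype=float)
        self._vals = sf.iloc[:, 0].to_numpy(dtype=float)

    def _lookup(self, t: float, left: bool) -> float:
        side = "left" if left else "right"
        idx = np.searchsorted(self._grid, t, side=side) - 1
        return 1.0 if idx < 0 else float(self._vals[idx])

    def at(self, t: float) -> float:
        """G(t), right-continuous."""
        return self._lookup(t, left=False)

    def at_minus(self, t: float) -> float:
        """G(t-), the left limit."""
        return self._lookup(t, left=True)

    @classmethod
    def from_predictions(cls, preds: PredictionSet) -> "CensoringDistribution":
        return cls(preds.outcome_age, preds.event)

    @classmethod
    def from_cohort(cls, cohort: Sequence[Subject]) -> "CensoringDistribution":
        return cls(
            np.array([s.outcome_age for s in cohort]),
            np.array([s.event for s in cohort]),
        )


def td_c_index(preds: PredictionSet) -> float:
    """Time-dependent concordance index.

    Over comparable pairs — ``i`` with an observed event at ``t_i`` and
    ``j`` still at risk at ``t_i`` (``t_j > t_i``) — the fraction in which
    the model predicts lower survival at ``t_i`` for the subject who
    actually failed; predicted-survival ties get half credit.  0.5 is
    chance level, 1 is perfect ranking.
    """
    n = len(preds)
    if n < 2:
        raise UndefinedMetricError("need at least two subjects")
    conc = 0.0
    pairs = 0
    for i in range(n):
        if preds.event[i] != 1:
            continue
        t_i = preds.outcome_age[i]
        k = preds.event_interval(i)
        s_i = preds.survival[i, k]
        for j in range(n):
            if preds.outcome_age[j] <= t_i or j == i:
                continue
            pairs += 1
            s_j = preds.survival[j, k]
            if s_i < s_j:
                conc += 1.0
            elif s_i == s_j:
                conc += 0.5
    if pairs == 0:
        raise UndefinedMetricError("no comparable pairs (no events before another "
                                   "subject's observation time)")
    return conc / pairs


def brier_score(
    preds: PredictionSet,
    at_age: float,
    weighting: str = "ipcw",
    censoring: CensoringDistribution | None = None,
) -> float:
    """Brier score of the predicted event-free probability at an age.

    Mean of ``(S_hat(at_age) - event_free_at_age)^2`` over subjects whose
    status at ``at_age`` is known.  Under ``weighting="ipcw"``, events
    before ``at_age`` are weighted by ``1/G(t_i-)`` and subjects still
    under observation at ``at_age`` by ``1/G(at_age)``, where G is the
    Kaplan–Meier censoring distribution (estimated from ``preds`` unless a
    fitted :class:`CensoringDistribution` is supplied, e.g. one from the
    training folds); subjects censored before ``at_age`` get zero weight.
    0 is perfect, 0.25 is the chance level of a constant-0.5 prediction.
    """
    if weighting not in ("ipcw", "unweighted"):
        raise ValueError("weighting must be 'ipcw' or 'unweighted'")
    if not (preds.scheme.min_age <= at_age <= preds.scheme.max_age):
        raise ValueError(f"at_age {at_age} outside the scheme range")
    if weighting == "ipcw" and censoring is None:
        censoring = CensoringDistribution.from_predictions(preds)
    num = 0.0
    den = 0.0
    for i in range(len(preds)):
        t, e = preds.outcome_age[i], preds.event[i]
        s_hat = preds.survival_at(i, at_age)
        if t < at_age and e == 1:        # failed before at_age
            y, w_t = 0.0, t
        elif t >= at_age:                # still event-free at at_age
            y, w_t = 1.0, at_age
        else:                            # censored before at_age: unknown status
            continue
        if weighting == "ipcw":
            g = censoring.at_minus(t) if (t < at_age and e == 1) else censoring.at(at_age)
            if g <= 0.0:
                raise UndefinedMetricError(
                    f"IPCW weight undefined: censoring survival is 0 at age "
                    f"{w_t:g}"
                )
            w = 1.0 / g
        else:
            w = 1.0
        num += w * (s_hat - y) ** 2
        den += 1.0
    if den == 0:
        raise UndefinedMetricError(f"no subject with known status at age {at_age}")
    # Graf's IPCW estimator averages over all subjects (the excluded ones
    # carry zero weight); the unweighted form averages over known statuses.
    return num / (len(preds) if weighting == "ipcw" else den)


def mean_brier(
    preds: PredictionSet,
    ages: Sequence[float] = DEFAULT_BRIER_AGES,
    weighting: str = "ipcw",
    censoring: CensoringDistribution | None = None,
) -> float:
    """Arithmetic mean of the Brier score over fixed ages (default 15/20/25)."""
    return float(
        np.mean([brier_score(preds, a, weighting=weighting, censoring=censoring) for a in ages])
    )


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMetricError("risk set needs at least one event and one non-event")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


def interval_auc(preds: PredictionSet, interval_index: int) -> float:
    """Incident/dynamic AUC of the predicted hazard for one interval.

    Among subjects at risk at the start of the interval (those censored
    within it excluded), the predicted interval hazard is scored as a
    classifier of event-in-interval versus survived-interval; ties get
    half credit.
    """
    rs = preds.risk_set(interval_index)
    labels = preds.event_in_interval(interval_index)[rs]
    scores = preds.hazards[rs, interval_index]
    if len(rs) == 0 or labels.sum() == 0 or labels.sum() == len(labels):
        raise UndefinedMetricError(
            f"interval {interval_index}: degenerate risk set "
            f"({len(rs)} at risk, {int(labels.sum()) if len(rs) else 0} events)"
        )
    if np.any(np.isnan(scores)):
        raise UndefinedMetricError(f"interval {interval_index}: NaN hazards in risk set")
    return float(_rank_auc(scores, labels))


@dataclass
class ConfusionMetrics:
    """2x2 classification summary at a hazard threshold.

    ``ppv`` is NaN with ``ppv_defined=False`` when no subject is predicted
    positive (it is reported as undefined, never as 0).
    """

    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    ppv_defined: bool
    tp: int
    fp: int
    fn: int
    tn: int


def confusion_at_threshold(
    preds: PredictionSet, interval_index: int, threshold: float
) -> ConfusionMetrics:
    """Accuracy / sensitivity / specificity / PPV at a hazard threshold.

    Subjects in the interval's risk set are classified positive when their
    predicted hazard for the interval is ``>= threshold``.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    rs = preds.risk_set(interval_index)
    if len(rs) == 0:
        raise UndefinedMetricError(f"interval {interval_index}: empty risk set")
    labels = preds.event_in_interval(interval_index)[rs]
    scores = preds.hazards[rs, interval_index]
    pred_pos = scores >= threshold
    tp = int(np.sum(pred_pos & (labels == 1)))
    fp = int(np.sum(pred_pos & (labels == 0)))
    fn = int(np.sum(~pred_pos & (labels == 1)))
    tn = int(np.sum(~pred_pos & (labels == 0)))
    acc = (tp + tn) / len(rs)
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    ppv_defined = (tp + fp) > 0
    ppv = tp / (tp + fp) if ppv_defined else np.nan
    return ConfusionMetrics(
        threshold=threshold, accuracy=acc, sensitivity=sens, specificity=spec,
        ppv=ppv, ppv_defined=ppv_defined, tp=tp, fp=fp, fn=fn, tn=tn,
    )


def optimal_threshold(preds: PredictionSet, interval_index: int) -> tuple[float, bool]:
    """Hazard threshold maximizing Youden's J (sensitivity + specificity - 1).

    Candidates are the observed predicted hazards in the risk set; ties are
    broken toward the smaller threshold, and the returned value is the
    midpoint between the chosen cut and the next-lower observed hazard when
    one exists.  Returns ``(threshold, degenerate)`` where ``degenerate``
    flags an all-ties risk set (J = 0 everywhere).
    """
    rs = preds.risk_set(interval_index)
    labels = preds.event_in_interval(interval_index)[rs]
    scores = preds.hazards[rs, interval_index]
    if len(rs) == 0 or labels.sum() == 0 or labels.sum() == len(labels):
        raise UndefinedMetricError(f"interval {interval_index}: degenerate risk set")
    uniq = np.unique(scores)
    best_j, best_cut = -np.inf, None
    for cut in uniq:  # ascending: ties keep the smaller threshold
        pred_pos = scores >= cut
        tp = np.sum(pred_pos & (labels == 1))
        fp = np.sum(pred_pos & (labels == 0))
        fn = np.sum(~pred_pos & (labels == 1))
        tn = np.sum(~pred_pos & (labels == 0))
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = j, cut
    degenerate = bool(best_j <= 1e-12 and len(uniq) == 1)
    idx = np.searchsorted(uniq, best_cut)
    if idx > 0:
        return float(0.5 * (uniq[idx - 1] + best_cut)), degenerate
    return float(best_cut), degenerate


def stratified_folds(cohort: Sequence[Subject], k: int = 10, seed: int = 0) -> np.ndarray:
    """Event-stratified k-fold assignment (fold id per subject).

    Events and non-events are spread as evenly as possible: per-fold event
    counts differ by at most one.  Deterministic given the seed.
    """
    n = len(cohort)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds cohort size {n}")
    y = np.array([s.event for s in cohort])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(n), y)):
        folds[test_idx] = f
    return folds


def ci_proportion(count: int, n: int, clip: bool = False) -> tuple[float, float]:
    """Wald 95% confidence interval for a percentage.

    ``100 * (p +/- 1.96 * sqrt(p*(1-p)/n))`` with ``p = count/n``, reported
    in percent.  Applied literally by default; ``clip=True`` truncates to
    [0, 100].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= count <= n):
        raise ValueError("count must be in [0, n]")
    p = count / n
    half = 1.96 * np.sqrt(p * (1 - p) / n)
    lo, hi = 100 * (p - half), 100 * (p + half)
    if clip:
        lo, hi = max(lo, 0.0), min(hi, 100.0)
    return lo, hi


def ci_mean(m: float, sd: float, n: int) -> tuple[float, float]:
    """95% confidence interval for a mean: ``m +/- 1.96 * sd / sqrt(n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    half = 1.96 * sd / np.sqrt(n)
    return m - half, m + half
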