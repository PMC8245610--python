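"""Discrete-time survival via logistic regression on person-period rows.

The comparison baseline: the conditional hazard of diagnosis in interval
``k`` is ``expit(alpha_k + beta . x)`` with one free intercept per age
interval (the classical discrete-hazard parameterization) and covariate
effects that are constant across intervals — the proportional-odds,
linear-on-the-logit assumptions the neural-network alternative relaxes.

Fitting maximizes the Bernoulli log-likelihood of ``event_in_interval``
by Newton–Raphson, optionally with a small ridge penalty on the
covariate coefficients (not the interval intercepts) to guard against
complete separation.  Continuous covariates are standardized internally
with the training data's statistics; reported coefficients are on the
original scale.

The ``time_input`` column (interval midpoint age) is excluded from the
design because it is an exact linear function of the interval dummies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CONTINUOUS_COLUMNS, COVARIATE_COLUMNS, IntervalScheme, PersonPeriodTable

__all__ = ["DiscreteTimeLogisticHazard", "DiscreteTimeLogisticResults", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """The likelihood has no finite maximum (e.g. complete separation)."""


#: Covariates entering the GLM design (time is carried by interval dummies).
GLM_COVARIATES: tuple[str, ...] = tuple(c for c in COVARIATE_COLUMNS if c != "time_input")


def _standardization(frame: pd.DataFrame, columns: Sequence[str]):
    """Per-column (mean, sd) for continuous columns; sd floored at tiny."""
    stats = {}
    for c in columns:
        if c in CONTINUOUS_COLUMNS:
            mu = float(frame[c].mean())
            sd = float(frame[c].std(ddof=0))
            stats[c] = (mu, sd if sd > 1e-12 else 1.0)
        else:
            stats[c] = (0.0, 1.0)
    return stats


class DiscreteTimeLogisticHazard:
    """Discrete-hazard logistic model on a person-period table.

    Parameters
    ----------
    table : PersonPeriodTable
        Training data (one row per subject per at-risk interval).
    ridge_penalty : float
        Ridge weight applied to standardized covariate coefficients;
        the default 1e-6 is a numerical-stability guard.  Set to 0 for the
        exact maximum-likelihood fit.
    standardize : bool
        Standardize continuous covariates using this table's statistics.
    """

    def __init__(
        self,
        table: PersonPeriodTable,
        ridge_penalty: float = 1e-6,
        standardize: bool = True,
    ):
        if len(table) == 0:
            raise ValueError("person-period table is empty")
        if ridge_penalty < 0:
            raise ValueError("ridge_penalty must be non-negative")
        self.table = table
        self.scheme = table.scheme
        self.ridge_penalty = float(ridge_penalty)
        self.standardize = bool(standardize)
        self.covariate_names = tuple(c for c in table.covariate_columns if c != "time_input")

        frame = table.frame
        seen = frame["interval_index"].astype(int)
        if seen.max() >= self.scheme.n_intervals or seen.min() < 0:
            raise ValueError("table contains interval indices outside its scheme")
        self._intervals_seen = np.sort(seen.unique())

    # -- design -------------------------------------------------------------
    def _design(self, frame: pd.DataFrame, stats) -> tuple[np.ndarray, np.ndarray]:
        n = len(frame)
        kidx = frame["interval_index"].to_numpy(dtype=int)
        pos = {k: j for j, k in enumerate(self._intervals_seen)}
        D = np.zeros((n, len(self._intervals_seen)))
        D[np.arange(n), [pos[k] for k in kidx]] = 1.0
        X = np.empty((n, len(self.covariate_names)))
        for j, c in enumerate(self.covariate_names):
            mu, sd = stats[c]
            X[:, j] = (frame[c].to_numpy(dtype=float) - mu) / sd
        return D, X

    def fit(self, max_iter: int = 100, tol: float = 1e-10) -> "DiscreteTimeLogisticResults":
        frame = self.table.frame
        stats = (
            _standardization(frame, self.covariate_names)
            if self.standardize
            else {c: (0.0, 1.0) for c in self.covariate_names}
        )
        D, X = self._design(frame, stats)
        y = frame["event_in_interval"].to_numpy(dtype=float)
        Z = np.hstack([D, X])
        n_int = D.shape[1]
        p = Z.shape[1]
        lam = self.ridge_penalty
        pen = np.zeros(p)
        pen[n_int:] = lam  # intercepts unpenalized

        theta = np.zeros(p)
        grad_norm = np.inf
        for it in range(1, max_iter + 1):
            eta = Z @ theta
            mu = expit(eta)
            grad = Z.T @ (y - mu) - pen * theta
            w = mu * (1.0 - mu)
            H = (Z * w[:, None]).T @ Z + np.diag(pen)
            # ties the Newton system down when an interval is degenerate
            H[np.diag_indices_from(H)] += 1e-12
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ConvergenceError(f"singular Hessian at iteration {it}") from exc
            # dampen huge steps (separation drives |theta| -> inf)
            norm = np.linalg.norm(step, ord=np.inf)
            if norm > 10.0:
                step *= 10.0 / norm
            theta = theta + step
            grad_norm = float(np.linalg.norm(Z.T @ (y - expit(Z @ theta)) - pen * theta, ord=np.inf))
            if grad_norm < tol:
                break
            if np.linalg.norm(theta, ord=np.inf) > 30.0 and lam == 0.0:
                raise ConvergenceError(
                    "likelihood appears unbounded (complete or quasi-complete "
                    "separation, or an interval with no events); refit with a "
                    "positive ridge_penalty"
                )
        else:
            if grad_norm > 1e-6:
                raise ConvergenceError(
                    f"Newton iteration did not converge in {max_iter} steps "
                    f"(|grad| = {grad_norm:.3g}); consider a positive ridge_penalty"
                )
        if lam == 0.0 and np.linalg.norm(theta, ord=np.inf) > 20.0:
            # a finite gradient norm with runaway parameters means the MLE is
            # at infinity (no events in some interval, or separation)
            raise ConvergenceError(
                "maximum-likelihood estimate lies at infinity (an interval "
                "without events, or complete separation); refit with a "
                "positive ridge_penalty"
            )

        eta = Z @ theta
        loglike = float(np.sum(y * eta - np.log1p(np.exp(np.clip(eta, None, 500)))))

        # intercepts per scheme interval; unseen intervals are inestimable
        intercepts = np.full(self.scheme.n_intervals, np.nan)
        intercepts[self._intervals_seen] = theta[:n_int]
        coef_std = theta[n_int:]
        # back to original scale: beta_orig = beta_std / sd; intercept shift
        coef = np.empty_like(coef_std)
        shift = 0.0
        for j, c in enumerate(self.covariate_names):
            mu, sd = stats[c]
            coef[j] = coef_std[j] / sd
            shift += coef_std[j] * mu / sd
        intercepts -= shift

        return DiscreteTimeLogisticResults(
            model=self,
            interval_intercepts=intercepts,
            coefficients=pd.Series(coef, index=list(self.covariate_names)),
            loglike=loglike,
            n_iter=it,
            final_grad_norm=grad_norm,
            standardization=stats,
        )


@dataclass
class DiscreteTimeLogisticResults:
    """Fitted discrete-hazard GLM.

    ``interval_intercepts`` holds one intercept per scheme interval on the
    original covariate scale (NaN for intervals with no at-risk rows in the
    training table); ``coefficients`` are per-covariate log-odds effects.
    """

    model: DiscreteTimeLogisticHazard
    interval_intercepts: np.ndarray
    coefficients: pd.Series
    loglike: float
    n_iter: int
    final_grad_norm: float
    standardization: dict

    @property
    def scheme(self) -> IntervalScheme:
        return self.model.scheme

    def linear_predictor(self, frame: pd.DataFrame, allow_missing: bool = False) -> np.ndarray:
        missing = [c for c in self.coefficients.index if c not in frame.columns]
        if missing:
            raise ValueError(f"prediction frame lacks covariate columns: {missing}")
        kidx = frame["interval_index"].to_numpy(dtype=int)
        if kidx.min() < 0 or kidx.max() >= len(self.interval_intercepts):
            raise ValueError("interval_index outside the fitted scheme")
        alpha = self.interval_intercepts[kidx]
        if not allow_missing and np.any(np.isnan(alpha)):
            bad = sorted(set(kidx[np.isnan(alpha)].tolist()))
            raise ValueError(
                f"no intercept estimated for interval(s) {bad} (no at-risk rows "
                "in training data); pass allow_missing=True to get NaN hazards"
            )
        eta = alpha.astype(float).copy()
        for c, b in self.coefficients.items():
            eta += b * frame[c].to_numpy(dtype=float)
        return eta

    def predict_hazard(self, rows, allow_missing: bool = False) -> np.ndarray:
        """Conditional event probability for each person-period row."""
        frame = rows.frame if isinstance(rows, PersonPeriodTable) else pd.DataFrame(rows)
        return expit(self.linear_predictor(frame, allow_missing=allow_missing))

    def summary(self) -> str:
        lines = [
            "Discrete-time logistic hazard model",
            "=" * 51,
            f"person-period rows: {len(self.model.table)}   "
            f"subjects: {self.model.table.n_subjects}",
            f"interval width: {self.scheme.width} y   "
            f"intervals: {self.scheme.n_intervals}",
            f"ridge penalty: {self.model.ridge_penalty:g}   "
            f"log-likelihood: {self.loglike:.3f}",
            f"Newton iterations: {self.n_iter}   |grad|: {self.final_grad_norm:.2e}",
            "-" * 51,
            f"{'covariate':<28}{'log-odds':>12}",
        ]
        for c, b in self.coefficients.items():
            lines.append(f"{c:<28}{b:>12.4f}")
        est = ~np.isnan(self.interval_intercepts)
        lines.append("-" * 51)
        lines.append(
            f"interval intercepts: {est.sum()} estimated, {(~est).sum()} inestimable"
        )
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": "discrete_time_logistic_hazard",
            "scheme": {
                "width": self.scheme.width,
                "min_age": self.scheme.min_age,
                "boundaries": list(self.scheme.boundaries),
            },
            "interval_intercepts": [None if np.isnan(v) else v for v in self.interval_intercepts],
            "coefficients": {c: float(b) for c, b in self.coefficients.items()},
            "standardization": {c: list(v) for c, v in self.standardization.items()},
            "loglike": self.loglike,
            "ridge_penalty": self.model.ridge_penalty,
        }
        Path(path).write_text(json.dumps(payload, indent=2))
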