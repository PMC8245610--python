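"""Partial logistic artificial neural network (PLANN) hazard estimator.

A feed-forward network with one hidden layer and sigmoid activations
throughout, fitted on person-period rows.  The single sigmoid output is
the conditional probability of diagnosis in the row's interval, so the
network is a drop-in replacement for the discrete-hazard GLM, trained
on the same Bernoulli (cross-entropy) likelihood plus weight decay.

Time enters as an ordinary input (the interval midpoint age,
``time_input``), which lets the network express non-proportional
hazards and nonlinear covariate effects; the GLM's interval dummies are
not used.

Training is deterministic given the seed: weights are initialized from
a seeded generator and optimized full-batch with L-BFGS (analytic
gradient).  An optional validation split provides early stopping — the
returned weights are the best seen on the held-out rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .cohort import CONTINUOUS_COLUMNS, COVARIATE_COLUMNS, IntervalScheme, PersonPeriodTable

__all__ = ["PlannHyperparams", "PLANN", "PlannResults"]


@dataclass
class PlannHyperparams:
    """Tunable training settings.

    hidden_units : width of the single hidden layer (default 8).
    weight_decay : L2 penalty on connection weights, not biases
        (default 0.01; larger values shrink predictions toward the
        marginal event rate).
    max_epochs : L-BFGS iteration cap.
    patience : early-stopping patience in iterations on the validation
        split; validation_fraction 0 disables early stopping.
    seed : controls initialization and the validation shuffle split.
    standardize : standardize continuous inputs (binary inputs stay 0/1).
    """

    hidden_units: int = 8
    weight_decay: float = 0.01
    max_epochs: int = 500
    patience: int = 25
    validation_fraction: float = 0.1
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.max_epochs < 1 or self.patience < 1:
            raise ValueError("max_epochs and patience must be positive")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")


def _unpack(theta: np.ndarray, d: int, h: int):
    i = 0
    W1 = theta[i : i + d * h].reshape(d, h); i += d * h
    b1 = theta[i : i + h]; i += h
    W2 = theta[i : i + h]; i += h
    b2 = theta[i]
    return W1, b1, W2, b2


def _forward(theta: np.ndarray, X: np.ndarray, d: int, h: int):
    W1, b1, W2, b2 = _unpack(theta, d, h)
    A = expit(X @ W1 + b1)
    return A, expit(A @ W2 + b2)


def _loss_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, d: int, h: int, lam: float):
    n = len(y)
    W1, b1, W2, b2 = _unpack(theta, d, h)
    A = expit(X @ W1 + b1)
    z = A @ W2 + b2
    p = expit(z)
    # mean cross-entropy, numerically via logaddexp; the decay penalty is on
    # the summed-likelihood scale (the classical penalized-deviance
    # convention), hence the 1/n here
    ll = np.mean(y * np.logaddexp(0.0, -z) + (1 - y) * np.logaddexp(0.0, z))
    lam_n = lam / n
    loss = ll + lam_n * (np.sum(W1 * W1) + np.sum(W2 * W2))
    delta = (p - y) / n                     # dLoss/dz
    gW2 = A.T @ delta + 2 * lam_n * W2
    gb2 = delta.sum()
    dA = np.outer(delta, W2) * A * (1 - A)  # back through hidden sigmoid
    gW1 = X.T @ dA + 2 * lam_n * W1
    gb1 = dA.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2, [gb2]])
    return loss, grad


class _EarlyStop(Exception):
    pass


class PLANN:
    """PLANN model bound to a person-period training table."""

    def __init__(self, table: PersonPeriodTable, hp: PlannHyperparams | None = None):
        if len(table) == 0:
            raise ValueError("person-period table is empty")
        if "time_input" not in table.covariate_columns:
            raise ValueError("PLANN requires the time_input covariate column")
        self.table = table
        self.scheme = table.scheme
        self.hp = hp or PlannHyperparams()
        self.input_columns: tuple[str, ...] = tuple(table.covariate_columns)

    def _standardization(self) -> dict[str, tuple[float, float]]:
        stats = {}
        frame = self.table.frame
        for c in self.input_columns:
            if self.hp.standardize and c in CONTINUOUS_COLUMNS:
                mu = float(frame[c].mean())
                sd = float(frame[c].std(ddof=0))
                stats[c] = (mu, sd if sd > 1e-12 else 1.0)
            else:
                stats[c] = (0.0, 1.0)
        return stats

    def fit(self) -> "PlannResults":
        hp = self.hp
        stats = self._standardization()
        frame = self.table.frame
        X = np.column_stack(
            [(frame[c].to_numpy(dtype=float) - stats[c][0]) / stats[c][1] for c in self.input_columns]
        )
        y = frame["event_in_interval"].to_numpy(dtype=float)
        n, d = X.shape
        h = hp.hidden_units

        rng = np.random.default_rng(hp.seed)
        # small symmetric init keeps the net near-linear at the start
        theta0 = rng.normal(0.0, 0.5 / np.sqrt(d + 1), size=d * h + h + h + 1)

        n_val = int(round(hp.validation_fraction * n))
        if n_val >= 1 and n - n_val >= 2:
            perm = rng.permutation(n)
            val_idx, train_idx = perm[:n_val], perm[n_val:]
        else:
            val_idx, train_idx = np.array([], dtype=int), np.arange(n)
        Xt, yt = X[train_idx], y[train_idx]
        Xv, yv = X[val_idx], y[val_idx]
        lam = hp.weight_decay

        history: list[dict[str, float]] = []
        best = {"theta": theta0.copy(), "val": np.inf, "iter": 0}
        stall = 0

        def callback(theta):
            nonlocal stall
            loss, _ = _loss_grad(theta, Xt, yt, d, h, lam)
            if np.isnan(loss):
                raise FloatingPointError("PLANN training loss became NaN")
            rec = {"iter": len(history) + 1, "train_loss": float(loss)}
            if len(yv):
                vloss, _ = _loss_grad(theta, Xv, yv, d, h, lam)
                rec["val_loss"] = float(vloss)
                if vloss < best["val"] - 1e-12:
                    best.update(theta=np.asarray(theta).copy(), val=vloss, iter=rec["iter"])
                    stall = 0
                else:
                    stall += 1
            history.append(rec)
            if len(yv) and stall >= hp.patience:
                raise _EarlyStop

        try:
            res = minimize(
                _loss_grad,
                theta0,
                args=(Xt, yt, d, h, lam),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": hp.max_epochs, "ftol": 1e-12, "gtol": 1e-9},
                callback=callback,
            )
            theta_final = res.x
        except _EarlyStop:
            theta_final = best["theta"]
        if len(yv) and best["val"] < np.inf:
            # return the best weights seen on the held-out split
            final_val, _ = _loss_grad(theta_final, Xv, yv, d, h, lam)
            if best["val"] < final_val:
                theta_final = best["theta"]
        loss_final, _ = _loss_grad(theta_final, Xt, yt, d, h, lam)
        if np.isnan(loss_final):
            raise FloatingPointError("PLANN training loss became NaN")

        W1, b1, W2, b2 = _unpack(theta_final, d, h)
        return PlannResults(
            model=self,
            W1=W1.copy(),
            b1=b1.copy(),
            W2=W2.copy(),
            b2=float(b2),
            standardization=stats,
            history=pd.DataFrame(history),
            final_train_loss=float(loss_final),
        )


@dataclass
class PlannResults:
    """Fitted PLANN: weights, standardization constants, training history."""

    model: PLANN
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: float
    standardization: dict
    history: pd.DataFrame
    final_train_loss: float

    @property
    def scheme(self) -> IntervalScheme:
        return self.model.scheme

    @property
    def input_columns(self) -> tuple[str, ...]:
        return self.model.input_columns

    def _matrix(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.input_columns if c not in frame.columns]
        extra = [
            c
            for c in frame.columns
            if c not in self.input_columns
            and c
            not in ("subject_id", "interval_index", "interval_start", "interval_end", "event_in_interval")
        ]
        if missing:
            raise ValueError(f"prediction frame: missing columns {missing}; extra columns {extra}")
        return np.column_stack(
            [
                (frame[c].to_numpy(dtype=float) - self.standardization[c][0])
                / self.standardization[c][1]
                for c in self.input_columns
            ]
        )

    def predict_hazard(self, rows) -> np.ndarray:
        """Forward pass: conditional event probability per row, in (0, 1)."""
        frame = rows.frame if isinstance(rows, PersonPeriodTable) else pd.DataFrame(rows)
        X = self._matrix(frame)
        A = expit(X @ self.W1 + self.b1)
        return expit(A @ self.W2 + self.b2)

    def summary(self) -> str:
        hp = self.model.hp
        lines = [
            "Partial logistic artificial neural network (PLANN)",
            "=" * 51,
            f"inputs: {len(self.input_columns)}   hidden units: {hp.hidden_units}",
            f"weight decay: {hp.weight_decay:g}   seed: {hp.seed}",
            f"training rows: {len(self.model.table)}   "
            f"iterations: {len(self.history)}",
            f"final penalized train loss: {self.final_train_loss:.5f}",
        ]
        if "val_loss" in self.history.columns and len(self.history):
            lines.append(f"best validation loss: {self.history['val_loss'].min():.5f}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        hp = self.model.hp
        payload = {
            "model": "plann",
            "scheme": {
                "width": self.scheme.width,
                "min_age": self.scheme.min_age,
                "boundaries": list(self.scheme.boundaries),
            },
            "input_columns": list(self.input_columns),
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
            "standardization": {c: list(v) for c, v in self.standardization.items()},
            "hyperparams": {
                "hidden_units": hp.hidden_units,
                "weight_decay": hp.weight_decay,
                "max_epochs": hp.max_epochs,
                "patience": hp.patience,
                "validation_fraction": hp.validation_fraction,
                "seed": hp.seed,
                "standardize": hp.standardize,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))
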