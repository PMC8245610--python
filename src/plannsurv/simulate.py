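"""Synthetic high-risk cohorts with known discrete-hazard truth.

The original cohort is not publicly deposited, so this module generates
cohorts with its statistical structure: time-fixed covariate marginals
matching the published descriptive table (41.4% male, 44.2% parental
lithium response, abuse yes/no/missing 10.3/51.7/38.0%, parental onset
age mean 25.4), antecedent indicator onsets arriving interval by
interval, small mood-episode counting processes, a discrete logistic
hazard for the diagnosis outcome using the same one-interval lag
convention as :mod:`plannsurv.cohort`, and administrative censoring at a
last-visit age drawn uniformly.

Every generated subject carries a closed-form truth record (linear
predictor, hazard and survival per at-risk interval) so that model
recovery can be tested against an exact oracle.

Covariates are generated independently (no joint distribution is
published); all joint structure in the defaults is invented and labelled
as such in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import expit

from .cohort import (
    COVARIATE_COLUMNS,
    INDICATOR_NAMES,
    IntervalScheme,
    Subject,
    build_interval_scheme,
    n_at_risk_intervals,
    subject_covariate_row,
    survival_from_hazards,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "generate_cohort",
    "true_survival",
    "default_onset_hazards",
]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


#: Lifetime prevalence of each antecedent indicator in the study sample
#: (full-sample column of the descriptive table).
INDICATOR_PREVALENCES: dict[str, float] = {
    "subthreshold_activation": 0.099,
    "subthreshold_depression": 0.106,
    "subthreshold_sleep": 0.031,
    "subthreshold_substance": 0.123,
    "subthreshold_anxiety": 0.154,
    "substance_use": 0.175,
    "sleep": 0.185,
    "anxiety": 0.298,
    "neurodevelopmental": 0.113,
}

#: Mean years a subject is at risk under the default follow-up window;
#: used once to convert lifetime prevalences into annual onset hazards.
DEFAULT_AT_RISK_YEARS = 16.0


def default_onset_hazards() -> dict[str, float]:
    """Per-indicator annual onset probabilities.

    Chosen so that a subject at risk for ``DEFAULT_AT_RISK_YEARS`` years has
    lifetime onset probability matching the published prevalence:
    ``h = 1 - (1 - p)**(1/T)``.
    """
    return {
        name: 1.0 - (1.0 - p) ** (1.0 / DEFAULT_AT_RISK_YEARS)
        for name, p in INDICATOR_PREVALENCES.items()
    }


def _default_coefficients() -> dict[str, float]:
    # Invented log-odds effects, directionally consistent with the observed
    # event-vs-full-sample contrasts (fewer males among events, more
    # substance use / subthreshold activation and depression among events).
    return {
        "sex_male": -0.4,
        "parental_lithium_response": -0.1,
        "abuse_yes": 0.3,
        "abuse_missing": -0.3,
        "subthreshold_activation": 0.6,
        "subthreshold_depression": 0.4,
        "substance_use": 0.5,
        "anxiety": 0.3,
        "major_episodes": 0.4,
        "minor_episodes": 0.2,
    }


@dataclass
class SimulationConfig:
    """Configuration of the synthetic cohort generator.

    Defaults emulate the study conditions: n = 292 subjects enrolled from
    age 5, annual at-risk intervals to age 40, uniform last-visit
    (censoring) ages, and an outcome hazard calibrated so that roughly
    38% of subjects are diagnosed, at a median age near 20.

    ``baseline_logit`` is the per-interval intercept of the outcome hazard
    on the log-odds scale; a scalar is broadcast, and ``baseline_age_slope``
    adds a linear trend in (age − min_age) to mimic the rising incidence of
    mood disorder onset through adolescence.
    """

    n_subjects: int = 292
    min_age: float = 5.0
    max_age: float = 40.0
    prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "sex_male": 0.414,
            "parental_lithium_response": 0.442,
            "abuse_yes": 0.103,
            "abuse_missing": 0.380,
        }
    )
    parental_onset_age_mean: float = 25.4
    parental_onset_age_sd: float = 9.2
    onset_hazards: dict[str, float] = field(default_factory=default_onset_hazards)
    episode_rate: float = 0.012
    baseline_logit: float | Sequence[float] = -4.55
    baseline_age_slope: float = 0.08
    coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    interactions: dict[str, float] = field(default_factory=dict)
    censoring_low: float = 5.0
    censoring_high: float = 40.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SimulationError("n_subjects must be >= 1")
        for name, p in {**self.prevalences, **self.onset_hazards}.items():
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"probability for {name!r} out of [0, 1]: {p}")
        if self.prevalences.get("abuse_yes", 0) + self.prevalences.get("abuse_missing", 0) > 1:
            raise SimulationError("abuse_yes + abuse_missing must be <= 1")
        if self.episode_rate < 0:
            raise SimulationError("episode_rate must be non-negative")
        unknown = set(self.coefficients) - set(COVARIATE_COLUMNS)
        if unknown:
            raise SimulationError(f"coefficients for unknown covariates: {sorted(unknown)}")
        for key in self.interactions:
            parts = key.split("*")
            if len(parts) != 2 or any(p not in COVARIATE_COLUMNS for p in parts):
                raise SimulationError(
                    f"interaction key must be 'cov1*cov2' over known covariates, got {key!r}"
                )
        if not (self.min_age <= self.censoring_low <= self.censoring_high <= self.max_age):
            raise SimulationError("censoring bounds must satisfy min_age <= low <= high <= max_age")

    @property
    def scheme(self) -> IntervalScheme:
        """The width-1 generation scheme (the process evolves annually)."""
        return build_interval_scheme(1.0, self.min_age, self.max_age)

    def baseline_logits(self) -> np.ndarray:
        scheme = self.scheme
        base = np.broadcast_to(
            np.asarray(self.baseline_logit, dtype=float), (scheme.n_intervals,)
        ).copy()
        mids = np.array([scheme.midpoint(k) for k in range(scheme.n_intervals)])
        return base + self.baseline_age_slope * (mids - self.min_age)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "min_age": self.min_age,
            "max_age": self.max_age,
            "prevalences": dict(self.prevalences),
            "parental_onset_age_mean": self.parental_onset_age_mean,
            "parental_onset_age_sd": self.parental_onset_age_sd,
            "onset_hazards": dict(self.onset_hazards),
            "episode_rate": self.episode_rate,
            "baseline_logit": self.baseline_logit
            if np.isscalar(self.baseline_logit)
            else list(self.baseline_logit),
            "baseline_age_slope": self.baseline_age_slope,
            "coefficients": dict(self.coefficients),
            "interactions": dict(self.interactions),
            "censoring_low": self.censoring_low,
            "censoring_high": self.censoring_high,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class TruthRecord:
    """Closed-form truth for a generated cohort.

    Per subject: true linear predictor, hazard and survival over the
    intervals the subject is at risk in (aligned with the person-period
    rows that :func:`plannsurv.cohort.expand_to_person_periods` emits for
    the generation scheme).
    """

    scheme: IntervalScheme
    baseline_logits: np.ndarray
    coefficients: dict[str, float]
    linear_predictor: dict[str, np.ndarray]
    hazard: dict[str, np.ndarray]
    survival: dict[str, np.ndarray]

    def to_frame(self):
        import pandas as pd

        rows = []
        for sid, h in self.hazard.items():
            lp, s = self.linear_predictor[sid], self.survival[sid]
            for k in range(len(h)):
                rows.append(
                    {
                        "subject_id": sid,
                        "interval_index": k,
                        "linear_predictor": lp[k],
                        "hazard": h[k],
                        "survival": s[k],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["subject_id", "interval_index", "linear_predictor", "hazard", "survival"],
        )


def _linear_predictor(config: SimulationConfig, row: Mapping[str, float], k: int,
                      baseline: np.ndarray) -> float:
    lp = baseline[k]
    for name, beta in config.coefficients.items():
        lp += beta * row[name]
    for key, beta in config.interactions.items():
        a, b = key.split("*")
        lp += beta * row[a] * row[b]
    return float(lp)


def true_survival(config: SimulationConfig, covariate_path) -> np.ndarray:
    """Closed-form survival curve for a covariate path under the config.

    ``covariate_path`` is a DataFrame (or mapping of column -> sequence)
    whose row ``k`` holds the covariate vector in force during interval
    ``k`` of the generation scheme; hazards are
    ``expit(baseline_logit_k + beta . x_k)`` and the curve is their
    product-limit composition.
    """
    import pandas as pd

    path = pd.DataFrame(covariate_path)
    if len(path) == 0:
        return np.array([])
    needed = set(config.coefficients)
    for key in config.interactions:
        needed.update(key.split("*"))
    missing = needed - set(path.columns)
    if missing:
        raise SimulationError(f"covariate path lacks columns: {sorted(missing)}")
    baseline = config.baseline_logits()
    if len(path) > len(baseline):
        raise SimulationError("covariate path longer than the generation scheme")
    lp = baseline[: len(path)].copy()
    for name, beta in config.coefficients.items():
        lp += beta * path[name].to_numpy(dtype=float)
    for key, beta in config.interactions.items():
        a, b = key.split("*")
        lp += beta * path[a].to_numpy(dtype=float) * path[b].to_numpy(dtype=float)
    return survival_from_hazards(expit(lp))


def generate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[Subject], TruthRecord]:
    """Draw a synthetic cohort plus its truth record.

    The outcome process runs interval by interval on the width-1 generation
    scheme: at interval ``k`` the hazard is computed from covariates lagged
    exactly as the person-period expansion lags them, an event is drawn,
    and only then are this interval's indicator onsets and episodes drawn
    (they can influence intervals ``> k`` only).  Event and onset ages are
    uniform within their interval; antecedents at or after the outcome age
    are discarded.  Subjects whose event has not occurred by their drawn
    last-visit age are censored there.
    """
    rng = np.random.default_rng(seed)
    scheme = config.scheme
    baseline = config.baseline_logits()
    pv = config.prevalences

    subjects: list[Subject] = []
    lp_map: dict[str, np.ndarray] = {}
    hz_map: dict[str, np.ndarray] = {}
    sv_map: dict[str, np.ndarray] = {}

    p_yes = pv.get("abuse_yes", 0.0)
    p_missing = pv.get("abuse_missing", 0.0)

    for i in range(config.n_subjects):
        sid = f"S{i:05d}"
        sex = int(rng.random() < pv.get("sex_male", 0.5))
        lith = int(rng.random() < pv.get("parental_lithium_response", 0.5))
        u = rng.random()
        abuse = "yes" if u < p_yes else ("missing" if u < p_yes + p_missing else "no")
        ponset = float(np.clip(rng.normal(config.parental_onset_age_mean,
                                          config.parental_onset_age_sd), 10.0, 60.0))
        censor_age = float(rng.uniform(config.censoring_low, config.censoring_high))

        subject = Subject(
            id=sid,
            sex_male=sex,
            parental_lithium_response=lith,
            parental_onset_age=ponset,
            abuse=abuse,
            outcome_age=scheme.max_age,  # placeholder until outcome drawn
            event=0,
        )

        lps: list[float] = []
        hzs: list[float] = []
        event = 0
        outcome_age = censor_age
        for k in range(scheme.n_intervals):
            row = subject_covariate_row(subject, k, scheme)
            lp = _linear_predictor(config, row, k, baseline)
            h = float(expit(lp))
            lps.append(lp)
            hzs.append(h)
            if rng.random() < h:
                event_age = float(rng.uniform(scheme.start(k), scheme.end(k)))
                if event_age < censor_age:
                    event, outcome_age = 1, event_age
                    break
                outcome_age = censor_age
                break
            if censor_age < scheme.end(k):
                outcome_age = censor_age
                break
            # draw this interval's onsets and episodes (affect intervals > k)
            for name in INDICATOR_NAMES:
                if name in subject.onset_ages:
                    continue
                if rng.random() < config.onset_hazards.get(name, 0.0):
                    subject.onset_ages[name] = float(
                        rng.uniform(scheme.start(k), scheme.end(k))
                    )
            for ages in (subject.major_episode_ages, subject.minor_episode_ages):
                for _ in range(rng.poisson(config.episode_rate)):
                    ages.append(float(rng.uniform(scheme.start(k), scheme.end(k))))

        subject.outcome_age = outcome_age
        subject.event = event
        # antecedents only: drop anything at or after the outcome
        subject.onset_ages = {
            n: a for n, a in subject.onset_ages.items() if a < outcome_age
        }
        subject.major_episode_ages = sorted(
            a for a in subject.major_episode_ages if a < outcome_age
        )
        subject.minor_episode_ages = sorted(
            a for a in subject.minor_episode_ages if a < outcome_age
        )
        subjects.append(subject)

        n_rows = n_at_risk_intervals(subject, scheme)
        lp_arr = np.array(lps[:n_rows])
        hz_arr = np.array(hzs[:n_rows])
        lp_map[sid] = lp_arr
        hz_map[sid] = hz_arr
        sv_map[sid] = survival_from_hazards(hz_arr)

    truth = TruthRecord(
        scheme=scheme,
        baseline_logits=baseline,
        coefficients=dict(config.coefficients),
        linear_predictor=lp_map,
        hazard=hz_map,
        survival=sv_map,
    )
    return subjects, truth
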