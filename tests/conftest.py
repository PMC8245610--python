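import numpy as np
import pytest

from plannsurv import (
    IntervalScheme,
    PredictionSet,
    SimulationConfig,
    Subject,
    build_interval_scheme,
    generate_cohort,
)


def make_subject(
    id="s1",
    sex_male=0,
    parental_lithium_response=0,
    parental_onset_age=25.0,
    abuse="no",
    onset_ages=None,
    major_episode_ages=None,
    minor_episode_ages=None,
    outcome_age=20.0,
    event=1,
) -> Subject:
    return Subject(
        id=id,
        sex_male=sex_male,
        parental_lithium_response=parental_lithium_response,
        parental_onset_age=parental_onset_age,
        abuse=abuse,
        onset_ages=dict(onset_ages or {}),
        major_episode_ages=list(major_episode_ages or []),
        minor_episode_ages=list(minor_episode_ages or []),
        outcome_age=outcome_age,
        event=event,
    )


def make_prediction_set(hazards, outcome_age, event, scheme=None, survival=None):
    hazards = np.atleast_2d(np.asarray(hazards, dtype=float))
    if scheme is None:
        scheme = build_interval_scheme(1.0, 0.0, float(hazards.shape[1]))
    return PredictionSet(
        scheme=scheme,
        subject_ids=[f"p{i}" for i in range(hazards.shape[0])],
        hazards=hazards,
        outcome_age=np.asarray(outcome_age, dtype=float),
        event=np.asarray(event, dtype=int),
        survival=survival,
    )


def random_prediction_set(rng, n=12, n_intervals=6, censor_frac=0.35):
    """Small random instance for oracle-equivalence checks."""
    scheme = build_interval_scheme(1.0, 0.0, float(n_intervals))
    hazards = rng.uniform(0.02, 0.6, size=(n, n_intervals))
    outcome_age = rng.uniform(0.2, n_intervals - 1e-6, size=n)
    event = (rng.random(n) > censor_frac).astype(int)
    return make_prediction_set(hazards, outcome_age, event, scheme=scheme)


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort at the study's default conditions (fixed seed)."""
    cohort, truth = generate_cohort(SimulationConfig(n_subjects=250), seed=42)
    return cohort, truth
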