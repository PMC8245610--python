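"""Domain model for a prospectively followed high-risk cohort.

The package studies time-to-diagnosis of bipolar-related major mood
disorder in the offspring of bipolar parents.  Each subject carries
time-fixed covariates (sex, parental lithium response, parental onset
age, childhood abuse), ages of first onset for nine antecedent clinical
indicators, ages of antecedent major/minor mood episodes, and an outcome
(diagnosis age, or censoring at the last follow-up visit).  The time
scale is the subject's age in years.

Both hazard models in this package are fitted on the *person-period*
expansion of the cohort: one row per subject per at-risk age interval,
with a binary outcome "event occurred in this interval".  Time-varying
covariates are lagged by one interval — a row for interval ``[a, b)``
only sees onsets and episodes that occurred strictly before ``a`` — so
that predictions for an interval use only information available at its
start and reverse causality is excluded by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_NAMES",
    "COVARIATE_COLUMNS",
    "LAGGED_COLUMNS",
    "CONTINUOUS_COLUMNS",
    "Subject",
    "IntervalScheme",
    "PersonPeriodTable",
    "build_interval_scheme",
    "expand_to_person_periods",
    "lagged_indicator",
    "lagged_cumulative_episodes",
    "survival_from_hazards",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: The nine antecedent time-varying indicators, in canonical column order.
INDICATOR_NAMES: tuple[str, ...] = (
    "subthreshold_activation",
    "subthreshold_depression",
    "subthreshold_sleep",
    "subthreshold_substance",
    "subthreshold_anxiety",
    "substance_use",
    "sleep",
    "anxiety",
    "neurodevelopmental",
)

#: Covariate columns of a person-period row, in canonical order.  The
#: indicator and episode-count columns hold *lagged* values.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "sex_male",
    "parental_lithium_response",
    "parental_onset_age",
    "abuse_yes",
    "abuse_missing",
    *INDICATOR_NAMES,
    "major_episodes",
    "minor_episodes",
    "time_input",
)

#: Columns whose values are functions of history strictly before the row's
#: interval (the one-interval lag convention).
LAGGED_COLUMNS: tuple[str, ...] = (*INDICATOR_NAMES, "major_episodes", "minor_episodes")

#: Continuous covariates (candidates for standardization inside models).
CONTINUOUS_COLUMNS: tuple[str, ...] = (
    "parental_onset_age",
    "major_episodes",
    "minor_episodes",
    "time_input",
)

ABUSE_LEVELS = ("yes", "no", "missing")


class CohortError(ValueError):
    """Invalid cohort data or an invalid cohort/scheme combination."""


@dataclass
class Subject:
    """One individual of the cohort.

    Parameters
    ----------
    id : str
        Opaque identifier.
    sex_male, parental_lithium_response : int
        Binary time-fixed covariates (0/1).
    parental_onset_age : float
        Age (years) at which the bipolar parent's illness began.
    abuse : str
        Childhood physical/sexual abuse, one of ``{"yes", "no", "missing"}``;
        "missing" is an explicit level (measure not age-appropriate or not
        yet administered), not a value to be imputed.
    onset_ages : dict
        Indicator name -> age of first onset in years.  Absent key means
        the indicator never onset before the outcome.
    major_episode_ages, minor_episode_ages : list of float
        Ages of antecedent mood episodes.
    outcome_age : float
        Age at diagnosis (``event=1``) or at the last follow-up visit
        (``event=0``).
    event : int
        1 if diagnosed with a major mood disorder, 0 if censored.
    """

    id: str
    sex_male: int
    parental_lithium_response: int
    parental_onset_age: float
    abuse: str
    onset_ages: dict[str, float] = field(default_factory=dict)
    major_episode_ages: list[float] = field(default_factory=list)
    minor_episode_ages: list[float] = field(default_factory=list)
    outcome_age: float = 0.0
    event: int = 0

    def __post_init__(self) -> None:
        if self.outcome_age <= 0:
            raise CohortError(f"subject {self.id!r}: outcome_age must be positive")
        if self.abuse not in ABUSE_LEVELS:
            raise CohortError(
                f"subject {self.id!r}: abuse must be one of {ABUSE_LEVELS}, got {self.abuse!r}"
            )
        if self.event not in (0, 1):
            raise CohortError(f"subject {self.id!r}: event must be 0 or 1")
        unknown = set(self.onset_ages) - set(INDICATOR_NAMES)
        if unknown:
            raise CohortError(f"subject {self.id!r}: unknown indicators {sorted(unknown)}")

    @property
    def abuse_yes(self) -> int:
        return int(self.abuse == "yes")

    @property
    def abuse_missing(self) -> int:
        return int(self.abuse == "missing")


@dataclass(frozen=True)
class IntervalScheme:
    """Partition of the age axis into contiguous half-open intervals.

    Intervals are ``[b[k], b[k+1])`` with equal width; an event at an exact
    boundary belongs to the interval starting there.
    """

    width: float
    min_age: float
    boundaries: tuple[float, ...]

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) - 1

    @property
    def max_age(self) -> float:
        return self.boundaries[-1]

    def interval_index(self, age: float) -> int:
        """Index ``k`` of the interval containing ``age``.

        Raises
        ------
        CohortError
            If ``age`` falls outside ``[min_age, boundaries[-1])``.
        """
        if age < self.min_age or age >= self.boundaries[-1]:
            raise CohortError(
                f"age {age} outside scheme range [{self.min_age}, {self.boundaries[-1]})"
            )
        k = int(math.floor((age - self.min_age) / self.width))
        # guard against float rounding near a boundary
        k = min(max(k, 0), self.n_intervals - 1)
        if age < self.boundaries[k]:
            k -= 1
        elif age >= self.boundaries[k + 1]:
            k += 1
        return k

    def start(self, k: int) -> float:
        return self.boundaries[k]

    def end(self, k: int) -> float:
        return self.boundaries[k + 1]

    def midpoint(self, k: int) -> float:
        return 0.5 * (self.boundaries[k] + self.boundaries[k + 1])

    def intervals(self) -> list[tuple[float, float]]:
        return [(self.boundaries[k], self.boundaries[k + 1]) for k in range(self.n_intervals)]

    def n_full_intervals(self, age: float) -> int:
        """Number of intervals fully contained in ``[min_age, age]``."""
        n = int(math.floor((age - self.min_age) / self.width + 1e-12))
        return min(max(n, 0), self.n_intervals)


def build_interval_scheme(width: float, min_age: float, max_age: float) -> IntervalScheme:
    """Partition ``[min_age, max_age)`` into half-open intervals of ``width`` years.

    The number of intervals is ``ceil((max_age - min_age)/width)``; the last
    interval may overshoot ``max_age``.
    """
    if width <= 0:
        raise CohortError(f"interval width must be positive, got {width}")
    if max_age <= min_age:
        raise CohortError(f"empty age range [{min_age}, {max_age})")
    n = int(math.ceil((max_age - min_age) / width - 1e-12))
    boundaries = tuple(min_age + k * width for k in range(n + 1))
    return IntervalScheme(width=float(width), min_age=float(min_age), boundaries=boundaries)


def lagged_indicator(subject: Subject, name: str, interval_index: int, scheme: IntervalScheme) -> int:
    """Lagged status of a time-varying indicator at interval ``interval_index``.

    Returns 1 iff the indicator's first onset occurred strictly before the
    start of the interval — i.e. the subject's status as of the end of the
    previous interval.  Onsets at or after the subject's outcome never
    contribute (antecedents only).
    """
    if name not in INDICATOR_NAMES:
        raise CohortError(f"unknown indicator {name!r}")
    onset = subject.onset_ages.get(name)
    if onset is None or onset >= subject.outcome_age:
        return 0
    return int(onset < scheme.start(interval_index))


def lagged_cumulative_episodes(
    subject: Subject, kind: str, interval_index: int, scheme: IntervalScheme
) -> int:
    """Lagged cumulative count of antecedent mood episodes.

    Counts episodes of the given kind (``"major"`` or ``"minor"``) with age
    strictly below the start of the interval; episodes at or after the
    outcome are ignored.
    """
    if kind == "major":
        ages = subject.major_episode_ages
    elif kind == "minor":
        ages = subject.minor_episode_ages
    else:
        raise CohortError(f"episode kind must be 'major' or 'minor', got {kind!r}")
    start = scheme.start(interval_index)
    return sum(1 for a in ages if a < start and a < subject.outcome_age)


def survival_from_hazards(hazards: Sequence[float]) -> np.ndarray:
    """Survival curve from discrete conditional hazards.

    ``S(k) = prod_{j<=k} (1 - h_j)``: the probability of remaining
    event-free through interval ``k`` given the per-interval conditional
    event probabilities.  Non-increasing and bounded in [0, 1].
    """
    h = np.asarray(hazards, dtype=float)
    if h.size == 0:
        return h.copy()
    if np.any(np.isnan(h)) or np.any(h < 0) or np.any(h > 1):
        raise CohortError("hazards must lie in [0, 1]")
    return np.cumprod(1.0 - h)


@dataclass
class PersonPeriodTable:
    """Person-period expansion of a cohort under an interval scheme.

    ``frame`` holds one row per subject per at-risk interval with columns
    ``subject_id, interval_index, interval_start, interval_end,
    event_in_interval`` followed by :data:`COVARIATE_COLUMNS`.
    """

    frame: pd.DataFrame
    scheme: IntervalScheme
    covariate_columns: tuple[str, ...] = COVARIATE_COLUMNS
    lagged_columns: tuple[str, ...] = LAGGED_COLUMNS

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    def covariates(self) -> pd.DataFrame:
        return self.frame[list(self.covariate_columns)]

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV plus a JSON sidecar recording the scheme."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        sidecar = {
            "scheme": {
                "width": self.scheme.width,
                "min_age": self.scheme.min_age,
                "boundaries": list(self.scheme.boundaries),
            },
            "covariate_columns": list(self.covariate_columns),
            "lagged_columns": list(self.lagged_columns),
            "lag_convention": "lagged columns use history strictly before interval_start",
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PersonPeriodTable":
        path = Path(path)
        frame = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        scheme = IntervalScheme(
            width=meta["scheme"]["width"],
            min_age=meta["scheme"]["min_age"],
            boundaries=tuple(meta["scheme"]["boundaries"]),
        )
        return cls(
            frame=frame,
            scheme=scheme,
            covariate_columns=tuple(meta["covariate_columns"]),
            lagged_columns=tuple(meta["lagged_columns"]),
        )


def n_at_risk_intervals(subject: Subject, scheme: IntervalScheme) -> int:
    """Number of person-period rows the subject contributes.

    An event subject is at risk through the interval containing the event.
    A censored subject is at risk only in intervals fully survived
    (``interval_end <= censoring age``): a partially observed final interval
    contributes no row.
    """
    if subject.outcome_age < scheme.min_age:
        raise CohortError(
            f"subject {subject.id!r}: outcome_age {subject.outcome_age} below "
            f"scheme min_age {scheme.min_age}"
        )
    if subject.event:
        if subject.outcome_age >= scheme.max_age:
            raise CohortError(
                f"subject {subject.id!r}: event age {subject.outcome_age} beyond "
                f"scheme max_age {scheme.max_age}"
            )
        return scheme.interval_index(subject.outcome_age) + 1
    return scheme.n_full_intervals(subject.outcome_age)


def subject_covariate_row(subject: Subject, k: int, scheme: IntervalScheme) -> dict[str, float]:
    """Covariate vector of subject at interval ``k`` under the lag convention."""
    row: dict[str, float] = {
        "sex_male": subject.sex_male,
        "parental_lithium_response": subject.parental_lithium_response,
        "parental_onset_age": subject.parental_onset_age,
        "abuse_yes": subject.abuse_yes,
        "abuse_missing": subject.abuse_missing,
    }
    for name in INDICATOR_NAMES:
        row[name] = lagged_indicator(subject, name, k, scheme)
    row["major_episodes"] = lagged_cumulative_episodes(subject, "major", k, scheme)
    row["minor_episodes"] = lagged_cumulative_episodes(subject, "minor", k, scheme)
    row["time_input"] = scheme.midpoint(k)
    return row


def expand_to_person_periods(
    cohort: Iterable[Subject], scheme: IntervalScheme
) -> PersonPeriodTable:
    """Expand a cohort into the person-period table both models are fitted on.

    A subject with an event at age ``t`` contributes one row per interval up
    to and including the interval containing ``t``, with
    ``event_in_interval = 1`` only in that last row.  A censored subject
    contributes rows only for fully survived intervals, all with
    ``event_in_interval = 0``.
    """
    records: list[dict[str, float]] = []
    for subject in cohort:
        n_rows = n_at_risk_intervals(subject, scheme)
        event_k = n_rows - 1 if subject.event else -1
        for k in range(n_rows):
            rec: dict[str, float] = {
                "subject_id": subject.id,
                "interval_index": k,
                "interval_start": scheme.start(k),
                "interval_end": scheme.end(k),
                "event_in_interval": int(k == event_k),
            }
            rec.update(subject_covariate_row(subject, k, scheme))
            records.append(rec)
    columns = [
        "subject_id",
        "interval_index",
        "interval_start",
        "interval_end",
        "event_in_interval",
        *COVARIATE_COLUMNS,
    ]
    frame = pd.DataFrame.from_records(records, columns=columns)
    return PersonPeriodTable(frame=frame, scheme=scheme)


# ---------------------------------------------------------------------------
# CSV interchange (three-table layout: subjects / onsets / episodes)
# ---------------------------------------------------------------------------

def read_cohort_csv(
    subjects_path: str | Path,
    onsets_path: str | Path | None = None,
    episodes_path: str | Path | None = None,
) -> list[Subject]:
    """Read a cohort from the three-table CSV layout.

    ``subjects.csv``: id, sex_male, parental_lithium_response,
    parental_onset_age, abuse, outcome_age, event.
    ``onsets.csv``: id, indicator_name, onset_age (absent row = never onset).
    ``episodes.csv``: id, kind, episode_age.
    """
    subjects = pd.read_csv(subjects_path, dtype={"id": str})
    onsets = (
        pd.read_csv(onsets_path, dtype={"id": str})
        if onsets_path is not None
        else pd.DataFrame(columns=["id", "indicator_name", "onset_age"])
    )
    episodes = (
        pd.read_csv(episodes_path, dtype={"id": str})
        if episodes_path is not None
        else pd.DataFrame(columns=["id", "kind", "episode_age"])
    )
    onset_map: dict[str, dict[str, float]] = {}
    for rec in onsets.itertuples(index=False):
        onset_map.setdefault(rec.id, {})[rec.indicator_name] = float(rec.onset_age)
    episode_map: dict[str, dict[str, list[float]]] = {}
    for rec in episodes.itertuples(index=False):
        episode_map.setdefault(rec.id, {"major": [], "minor": []})[rec.kind].append(
            float(rec.episode_age)
        )
    cohort = []
    for rec in subjects.itertuples(index=False):
        eps = episode_map.get(rec.id, {"major": [], "minor": []})
        cohort.append(
            Subject(
                id=rec.id,
                sex_male=int(rec.sex_male),
                parental_lithium_response=int(rec.parental_lithium_response),
                parental_onset_age=float(rec.parental_onset_age),
                abuse=str(rec.abuse),
                onset_ages=onset_map.get(rec.id, {}),
                major_episode_ages=sorted(eps["major"]),
                minor_episode_ages=sorted(eps["minor"]),
                outcome_age=float(rec.outcome_age),
                event=int(rec.event),
            )
        )
    return cohort


def write_cohort_csv(cohort: Sequence[Subject], out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort in the three-table CSV layout; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subj_rows, onset_rows, episode_rows = [], [], []
    for s in cohort:
        subj_rows.append(
            {
                "id": s.id,
                "sex_male": s.sex_male,
                "parental_lithium_response": s.parental_lithium_response,
                "parental_onset_age": s.parental_onset_age,
                "abuse": s.abuse,
                "outcome_age": s.outcome_age,
                "event": s.event,
            }
        )
        for name, age in sorted(s.onset_ages.items()):
            onset_rows.append({"id": s.id, "indicator_name": name, "onset_age": age})
        for age in s.major_episode_ages:
            episode_rows.append({"id": s.id, "kind": "major", "episode_age": age})
        for age in s.minor_episode_ages:
            episode_rows.append({"id": s.id, "kind": "minor", "episode_age": age})
    paths = {
        "subjects": out_dir / "subjects.csv",
        "onsets": out_dir / "onsets.csv",
        "episodes": out_dir / "episodes.csv",
    }
    pd.DataFrame(subj_rows, columns=list(subj_rows[0]) if subj_rows else
                 ["id", "sex_male", "parental_lithium_response", "parental_onset_age",
                  "abuse", "outcome_age", "event"]).to_csv(paths["subjects"], index=False)
    pd.DataFrame(onset_rows, columns=["id", "indicator_name", "onset_age"]).to_csv(
        paths["onsets"], index=False
    )
    pd.DataFrame(episode_rows, columns=["id", "kind", "episode_age"]).to_csv(
        paths["episodes"], index=False
    )
    return paths
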