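"""Reading, validation and design construction for dyadic behavior data.

The expected inputs are two plain CSV tables:

* a **roster** (one row per child): ``child_id, sex, household_id,
  age_at_study_start``
* an **observations** table (one row per directed dyadic event):
  ``event_id, episode_id, date, initiator_id, recipient_id, behavior_code,
  initiator_age, recipient_age``

``build_design`` turns these into the index/covariate arrays consumed by the
multinomial likelihood: event-level category index, initiator/recipient
individual and household indices, standardized-age covariate blocks, and the
same-household indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorTaxonomy",
    "ChildRecord",
    "ObservationEvent",
    "ModelData",
    "SchemaError",
    "load_roster",
    "load_observations",
    "write_roster",
    "write_observations",
    "build_design",
]

#: the 19 proactive behavior categories, in their conventional order; the
#: last one (ownership assertion) is the reference category of the model.
DEFAULT_BEHAVIOR_LABELS = (
    "comforting",
    "dominating",
    "helping",
    "leading",
    "dirty looks",
    "physical aggression",
    "requesting for access",
    "requesting for comfort",
    "requesting for help",
    "requesting for sharing",
    "scolding",
    "sharing",
    "supporting opinions",
    "taking",
    "tattling",
    "teasing (aggressive)",
    "teasing (playful)",
    "verbal aggression",
    "ownership assertion",
)


class SchemaError(ValueError):
    """A required column is missing or a table has an invalid layout."""


@dataclass(frozen=True)
class BehaviorTaxonomy:
    """Ordered behavior categories with a designated reference category.

    ``reference_index`` is 1-based (category codes in data files run 1..K);
    by default the last category is the reference, whose log-odds contrast
    is pinned at zero in the model.
    """

    labels: tuple[str, ...] = DEFAULT_BEHAVIOR_LABELS
    reference_index: int = len(DEFAULT_BEHAVIOR_LABELS)

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("taxonomy needs at least two categories")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("taxonomy labels must be unique")
        if not (1 <= self.reference_index <= len(self.labels)):
            raise ValueError("reference_index out of range")

    @property
    def K(self) -> int:
        return len(self.labels)

    @classmethod
    def default(cls) -> "BehaviorTaxonomy":
        return cls()

    @classmethod
    def reduced(cls, K: int) -> "BehaviorTaxonomy":
        """A K-category taxonomy for desk-scale work: the first K-1 default
        labels plus the reference category."""
        if not (2 <= K <= len(DEFAULT_BEHAVIOR_LABELS)):
            raise ValueError("K must be in 2..%d" % len(DEFAULT_BEHAVIOR_LABELS))
        labels = DEFAULT_BEHAVIOR_LABELS[: K - 1] + (DEFAULT_BEHAVIOR_LABELS[-1],)
        return cls(labels=labels, reference_index=K)


@dataclass(frozen=True)
class ChildRecord:
    child_id: str
    sex: str  # "female" | "male"
    household_id: str
    age_at_study_start: float

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex token {self.sex!r} for child {self.child_id}")
        if not str(self.household_id):
            raise ValueError(f"empty household_id for child {self.child_id}")


@dataclass(frozen=True)
class ObservationEvent:
    event_id: int
    episode_id: int
    date: str  # ISO-8601; recorded but not used by the likelihood
    initiator_id: str
    recipient_id: str
    behavior_code: int  # 1..K
    initiator_age: float
    recipient_age: float

    def __post_init__(self):
        if self.initiator_id == self.recipient_id:
            raise ValueError(
                f"event {self.event_id}: initiator equals recipient ({self.initiator_id})"
            )
        for role, age in (("initiator", self.initiator_age), ("recipient", self.recipient_age)):
            if not (0.0 <= age < 13.0):
                raise ValueError(f"event {self.event_id}: {role} age {age} outside [0, 13)")


@dataclass
class ModelData:
    """Index-coded events with standardized covariates, ready for the model.

    Attributes use 0-based indices internally. ``X_I``/``X_R`` columns are
    (standardized age, sex code, standardized age x sex); sex is coded
    female=0, male=1 and the household flag 0=different household, so the
    intercepts are the female/female, different-household, mean-age baseline.
    """

    y: np.ndarray  # (N,) category index 0..K-1
    i_idx: np.ndarray  # (N,) initiator individual index
    j_idx: np.ndarray  # (N,) recipient individual index
    hi_idx: np.ndarray  # (N,) initiator household index
    hj_idx: np.ndarray  # (N,) recipient household index
    X_I: np.ndarray  # (N, 3)
    X_R: np.ndarray  # (N, 3)
    x_H: np.ndarray  # (N,) same-household indicator {0,1}
    scaler: dict  # column -> (mean, sd) on the natural age scale
    taxonomy: BehaviorTaxonomy = field(default_factory=BehaviorTaxonomy)
    child_ids: tuple[str, ...] = ()
    household_ids: tuple[str, ...] = ()
    child_household: np.ndarray | None = None  # (I,) household index per child

    @property
    def n_events(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_individuals(self) -> int:
        return len(self.child_ids)

    @property
    def n_households(self) -> int:
        return len(self.household_ids)

    @property
    def K(self) -> int:
        return self.taxonomy.K

    def covariate_names(self) -> tuple[str, ...]:
        return ("age_std", "sex", "age_std_x_sex")


_ROSTER_COLS = ("child_id", "sex", "household_id", "age_at_study_start")
_OBS_COLS = (
    "event_id",
    "episode_id",
    "date",
    "initiator_id",
    "recipient_id",
    "behavior_code",
    "initiator_age",
    "recipient_age",
)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def load_roster(path) -> list[ChildRecord]:
    """Read and validate a roster CSV; duplicate child ids are rejected."""
    df = pd.read_csv(path, dtype={"child_id": str, "household_id": str})
    _require_columns(df, _ROSTER_COLS, "roster")
    dup = df["child_id"][df["child_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate child_id in roster: {dup.iloc[0]}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                ChildRecord(
                    child_id=str(row.child_id),
                    sex=str(row.sex),
                    household_id=str(row.household_id),
                    age_at_study_start=float(row.age_at_study_start),
                )
            )
        except ValueError as err:
            raise ValueError(f"roster row {row_no}: {err}") from err
    return records


def load_observations(path, taxonomy: BehaviorTaxonomy, roster: Sequence[ChildRecord]) -> list[ObservationEvent]:
    """Read and validate an observations CSV against a roster and taxonomy."""
    df = pd.read_csv(path, dtype={"initiator_id": str, "recipient_id": str, "date": str})
    _require_columns(df, _OBS_COLS, "observations table")
    known = {r.child_id for r in roster}
    events = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        code = int(row.behavior_code)
        if not (1 <= code <= taxonomy.K):
            raise ValueError(
                f"observations row {row_no}: behavior_code {code} outside 1..{taxonomy.K}"
            )
        for role, cid in (("initiator", str(row.initiator_id)), ("recipient", str(row.recipient_id))):
            if cid not in known:
                raise ValueError(f"observations row {row_no}: unknown {role} id {cid!r}")
        try:
            events.append(
                ObservationEvent(
                    event_id=int(row.event_id),
                    episode_id=int(row.episode_id),
                    date=str(row.date),
                    initiator_id=str(row.initiator_id),
                    recipient_id=str(row.recipient_id),
                    behavior_code=code,
                    initiator_age=float(row.initiator_age),
                    recipient_age=float(row.recipient_age),
                )
            )
        except ValueError as err:
            raise ValueError(f"observations row {row_no}: {err}") from err
    return events


def write_roster(path, roster: Sequence[ChildRecord]) -> None:
    pd.DataFrame(
        [
            {
                "child_id": r.child_id,
                "sex": r.sex,
                "household_id": r.household_id,
                "age_at_study_start": r.age_at_study_start,
            }
            for r in roster
        ],
        columns=list(_ROSTER_COLS),
    ).to_csv(path, index=False)


def write_observations(path, events: Sequence[ObservationEvent]) -> None:
    pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "episode_id": e.episode_id,
                "date": e.date,
                "initiator_id": e.initiator_id,
                "recipient_id": e.recipient_id,
                "behavior_code": e.behavior_code,
                "initiator_age": e.initiator_age,
                "recipient_age": e.recipient_age,
            }
            for e in events
        ],
        columns=list(_OBS_COLS),
    ).to_csv(path, index=False)


def standardize(x: np.ndarray, mean: float | None = None, sd: float | None = None):
    """Center/scale a column; returns (column, mean, sd).

    When ``mean``/``sd`` come from a stored scaler the same transform is
    reapplied bit-for-bit (prediction scenarios rely on this).
    """
    x = np.asarray(x, dtype=float)
    if mean is None:
        mean = float(np.mean(x))
    if sd is None:
        sd = float(np.std(x, ddof=0))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("zero age variance: cannot standardize")
    return (x - mean) / sd, mean, sd


def build_design(
    events: Sequence[ObservationEvent],
    roster: Sequence[ChildRecord],
    taxonomy: BehaviorTaxonomy | None = None,
    scaler: dict | None = None,
) -> ModelData:
    """Assemble ``ModelData`` from validated events and roster.

    Initiator and recipient ages are standardized separately, each by its
    own mean/SD over the analyzed events (unless a stored ``scaler`` is
    supplied, in which case it is reapplied verbatim).
    """
    taxonomy = taxonomy or BehaviorTaxonomy()
    child_ids = tuple(r.child_id for r in roster)
    child_pos = {cid: i for i, cid in enumerate(child_ids)}
    household_ids = tuple(dict.fromkeys(r.household_id for r in roster))
    house_pos = {hid: i for i, hid in enumerate(household_ids)}
    child_house = np.array([house_pos[r.household_id] for r in roster], dtype=np.int64)
    sex_code = {r.child_id: (0.0 if r.sex == "female" else 1.0) for r in roster}

    n = len(events)
    y = np.empty(n, dtype=np.int64)
    i_idx = np.empty(n, dtype=np.int64)
    j_idx = np.empty(n, dtype=np.int64)
    age_i = np.empty(n)
    age_j = np.empty(n)
    sex_i = np.empty(n)
    sex_j = np.empty(n)
    for m, e in enumerate(events):
        y[m] = e.behavior_code - 1
        i_idx[m] = child_pos[e.initiator_id]
        j_idx[m] = child_pos[e.recipient_id]
        age_i[m] = e.initiator_age
        age_j[m] = e.recipient_age
        sex_i[m] = sex_code[e.initiator_id]
        sex_j[m] = sex_code[e.recipient_id]

    scaler = dict(scaler) if scaler else {}
    zi, mi, si = standardize(age_i, *(scaler.get("initiator_age") or (None, None)))
    zj, mj, sj = standardize(age_j, *(scaler.get("recipient_age") or (None, None)))
    scaler["initiator_age"] = (mi, si)
    scaler["recipient_age"] = (mj, sj)
    scaler.setdefault("initiator_age_range", (float(age_i.min()), float(age_i.max())))
    scaler.setdefault("recipient_age_range", (float(age_j.min()), float(age_j.max())))

    X_I = np.column_stack([zi, sex_i, zi * sex_i])
    X_R = np.column_stack([zj, sex_j, zj * sex_j])
    hi_idx = child_house[i_idx]
    hj_idx = child_house[j_idx]
    x_H = (hi_idx == hj_idx).astype(float)

    return ModelData(
        y=y,
        i_idx=i_idx,
        j_idx=j_idx,
        hi_idx=hi_idx,
        hj_idx=hj_idx,
        X_I=X_I,
        X_R=X_R,
        x_H=x_H,
        scaler=scaler,
        taxonomy=taxonomy,
        child_ids=child_ids,
        household_ids=household_ids,
        child_household=child_house,
    )
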