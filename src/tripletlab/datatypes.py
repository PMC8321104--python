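"""Core domain types for the triplet-annotation experiment.

The experiment presents each annotator with *triplets* of clinical records:
a left anchor A with hepatic steatosis, a right anchor C without, and a
middle record B whose class is hidden.  The annotator assigns B to the more
similar anchor and states an ordinal uncertainty; task duration and
electrodermal activity (EDA) are recorded alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

#: The ten variables shown to annotators, in canonical column order.
ANNOTATION_VARIABLES: tuple[str, ...] = (
    "age",
    "alat_s",
    "alcohol_g_day",
    "beta_blocker",
    "crp_hs",
    "diabetes",
    "hypertonia",
    "ldlch",
    "sex",
    "smoke_status",
)

#: Variables compared by range-normalised absolute difference.
CONTINUOUS_VARIABLES: tuple[str, ...] = (
    "age",
    "alat_s",
    "alcohol_g_day",
    "crp_hs",
    "ldlch",
)

#: Variables compared by 0/1 overlap.
NOMINAL_VARIABLES: tuple[str, ...] = (
    "beta_blocker",
    "diabetes",
    "hypertonia",
    "sex",
    "smoke_status",
)

SMOKE_LEVELS: tuple[str, ...] = ("never", "former", "current")
SEX_LEVELS: tuple[str, ...] = ("female", "male")

ChoiceLabel = Literal["A", "C"]


@dataclass(frozen=True)
class CohortRecord:
    """One study individual: ten annotation variables plus the hidden outcome.

    ``livfat_per`` (MRI liver-fat fraction, %) and ``stea`` (hepatic
    steatosis, 0/1) define the class and are never shown to annotators.
    """

    id: str
    age: float            # years
    alat_s: float         # alanine aminotransferase, ukatal/l
    alcohol_g_day: float  # g/day
    beta_blocker: int     # 0/1
    crp_hs: float         # high-sensitive CRP, mg/l
    diabetes: int         # 0/1
    hypertonia: int       # 0/1
    ldlch: float          # LDL cholesterol, mmol/l
    sex: str              # female/male
    smoke_status: str     # never/former/current
    livfat_per: float     # % liver fat
    stea: int             # 0/1

    def __post_init__(self) -> None:
        if self.livfat_per < 0:
            raise ValueError(f"livfat_per must be >= 0, got {self.livfat_per}")
        if self.stea not in (0, 1):
            raise ValueError(f"stea must be 0 or 1, got {self.stea}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if self.smoke_status not in SMOKE_LEVELS:
            raise ValueError(
                f"smoke_status must be one of {SMOKE_LEVELS}, got {self.smoke_status!r}"
            )
        for name in ("beta_blocker", "diabetes", "hypertonia"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {getattr(self, name)}")

    def features(self) -> dict[str, float | str]:
        """The ten annotation variables as a mapping (the similarity space)."""
        return {name: getattr(self, name) for name in ANNOTATION_VARIABLES}


@dataclass(frozen=True)
class Triplet:
    """An annotation task: anchors A (steatosis) and C (healthy) plus hidden B.

    ``true_label`` is the anchor sharing B's class: A iff ``record_B.stea == 1``.
    """

    triplet_id: int
    record_A: CohortRecord
    record_B: CohortRecord
    record_C: CohortRecord
    true_label: ChoiceLabel

    def __post_init__(self) -> None:
        if self.record_A.stea != 1:
            raise ValueError("record_A must have stea = 1")
        if self.record_C.stea != 0:
            raise ValueError("record_C must have stea = 0")
        expected = "A" if self.record_B.stea == 1 else "C"
        if self.true_label != expected:
            raise ValueError(
                f"true_label {self.true_label!r} inconsistent with record_B.stea "
                f"= {self.record_B.stea}"
            )

    @property
    def records(self) -> tuple[CohortRecord, CohortRecord, CohortRecord]:
        return (self.record_A, self.record_B, self.record_C)


@dataclass(frozen=True)
class AnnotationEvent:
    """One (annotator, triplet) observation."""

    annotator_id: str
    triplet_id: int
    choice: ChoiceLabel
    stated_u: int              # 0 very certain ... 3 very uncertain
    duration_s: float          # seconds
    eda_mean: float | None = None  # mean electrodermal activity, uS

    def __post_init__(self) -> None:
        if self.choice not in ("A", "C"):
            raise ValueError(f"choice must be 'A' or 'C', got {self.choice!r}")
        if self.stated_u not in (0, 1, 2, 3):
            raise ValueError(f"stated_u must be in 0..3, got {self.stated_u}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.eda_mean is not None and self.eda_mean < 0:
            raise ValueError(f"eda_mean must be >= 0, got {self.eda_mean}")


class AnnotationMatrix:
    """A complete annotator x triplet grid of events plus the truth mapping.

    Completeness (exactly one event per pair) is enforced at construction.
    """

    def __init__(
        self,
        events: Iterable[AnnotationEvent],
        truth: Mapping[int, ChoiceLabel],
    ) -> None:
        events = list(events)
        if not events:
            raise ValueError("no annotation events supplied")
        self.annotators: list[str] = sorted({e.annotator_id for e in events})
        self.triplets: list[int] = sorted({e.triplet_id for e in events})
        self.truth: dict[int, ChoiceLabel] = dict(truth)

        missing_truth = [t for t in self.triplets if t not in self.truth]
        if missing_truth:
            raise ValueError(f"truth missing for triplets: {missing_truth}")

        seen: dict[tuple[str, int], AnnotationEvent] = {}
        for e in events:
            key = (e.annotator_id, e.triplet_id)
            if key in seen:
                raise ValueError(f"duplicate annotation event for {key}")
            seen[key] = e
        expected = {(a, t) for a in self.annotators for t in self.triplets}
        missing = sorted(expected - set(seen))
        if missing:
            raise ValueError(
                f"incomplete annotation grid; {len(missing)} missing pairs, "
                f"first few: {missing[:5]}"
            )
        self._events = seen

    @property
    def n(self) -> int:
        """Number of raters."""
        return len(self.annotators)

    @property
    def events(self) -> list[AnnotationEvent]:
        return [self._events[(a, t)] for a in self.annotators for t in self.triplets]

    def event(self, annotator_id: str, triplet_id: int) -> AnnotationEvent:
        return self._events[(annotator_id, triplet_id)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame, one row per event, with truth and correctness."""
        rows = []
        for e in self.events:
            truth = self.truth[e.triplet_id]
            rows.append(
                {
                    "annotator_id": e.annotator_id,
                    "triplet_id": e.triplet_id,
                    "choice": e.choice,
                    "stated_u": e.stated_u,
                    "duration_s": e.duration_s,
                    "eda_mean": e.eda_mean,
                    "true_label": truth,
                    "correct": int(e.choice == truth),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class EDATimeSeries:
    """Raw electrodermal recording of one annotator over the whole experiment."""

    annotator_id: str
    timestamps: np.ndarray      # seconds, strictly increasing
    values: np.ndarray          # uS, >= 0
    experiment_start: float = field(default=None)  # type: ignore[assignment]
    experiment_end: float = field(default=None)    # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if self.timestamps.size == 0:
            raise ValueError("empty EDA series")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("EDA values must be >= 0")
        if self.experiment_start is None:
            self.experiment_start = float(self.timestamps[0])
        if self.experiment_end is None:
            self.experiment_end = float(self.timestamps[-1])


@dataclass(frozen=True)
class GroupAssignment:
    """Membership of one cohort record in the six-group triplet scheme.

    Groups 1-3 hold healthy records (stea = 0), groups 4-6 steatosis
    records; members are numbered 1-15 within each group and matched by
    number across groups to form triplets.
    """

    group: int
    member_number: int
    record_id: str

    def __post_init__(self) -> None:
        if self.group not in range(1, 7):
            raise ValueError(f"group must be in 1..6, got {self.group}")
        if self.member_number not in range(1, 16):
            raise ValueError(f"member_number must be in 1..15, got {self.member_number}")
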