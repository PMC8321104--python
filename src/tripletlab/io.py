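"""CSV readers/writers and loaders for the packaged reference tables.

All files are comma-separated UTF-8 with a mandatory header row and "."
decimal separator.  Binary fields are serialized as 0/1; "yes"/"no" are
accepted on read.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .datatypes import (
    ANNOTATION_VARIABLES,
    CONTINUOUS_VARIABLES,
    AnnotationEvent,
    AnnotationMatrix,
    CohortRecord,
    EDATimeSeries,
)

COHORT_COLUMNS = list(("id",) + ANNOTATION_VARIABLES + ("livfat_per", "stea"))
ANNOTATION_COLUMNS = [
    "annotator_id",
    "triplet_id",
    "choice",
    "stated_u",
    "duration_s",
    "eda_mean",
]
EDA_COLUMNS = ["annotator_id", "timestamp_s", "eda_uS"]

_BINARY_ALIASES = {"yes": 1, "no": 0, "1": 1, "0": 0, 1: 1, 0: 0}

FIXTURE_NAMES = ("table4", "table7", "table8")


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing column(s): {', '.join(missing)}")


def _parse_binary(value, column: str, row: int) -> int:
    key = value.strip().lower() if isinstance(value, str) else value
    try:
        return _BINARY_ALIASES[key]
    except (KeyError, TypeError):
        raise SchemaError(
            f"column {column!r}, row {row}: expected 0/1 or yes/no, got {value!r}"
        ) from None


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a cohort table (one row per individual, Table-1 schema)."""
    df = pd.read_csv(path, dtype={"id": str})
    _require_columns(df, COHORT_COLUMNS, "cohort")
    records = []
    for i, row in df.iterrows():
        kwargs: dict = {"id": str(row["id"])}
        for col in CONTINUOUS_VARIABLES + ("livfat_per",):
            try:
                kwargs[col] = float(row[col])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"column {col!r}, row {i}: non-numeric value {row[col]!r}"
                ) from None
        for col in ("beta_blocker", "diabetes", "hypertonia", "stea"):
            kwargs[col] = _parse_binary(row[col], col, i)
        kwargs["sex"] = str(row["sex"]).strip().lower()
        kwargs["smoke_status"] = str(row["smoke_status"]).strip().lower()
        records.append(CohortRecord(**kwargs))
    return records


def write_cohort(records: Iterable[CohortRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"id": r.id, **r.features(), "livfat_per": r.livfat_per, "stea": r.stea}
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_annotations(path: str | Path, truth: dict[int, str] | None = None) -> AnnotationMatrix:
    """Read an annotation-event table into a complete AnnotationMatrix.

    The file needs one row per (annotator, triplet) with choice, stated_u
    and duration_s; eda_mean is optional (empty cells allowed).  If the
    file carries a ``true_label`` column the truth mapping is taken from
    it, otherwise it must be supplied.
    """
    df = pd.read_csv(path, dtype={"annotator_id": str})
    _require_columns(df, [c for c in ANNOTATION_COLUMNS if c != "eda_mean"], "annotations")
    events = []
    for i, row in df.iterrows():
        stated = row["stated_u"]
        try:
            stated = int(stated)
        except (TypeError, ValueError):
            raise SchemaError(f"row {i}: non-integer stated_u {row['stated_u']!r}") from None
        eda = row.get("eda_mean")
        eda = None if pd.isna(eda) else float(eda)
        events.append(
            AnnotationEvent(
                annotator_id=str(row["annotator_id"]),
                triplet_id=int(row["triplet_id"]),
                choice=str(row["choice"]).strip().upper(),
                stated_u=stated,
                duration_s=float(row["duration_s"]),
                eda_mean=eda,
            )
        )
    if truth is None:
        if "true_label" not in df.columns:
            raise SchemaError(
                "annotations file has no 'true_label' column and no truth mapping "
                "was supplied"
            )
        truth = {
            int(t): str(v).strip().upper()
            for t, v in df.groupby("triplet_id")["true_label"].first().items()
        }
    return AnnotationMatrix(events, truth)


def write_annotations(matrix: AnnotationMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.to_csv(path, index=False)


def read_eda_series(path: str | Path) -> list[EDATimeSeries]:
    """Read per-annotator EDA recordings (annotator_id, timestamp_s, eda_uS)."""
    df = pd.read_csv(path, dtype={"annotator_id": str})
    _require_columns(df, EDA_COLUMNS, "EDA")
    out = []
    for annotator_id, grp in df.groupby("annotator_id", sort=True):
        grp = grp.sort_values("timestamp_s")
        out.append(
            EDATimeSeries(
                annotator_id=str(annotator_id),
                timestamps=grp["timestamp_s"].to_numpy(float),
                values=grp["eda_uS"].to_numpy(float),
            )
        )
    return out


def write_eda_series(series: Iterable[EDATimeSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "annotator_id": s.annotator_id,
                    "timestamp_s": s.timestamps,
                    "eda_uS": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables.

    ``table4`` — 2x2 counts of binary stated uncertainty vs correctness over
    the 870 annotations.  ``table7`` — per-triplet correct label, voteFor
    ratios, agreement flags at tau = 2/3 and 3/4, and the triplet
    correctness ratio.  ``table8`` — per-triplet mean stated uncertainty,
    machine-annotator uncertainty, and both correctness columns.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = importlib.resources.files("tripletlab.fixtures") / f"{name}.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def load_table4_counts() -> "pd.DataFrame":
    """The 2x2 binary-uncertainty x correctness table as a 2x2 int frame."""
    df = load_fixture("table4").set_index("binary_uncertainty")
    return df[["correct", "incorrect"]].astype(int)
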