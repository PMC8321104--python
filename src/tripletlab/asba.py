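"""Artificial Similarity-Based Annotator (ASBA).

A deterministic 1-nearest-neighbour annotator over the Heterogeneous
Euclidean-Overlap Metric (HEOM): nominal variables contribute a 0/1
overlap term, continuous ones a range-normalised absolute difference,
aggregated as sqrt(sum of squares).  Its uncertainty for a triplet is the
ratio of the smaller to the larger anchor distance, in [0, 1]; 0 means one
anchor is an exact match, 1 means both anchors are equally far.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .datatypes import (
    ANNOTATION_VARIABLES,
    CONTINUOUS_VARIABLES,
    NOMINAL_VARIABLES,
    CohortRecord,
    Triplet,
)

logger = logging.getLogger(__name__)

DEFAULT_TAU_ASBA = 0.5


@dataclass(frozen=True)
class FeatureSchema:
    """Variable kinds and continuous normalisation ranges for HEOM.

    Ranges are fitted on a stated reference set — conventionally the 90
    records of the 30 triplets — and fix the [min, max] used to normalise
    each continuous variable.
    """

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = [v for v in CONTINUOUS_VARIABLES if v not in self.ranges]
        if missing:
            raise ValueError(f"schema missing range(s) for: {missing}")
        for var, (lo, hi) in self.ranges.items():
            if hi < lo:
                raise ValueError(f"range for {var!r} has max < min: ({lo}, {hi})")

    @classmethod
    def fit(cls, records: Iterable[CohortRecord]) -> "FeatureSchema":
        """Compute per-variable min/max over a reference record set."""
        records = list(records)
        if not records:
            raise ValueError("cannot fit a schema on an empty reference set")
        ranges = {}
        for var in CONTINUOUS_VARIABLES:
            values = [float(getattr(r, var)) for r in records]
            ranges[var] = (min(values), max(values))
        return cls(ranges=ranges)

    @classmethod
    def from_triplets(cls, triplets: Sequence[Triplet]) -> "FeatureSchema":
        return cls.fit(r for t in triplets for r in t.records)


def heom(a: CohortRecord, b: CohortRecord, schema: FeatureSchema) -> float:
    """HEOM distance between two records over the ten annotation variables.

    Per-variable distances lie in [0, 1] (continuous differences are
    clipped), so the aggregate is bounded by sqrt(10).  A zero-width range
    yields distance 0 for that variable: a constant variable carries no
    information.
    """
    total = 0.0
    for var in ANNOTATION_VARIABLES:
        if var in NOMINAL_VARIABLES:
            d = 0.0 if getattr(a, var) == getattr(b, var) else 1.0
        else:
            lo, hi = schema.ranges[var]
            width = hi - lo
            if width == 0:
                d = 0.0
            else:
                d = min(abs(float(getattr(a, var)) - float(getattr(b, var))) / width, 1.0)
        total += d * d
    return math.sqrt(total)


@dataclass(frozen=True)
class ASBAResult:
    """Machine annotation of one triplet."""

    triplet_id: int
    dist_AB: float
    dist_CB: float
    choice: str
    asba_u: float
    asba_u_aggregated: int
    asba_u_binary: int
    correct: int | None = None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def discretize_asba_u(u: float, tau_asba: float = DEFAULT_TAU_ASBA) -> tuple[int, int]:
    """Map a raw uncertainty in [0, 1] to its 4-level and binary forms.

    Aggregated level = round-half-up(3 u) in {0..3}; binary = 0 (certain)
    iff u < tau_asba, else 1 (uncertain).
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"uncertainty must be in [0, 1], got {u}")
    if not 0.0 < tau_asba <= 1.0:
        raise ValueError(f"tau_asba must be in (0, 1], got {tau_asba}")
    aggregated = _round_half_up(3.0 * u)
    binary = 0 if u < tau_asba else 1
    return aggregated, binary


def asba_annotate(
    t: Triplet, schema: FeatureSchema, tau_asba: float = DEFAULT_TAU_ASBA
) -> ASBAResult:
    """Annotate one triplet: nearest anchor of B plus the uncertainty score.

    Ties (equal distances) resolve deterministically to C with a logged
    warning; if both distances are zero the uncertainty is maximal (1).
    """
    dist_ab = heom(t.record_A, t.record_B, schema)
    dist_cb = heom(t.record_C, t.record_B, schema)
    if dist_ab == dist_cb:
        logger.warning(
            "triplet %s: equal anchor distances (%.6g); choosing C by convention",
            t.triplet_id,
            dist_ab,
        )
        choice = "C"
    else:
        choice = "A" if dist_ab < dist_cb else "C"
    largest = max(dist_ab, dist_cb)
    asba_u = 1.0 if largest == 0 else min(dist_ab, dist_cb) / largest
    aggregated, binary = discretize_asba_u(asba_u, tau_asba)
    return ASBAResult(
        triplet_id=t.triplet_id,
        dist_AB=dist_ab,
        dist_CB=dist_cb,
        choice=choice,
        asba_u=asba_u,
        asba_u_aggregated=aggregated,
        asba_u_binary=binary,
        correct=int(choice == t.true_label),
    )


def annotate_triplets(
    triplets: Sequence[Triplet],
    schema: FeatureSchema | None = None,
    tau_asba: float = DEFAULT_TAU_ASBA,
) -> list[ASBAResult]:
    """Annotate a triplet set; the schema defaults to a fit on its 90 records."""
    if schema is None:
        schema = FeatureSchema.from_triplets(triplets)
    return [asba_annotate(t, schema, tau_asba) for t in triplets]
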