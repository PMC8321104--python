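"""Construction of annotation triplets from a cohort table.

Ninety records are sampled — 45 without hepatic steatosis (liver-fat
fraction <= 5%) and 45 with moderate-to-severe steatosis (>= 14%); mild
cases (5-14%) are excluded beforehand.  The two subsamples are split into
six groups of 15 (1-3 healthy, 4-6 steatosis) and members matched by
number across groups: triplets 1-15 come from groups (1, 2, 6), triplets
16-30 from (3, 4, 5), so each scheme hides one record of the minority
class in the middle slot.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CohortRecord, GroupAssignment, Triplet

STEATOSIS_CLASSES = ("none", "mild", "moderate_severe")


def classify_steatosis(livfat_per: float) -> str:
    """Map a liver-fat percentage to its steatosis class.

    <= 5.0 % -> "none"; 5-14 % -> "mild"; >= 14 % -> "moderate_severe".
    """
    if livfat_per < 0:
        raise ValueError(f"liver-fat percentage must be >= 0, got {livfat_per}")
    if livfat_per <= 5.0:
        return "none"
    if livfat_per < 14.0:
        return "mild"
    return "moderate_severe"


class SamplingError(ValueError):
    """Cohort lacks enough records in a required steatosis class."""


def sample_and_group(
    cohort: list[CohortRecord], seed: int
) -> list[GroupAssignment]:
    """Sample 45 + 45 records and assign them to the six-group scheme.

    Mild cases are excluded before sampling.  Selection is uniform at
    random under ``seed``; each subsample is split into three groups of 15
    whose members are numbered 1-15.
    """
    healthy = [r for r in cohort if classify_steatosis(r.livfat_per) == "none"]
    severe = [r for r in cohort if classify_steatosis(r.livfat_per) == "moderate_severe"]
    for name, pool in (("none", healthy), ("moderate_severe", severe)):
        if len(pool) < 45:
            raise SamplingError(
                f"need >= 45 records of class {name!r}, found {len(pool)} "
                f"(shortfall {45 - len(pool)})"
            )
    rng = np.random.default_rng(seed)
    picked_healthy = [healthy[i] for i in rng.choice(len(healthy), 45, replace=False)]
    picked_severe = [severe[i] for i in rng.choice(len(severe), 45, replace=False)]

    assignments: list[GroupAssignment] = []
    for base_group, picked in ((1, picked_healthy), (4, picked_severe)):
        for j, record in enumerate(picked):
            assignments.append(
                GroupAssignment(
                    group=base_group + j // 15,
                    member_number=j % 15 + 1,
                    record_id=record.id,
                )
            )
    return assignments


# Triplet scheme: (groups, slot roles).  In scheme (1, 2, 6) the middle
# record is healthy, so the true label is C; in (3, 4, 5) it is A.  The
# lower-numbered group of the same-class pair takes the visible anchor
# slot by default (the original assignment rule is not documented).
_SCHEMES = (
    {"groups": (1, 2, 6), "anchor_same_class": 1, "hidden": 2, "opposite": 6},
    {"groups": (3, 4, 5), "anchor_same_class": 4, "hidden": 5, "opposite": 3},
)


class TripletConstructionError(ValueError):
    pass


def build_triplets(
    groups: list[GroupAssignment],
    cohort: list[CohortRecord],
    hidden_from_higher_group: bool = True,
) -> list[Triplet]:
    """Assemble the 30 triplets from a complete six-group assignment.

    ``hidden_from_higher_group`` controls which record of the same-class
    pair is hidden in the middle slot: by default the record from the
    higher-numbered group (2 or 5), leaving the lower-numbered group (1 or
    4) as the visible anchor of its class.
    """
    by_id = {r.id: r for r in cohort}
    table: dict[tuple[int, int], CohortRecord] = {}
    for g in groups:
        if g.record_id not in by_id:
            raise TripletConstructionError(f"record {g.record_id!r} not in cohort")
        table[(g.group, g.member_number)] = by_id[g.record_id]

    triplets: list[Triplet] = []
    for scheme_index, scheme in enumerate(_SCHEMES):
        same_anchor, hidden, opposite = (
            scheme["anchor_same_class"],
            scheme["hidden"],
            scheme["opposite"],
        )
        if not hidden_from_higher_group:
            same_anchor, hidden = hidden, same_anchor
        for number in range(1, 16):
            try:
                rec_anchor = table[(same_anchor, number)]
                rec_hidden = table[(hidden, number)]
                rec_opp = table[(opposite, number)]
            except KeyError as exc:
                raise TripletConstructionError(
                    f"missing (group, member) combination {exc.args[0]}"
                ) from None
            if rec_hidden.stea == 1:
                record_A, record_C = rec_anchor, rec_opp
                true_label = "A"
            else:
                record_A, record_C = rec_opp, rec_anchor
                true_label = "C"
            triplets.append(
                Triplet(
                    triplet_id=scheme_index * 15 + number,
                    record_A=record_A,
                    record_B=rec_hidden,
                    record_C=record_C,
                    true_label=true_label,
                )
            )
    return triplets


def shuffle_presentation_order(
    triplets: list[Triplet], seed: int
) -> list[Triplet]:
    """Re-number triplet IDs under a seeded random presentation order."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(triplets))
    out = []
    for new_id, idx in enumerate(order, start=1):
        t = triplets[idx]
        out.append(
            Triplet(
                triplet_id=new_id,
                record_A=t.record_A,
                record_B=t.record_B,
                record_C=t.record_C,
                true_label=t.true_label,
            )
        )
    return out
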