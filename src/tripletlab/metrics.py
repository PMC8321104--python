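"""Correctness, stated-uncertainty, agreement and reliability metrics.

Per triplet ``t`` with ``n`` raters the normalised majority is

    agrm(t) = max{voteFor(t, A), voteFor(t, C)} / n            in [0.5, 1]

and the binary agreement flag compares ``agrm`` rounded to two decimals
against the threshold tau truncated to two decimals (0.66, 0.75) — the
comparison rule that reproduces every printed flag at both thresholds.
Triplet-level correctness and stated-uncertainty sums are binarised
differently, against floor(n * tau); both rules are exposed as given.

Overall inter-rater reliability is nominal-scale Krippendorff's alpha,
with the conventional 0.667 / 0.800 reliability guideline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnnotationMatrix

DEFAULT_TAUS = (2.0 / 3.0, 3.0 / 4.0)

STATED_U_LABELS = {
    "very certain": 0,
    "rather certain": 1,
    "rather uncertain": 2,
    "very uncertain": 3,
}


def _round_half_up(x: float, decimals: int = 0) -> float:
    scale = 10.0 ** decimals
    return math.floor(x * scale + 0.5) / scale


def encode_stated_u(label: str | int) -> tuple[int, int]:
    """Encode a stated-uncertainty answer to its ordinal and binary forms.

    "very certain" -> 0 ... "very uncertain" -> 3; binary is 0 for levels
    {0, 1} (low) and 1 for {2, 3} (high).  Integer inputs in 0..3 pass
    through.
    """
    if isinstance(label, str):
        key = label.strip().lower()
        if key not in STATED_U_LABELS:
            raise ValueError(f"unknown stated-uncertainty label {label!r}")
        ordinal = STATED_U_LABELS[key]
    else:
        ordinal = int(label)
        if ordinal not in (0, 1, 2, 3):
            raise ValueError(f"stated uncertainty must be in 0..3, got {label}")
    return ordinal, int(ordinal >= 2)


@dataclass
class CorrectnessSummary:
    """Correct-answer counts aggregated per annotator and per triplet."""

    per_annotator: pd.DataFrame   # index annotator_id: a_correctness, a_correctness_ratio
    per_triplet: pd.DataFrame     # index triplet_id: t_correctness, t_correctness_ratio
    skip_first: int
    n_annotators: int
    n_triplets: int               # after filtering


def correctness_summary(m: AnnotationMatrix, skip_first: int = 0) -> CorrectnessSummary:
    """Count correct answers per annotator and per triplet.

    ``skip_first`` drops the first k triplets (by ordinal ID) before
    aggregating — used to discount the acclimatization phase.
    """
    if skip_first < 0:
        raise ValueError("skip_first must be >= 0")
    if skip_first >= len(m.triplets):
        raise ValueError(
            f"skip_first = {skip_first} leaves no triplets (have {len(m.triplets)})"
        )
    df = m.to_frame()
    kept = sorted(m.triplets)[skip_first:]
    df = df[df["triplet_id"].isin(kept)]

    per_annotator = df.groupby("annotator_id")["correct"].sum().to_frame("a_correctness")
    per_annotator["a_correctness_ratio"] = per_annotator["a_correctness"] / len(kept)
    per_triplet = df.groupby("triplet_id")["correct"].sum().to_frame("t_correctness")
    per_triplet["t_correctness_ratio"] = per_triplet["t_correctness"] / m.n
    return CorrectnessSummary(
        per_annotator=per_annotator,
        per_triplet=per_triplet,
        skip_first=skip_first,
        n_annotators=m.n,
        n_triplets=len(kept),
    )


def stated_u_summary(m: AnnotationMatrix, skip_first: int = 0) -> dict[str, pd.DataFrame]:
    """Sums and ratios of stated uncertainty per annotator and per triplet."""
    df = m.to_frame()
    kept = sorted(m.triplets)[skip_first:]
    df = df[df["triplet_id"].isin(kept)].copy()
    df["stated_u_binary"] = (df["stated_u"] >= 2).astype(int)

    per_annotator = df.groupby("annotator_id")[["stated_u", "stated_u_binary"]].sum()
    per_annotator.columns = ["a_stated_u", "a_stated_u_binary"]
    per_annotator["a_stated_u_ratio"] = per_annotator["a_stated_u"] / len(kept)
    per_annotator["a_stated_u_binary_ratio"] = per_annotator["a_stated_u_binary"] / len(kept)

    per_triplet = df.groupby("triplet_id")[["stated_u", "stated_u_binary"]].sum()
    per_triplet.columns = ["t_stated_u", "t_stated_u_binary"]
    per_triplet["t_uratio"] = per_triplet["t_stated_u"] / m.n
    per_triplet["t_stated_u_binary_ratio"] = per_triplet["t_stated_u_binary"] / m.n
    return {"per_annotator": per_annotator, "per_triplet": per_triplet}


@dataclass(frozen=True)
class VoteCount:
    """Per-triplet vote tally with agreement flags at each threshold tau."""

    triplet_id: int
    votes_A: int
    votes_C: int
    flags: dict[float, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.votes_A + self.votes_C

    @property
    def agrm(self) -> float:
        return max(self.votes_A, self.votes_C) / self.n

    @property
    def majority_label(self) -> str:
        # C wins exact ties; a tie never reaches an agreement flag anyway
        return "A" if self.votes_A > self.votes_C else "C"


def agreement_flag(votes_A: int, votes_C: int, tau: float) -> int:
    """Binary agreement at threshold tau, on the 2-decimal comparison scale."""
    agrm = max(votes_A, votes_C) / (votes_A + votes_C)
    return int(_round_half_up(agrm, 2) >= math.floor(tau * 100) / 100)


def vote_counts(
    m: AnnotationMatrix, taus: Sequence[float] = DEFAULT_TAUS
) -> list[VoteCount]:
    """Tally A/C votes per triplet and flag agreement at each threshold."""
    df = m.to_frame()
    out = []
    for triplet_id, grp in df.groupby("triplet_id"):
        votes_a = int((grp["choice"] == "A").sum())
        votes_c = int((grp["choice"] == "C").sum())
        flags = {tau: agreement_flag(votes_a, votes_c, tau) for tau in taus}
        out.append(VoteCount(int(triplet_id), votes_a, votes_c, flags))
    return out


def reconstruct_counts(ratio: float, n: int) -> int:
    """Invert a printed 2-decimal vote ratio to an integer count (half-up)."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio must be in [0, 1], got {ratio}")
    return int(math.floor(ratio * n + 0.5))


class ReconstructionError(ValueError):
    pass


def vote_counts_from_ratios(
    table: pd.DataFrame, n: int = 29, taus: Sequence[float] = DEFAULT_TAUS
) -> list[VoteCount]:
    """Rebuild integer vote tallies from printed voteFor ratios.

    ``table`` needs columns triplet_id, votefor_A, votefor_C (the table7
    fixture layout).  Each reconstructed pair must sum to n.
    """
    out = []
    for _, row in table.iterrows():
        votes_a = reconstruct_counts(float(row["votefor_A"]), n)
        votes_c = reconstruct_counts(float(row["votefor_C"]), n)
        if votes_a + votes_c != n:
            raise ReconstructionError(
                f"triplet {row['triplet_id']}: reconstructed counts "
                f"{votes_a} + {votes_c} != {n}"
            )
        flags = {tau: agreement_flag(votes_a, votes_c, tau) for tau in taus}
        out.append(VoteCount(int(row["triplet_id"]), votes_a, votes_c, flags))
    return out


def binarize_triplet_scores(score: int, n: int, tau: float) -> int:
    """Binarise a triplet-level sum (correctness or stated-U) at floor(n tau)."""
    if not 0.5 < tau <= 1.0:
        raise ValueError(f"tau must be in (0.5, 1], got {tau}")
    if not 0 <= score <= n:
        raise ValueError(f"score must be in 0..{n}, got {score}")
    return int(score >= math.floor(n * tau))


class DegenerateInputError(ValueError):
    """Statistic undefined on the given input (e.g. a single category)."""


def krippendorff_alpha(counts: Sequence[VoteCount]) -> float:
    """Nominal-scale Krippendorff's alpha from per-item A/C vote counts.

    alpha = 1 - D_o / D_e with observed disagreement
    D_o = (1/N) sum_u 2 a_u c_u / (m_u - 1) and expected disagreement
    D_e = 2 n_A n_C / (N (N - 1)), where N is the total number of ratings.
    """
    if len(counts) < 2:
        raise DegenerateInputError("alpha needs at least two items")
    if any(c.n < 2 for c in counts):
        raise DegenerateInputError("every item needs at least two ratings")
    big_n = sum(c.n for c in counts)
    n_a = sum(c.votes_A for c in counts)
    n_c = sum(c.votes_C for c in counts)
    if n_a == 0 or n_c == 0:
        raise DegenerateInputError("alpha undefined with a single observed category")
    d_o = sum(2.0 * c.votes_A * c.votes_C / (c.n - 1) for c in counts) / big_n
    d_e = 2.0 * n_a * n_c / (big_n * (big_n - 1))
    return 1.0 - d_o / d_e


def alpha_reliability_label(alpha: float) -> str:
    """The conventional reliability reading of an alpha value."""
    if alpha >= 0.800:
        return "reliable"
    if alpha >= 0.667:
        return "tentative"
    return "unreliable"


def choice_tally(m: AnnotationMatrix) -> pd.DataFrame:
    """2x2 counts of chosen label (A/C) x correctness."""
    df = m.to_frame()
    table = pd.crosstab(df["choice"], df["correct"])
    out = pd.DataFrame(0, index=["A", "C"], columns=["correct", "incorrect"])
    for label in ("A", "C"):
        if label in table.index:
            out.loc[label, "correct"] = int(table.loc[label].get(1, 0))
            out.loc[label, "incorrect"] = int(table.loc[label].get(0, 0))
    return out


def choice_tally_from_ratios(table: pd.DataFrame, n: int = 29) -> pd.DataFrame:
    """Choice x correctness tally from printed voteFor ratios and truth."""
    counts = vote_counts_from_ratios(table, n)
    truth = dict(zip(table["triplet_id"].astype(int), table["correct_label"]))
    out = pd.DataFrame(0, index=["A", "C"], columns=["correct", "incorrect"])
    for c in counts:
        correct_label = truth[c.triplet_id]
        for label, votes in (("A", c.votes_A), ("C", c.votes_C)):
            col = "correct" if label == correct_label else "incorrect"
            out.loc[label, col] += votes
    return out


def uncertainty_correctness_table(m: AnnotationMatrix) -> pd.DataFrame:
    """2x2 counts of binary stated uncertainty (0 certain / 1 uncertain)
    x correctness over all events."""
    df = m.to_frame()
    df["binary_u"] = (df["stated_u"] >= 2).astype(int)
    out = pd.DataFrame(0, index=[0, 1], columns=["correct", "incorrect"])
    for bu in (0, 1):
        grp = df[df["binary_u"] == bu]
        out.loc[bu, "correct"] = int((grp["correct"] == 1).sum())
        out.loc[bu, "incorrect"] = int((grp["correct"] == 0).sum())
    return out


def conditional_proportions(table: pd.DataFrame) -> dict[str, float]:
    """Row/column conditional percentages of a binary-U x correctness table.

    Keys: p_correct_given_certain, p_correct_given_uncertain,
    p_incorrect_given_certain, p_certain (all in percent).
    """
    certain_total = table.loc[0].sum()
    uncertain_total = table.loc[1].sum()
    grand = table.to_numpy().sum()
    return {
        "p_correct_given_certain": 100.0 * table.loc[0, "correct"] / certain_total,
        "p_correct_given_uncertain": 100.0 * table.loc[1, "correct"] / uncertain_total,
        "p_incorrect_given_certain": 100.0 * table.loc[0, "incorrect"] / certain_total,
        "p_certain": 100.0 * certain_total / grand,
    }


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction, 1 df) on a 2x2 table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateInputError("chi-square undefined with a zero marginal")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def agreement_breakdown(
    counts: Sequence[VoteCount],
    truth: Mapping[int, str],
    tau_strict: float = 3.0 / 4.0,
    tau_loose: float = 2.0 / 3.0,
) -> pd.DataFrame:
    """Cross-classify agreed-upon triplets by majority label and correctness.

    Rows A/C; columns: agreement at the strict threshold split by whether
    the majority label is correct, plus triplets agreeing only at the
    loose threshold, likewise split.
    """
    out = pd.DataFrame(
        0,
        index=["A", "C"],
        columns=[
            "strict_correct",
            "strict_incorrect",
            "loose_only_correct",
            "loose_only_incorrect",
        ],
    )
    for c in counts:
        strict = c.flags.get(tau_strict, agreement_flag(c.votes_A, c.votes_C, tau_strict))
        loose = c.flags.get(tau_loose, agreement_flag(c.votes_A, c.votes_C, tau_loose))
        if not loose:
            continue
        label = c.majority_label
        is_correct = label == truth[c.triplet_id]
        if strict:
            col = "strict_correct" if is_correct else "strict_incorrect"
        else:
            col = "loose_only_correct" if is_correct else "loose_only_incorrect"
        out.loc[label, col] += 1
    return out


def erroneous_agreement_count(
    counts: Sequence[VoteCount], truth: Mapping[int, str], tau: float
) -> int:
    """Triplets where the group agreed (at tau) on the wrong label."""
    total = 0
    for c in counts:
        flag = c.flags.get(tau, agreement_flag(c.votes_A, c.votes_C, tau))
        if flag and c.majority_label != truth[c.triplet_id]:
            total += 1
    return total


def correct_agreement_count(
    counts: Sequence[VoteCount], truth: Mapping[int, str], tau: float
) -> int:
    """Triplets where the group agreed (at tau) on the correct label."""
    total = 0
    for c in counts:
        flag = c.flags.get(tau, agreement_flag(c.votes_A, c.votes_C, tau))
        if flag and c.majority_label == truth[c.triplet_id]:
            total += 1
    return total
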