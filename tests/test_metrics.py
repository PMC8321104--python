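import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tripletlab as tl
from tripletlab.datatypes import AnnotationEvent, AnnotationMatrix
from tripletlab.metrics import (
    DegenerateInputError,
    ReconstructionError,
    VoteCount,
    agreement_flag,
)

from conftest import brute_force_alpha


def tiny_matrix(choices: dict[str, list[str]], truth: dict[int, str],
                stated: dict[str, list[int]] | None = None) -> AnnotationMatrix:
    """Build a complete matrix from per-annotator choice lists."""
    events = []
    for annotator, labels in choices.items():
        for t, label in enumerate(labels, start=1):
            su = stated[annotator][t - 1] if stated else 0
            events.append(AnnotationEvent(annotator, t, label, su, 10.0))
    return AnnotationMatrix(events, truth)


class TestEncodeStatedU:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("very certain", (0, 0)),
            ("rather certain", (1, 0)),
            ("rather uncertain", (2, 1)),
            ("very uncertain", (3, 1)),
            (0, (0, 0)),
            (3, (3, 1)),
        ],
    )
    def test_encoding(self, label, expected):
        assert tl.encode_stated_u(label) == expected

    @pytest.mark.parametrize("bad", ["certain-ish", 4, -1])
    def test_unknown_label(self, bad):
        with pytest.raises(ValueError):
            tl.encode_stated_u(bad)


class TestCorrectnessSummary:
    def test_all_correct_gives_unit_ratios(self):
        m = tiny_matrix(
            {"x": ["A", "C"], "y": ["A", "C"]}, truth={1: "A", 2: "C"}
        )
        s = tl.correctness_summary(m)
        assert (s.per_annotator["a_correctness_ratio"] == 1.0).all()
        assert (s.per_triplet["t_correctness_ratio"] == 1.0).all()

    def test_marginal_consistency(self, sim_matrix):
        s = tl.correctness_summary(sim_matrix)
        assert (
            s.per_annotator["a_correctness"].sum()
            == s.per_triplet["t_correctness"].sum()
        )

    def test_skip_first_changes_denominator(self, sim_matrix):
        s = tl.correctness_summary(sim_matrix, skip_first=3)
        assert s.n_triplets == 27
        a = s.per_annotator
        assert np.allclose(a["a_correctness_ratio"], a["a_correctness"] / 27)

    def test_skip_all_rejected(self, sim_matrix):
        with pytest.raises(ValueError):
            tl.correctness_summary(sim_matrix, skip_first=30)

    def test_reference_triplet_ratio(self, table7_counts, table7_truth):
        """Reconstructed votes reproduce the printed correctness ratio of
        the first triplet (23 of 29 for the correct label C -> 0.79)."""
        c = table7_counts[0]
        votes_for_truth = c.votes_C if table7_truth[1] == "C" else c.votes_A
        assert round(votes_for_truth / 29, 2) == 0.79


class TestVoteCounts:
    def test_counts_and_flags_from_matrix(self):
        m = tiny_matrix(
            {f"x{i}": ["A" if i < 6 else "C"] for i in range(29)}, truth={1: "C"}
        )
        (vc,) = tl.vote_counts(m)
        assert (vc.votes_A, vc.votes_C) == (6, 23)
        assert vc.agrm == pytest.approx(23 / 29)
        assert vc.flags[2 / 3] == 1 and vc.flags[3 / 4] == 1

    @pytest.mark.parametrize(
        "votes_a, votes_c, f23, f34",
        [
            (6, 23, 1, 1),
            (16, 13, 0, 0),   # agrm 0.55: below both thresholds
            (21, 8, 1, 0),    # agrm 0.72: loose only
            (10, 19, 1, 0),   # agrm 0.655 -> 0.66 on the printed scale
            (7, 22, 1, 1),    # agrm 0.759 -> 0.76 >= 0.75
        ],
    )
    def test_two_decimal_flag_rule(self, votes_a, votes_c, f23, f34):
        assert agreement_flag(votes_a, votes_c, 2 / 3) == f23
        assert agreement_flag(votes_a, votes_c, 3 / 4) == f34

    def test_flags_monotone_in_tau(self):
        rng = np.random.default_rng(1)
        taus = np.linspace(0.51, 1.0, 30)
        for _ in range(50):
            votes_a = int(rng.integers(0, 30))
            flags = [agreement_flag(votes_a, 29 - votes_a, t) for t in taus]
            assert all(f1 >= f2 for f1, f2 in zip(flags, flags[1:]))

    def test_reconstructed_flags_match_printed(self, table7, table7_counts):
        for row, vc in zip(table7.itertuples(), table7_counts):
            assert vc.flags[2 / 3] == row.agreement_23
            assert vc.flags[3 / 4] == row.agreement_34


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "ratio, n, expected",
        [(0.79, 29, 23), (1.00, 29, 29), (0.03, 29, 1), (0.5, 2, 1)],
    )
    def test_rounding(self, ratio, n, expected):
        assert tl.reconstruct_counts(ratio, n) == expected

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            tl.reconstruct_counts(1.2, 29)

    def test_pair_sum_enforced(self):
        df = pd.DataFrame(
            {"triplet_id": [1], "votefor_A": [0.5], "votefor_C": [0.6]}
        )
        with pytest.raises(ReconstructionError):
            tl.vote_counts_from_ratios(df, n=29)

    def test_all_reference_pairs_reconstruct(self, table7_counts):
        assert all(c.n == 29 for c in table7_counts)
        assert sum(c.votes_A for c in table7_counts) == 414
        assert sum(c.votes_C for c in table7_counts) == 456


class TestBinarize:
    @pytest.mark.parametrize(
        "score, n, tau, expected",
        [
            (22, 29, 3 / 4, 1),  # floor(21.75) = 21 <= 22
            (19, 29, 2 / 3, 1),  # floor(19.33) = 19
            (20, 29, 3 / 4, 0),  # 20 < 21
            (0, 29, 2 / 3, 0),
        ],
    )
    def test_floor_rule(self, score, n, tau, expected):
        assert tl.binarize_triplet_scores(score, n, tau) == expected

    @pytest.mark.parametrize("tau", [0.5, 0.4, 1.01])
    def test_tau_domain(self, tau):
        with pytest.raises(ValueError):
            tl.binarize_triplet_scores(10, 29, tau)


class TestKrippendorffAlpha:
    def test_unanimity_gives_one(self):
        counts = [VoteCount(1, 5, 0), VoteCount(2, 0, 5), VoteCount(3, 5, 0)]
        assert tl.krippendorff_alpha(counts) == pytest.approx(1.0)

    def test_two_rater_hand_case(self):
        # items (2,0) and (1,1): D_o = D_e = 0.5 by pair enumeration
        counts = [VoteCount(1, 2, 0), VoteCount(2, 1, 1)]
        assert tl.krippendorff_alpha(counts) == pytest.approx(0.0)
        assert brute_force_alpha([["A", "A"], ["A", "C"]]) == pytest.approx(0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5)).filter(
                lambda t: t[0] + t[1] >= 2
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_matches_pair_enumeration_oracle(self, items):
        n_a = sum(a for a, _ in items)
        n_c = sum(c for _, c in items)
        counts = [VoteCount(i, a, c) for i, (a, c) in enumerate(items)]
        ratings = [["A"] * a + ["C"] * c for a, c in items]
        if n_a == 0 or n_c == 0:
            with pytest.raises(DegenerateInputError):
                tl.krippendorff_alpha(counts)
            return
        assert tl.krippendorff_alpha(counts) == pytest.approx(
            brute_force_alpha(ratings)
        )

    def test_invariant_under_relabeling_and_permutation(self, table7_counts):
        alpha = tl.krippendorff_alpha(table7_counts)
        swapped = [VoteCount(c.triplet_id, c.votes_C, c.votes_A) for c in table7_counts]
        assert tl.krippendorff_alpha(swapped) == pytest.approx(alpha)
        assert tl.krippendorff_alpha(table7_counts[::-1]) == pytest.approx(alpha)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            tl.krippendorff_alpha([VoteCount(1, 3, 2)])
        with pytest.raises(DegenerateInputError):
            tl.krippendorff_alpha([VoteCount(1, 3, 0), VoteCount(2, 4, 0)])

    def test_reliability_labels(self):
        assert tl.metrics.alpha_reliability_label(0.85) == "reliable"
        assert tl.metrics.alpha_reliability_label(0.7) == "tentative"
        assert tl.metrics.alpha_reliability_label(0.593) == "unreliable"


class TestChoiceTally:
    def test_reference_marginals_and_cells(self, table7):
        tally = tl.choice_tally_from_ratios(table7)
        assert tally.loc["A", "correct"] == 208
        assert tally.loc["A"].sum() == 414
        assert tally.loc["C"].sum() == 456
        assert tally.to_numpy().sum() == 870

    def test_all_correct_matrix(self):
        m = tiny_matrix({"x": ["A", "C"], "y": ["A", "C"]}, {1: "A", 2: "C"})
        tally = tl.choice_tally(m)
        assert tally["incorrect"].sum() == 0
        assert tally.to_numpy().sum() == 4

    def test_brute_force_hand_case(self):
        m = tiny_matrix({"x": ["A", "A"], "y": ["C", "A"]}, {1: "A", 2: "C"})
        tally = tl.choice_tally(m)
        # enumerate: x: (A,1), (A,0); y: (C,0), (A,0)
        assert tally.loc["A", "correct"] == 1
        assert tally.loc["A", "incorrect"] == 2
        assert tally.loc["C", "incorrect"] == 1
        assert tally.loc["C", "correct"] == 0


class TestUncertaintyCorrectness:
    def test_degenerate_all_certain_correct(self):
        m = tiny_matrix(
            {"x": ["A"], "y": ["A"]}, {1: "A"}, stated={"x": [0], "y": [1]}
        )
        table = tl.uncertainty_correctness_table(m)
        assert table.loc[0, "correct"] == 2
        assert table.to_numpy().sum() == 2

    def test_reference_conditional_proportions(self, table4):
        props = tl.conditional_proportions(table4)
        assert props["p_correct_given_uncertain"] == pytest.approx(
            100 * 156 / 334, abs=1e-9
        )
        assert props["p_certain"] == pytest.approx(100 * 536 / 870, abs=1e-9)


class TestChiSquare:
    def test_independence(self):
        stat, p = tl.chi_square_2x2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_oracle(self):
        # direct sum((O-E)^2 / E): all marginals 25, grand 50, E = 12.5
        stat, p = tl.chi_square_2x2([[20, 5], [5, 20]])
        expected_stat = sum((o - 12.5) ** 2 / 12.5 for o in (20, 5, 5, 20))
        assert stat == pytest.approx(expected_stat)
        assert 0 < p < 0.001

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateInputError):
            tl.chi_square_2x2([[0, 0], [5, 5]])


class TestAgreementBreakdown:
    def test_reference_table_cells(self, table7_counts, table7_truth):
        b = tl.agreement_breakdown(table7_counts, table7_truth)
        assert b.loc["A"].tolist() == [5, 4, 2, 3]
        assert b.loc["C"].tolist() == [7, 6, 0, 1]
        assert b.to_numpy().sum() == 28
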