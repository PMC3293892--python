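"""Canberra distances (full, partial-complete, core), normalization, MCC, AUPR."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnbench.list_metrics import (
    ConfusionCounts,
    RankedList,
    aupr,
    canberra_core,
    canberra_enumerated,
    canberra_full,
    canberra_partial_complete,
    expected_canberra,
    mcc,
    precision_recall,
    stability_indicator,
)


class TestCanberraFull:
    def test_hand_evaluated_values(self):
        assert canberra_full([0, 1, 2], [0, 1, 2]) == 0.0
        assert np.isclose(canberra_full([0, 1], [1, 0]), 2 / 3)
        # identity vs transposition of the first two of three elements
        assert np.isclose(canberra_full([0, 1, 2], [1, 0, 2]), 2 / 3)

    def test_symmetry_and_string_ids(self):
        a = RankedList(("x", "y", "z", "w"), p=4)
        b = RankedList(("w", "y", "x", "z"), p=4)
        assert np.isclose(canberra_full(a, b), canberra_full(b, a))
        assert canberra_full(a, a) == 0.0

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            canberra_full([0, 1, 2], [0, 1, 3])

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            RankedList((1, 1, 2), p=3)


class TestPartialDistances:
    @pytest.mark.parametrize("p", [2, 3, 4, 5])
    def test_matches_enumeration_for_all_pairs(self, p):
        """Closed form == exhaustive mean over completions, machine precision."""
        universe = list(range(p))
        for l1 in range(1, p + 1):
            for l2 in range(1, p + 1):
                for ids1 in permutations(universe, l1):
                    for ids2 in permutations(universe, l2):
                        t1 = RankedList(ids1, p)
                        t2 = RankedList(ids2, p)
                        want = canberra_enumerated(t1, t2, p)
                        got = canberra_partial_complete(t1, t2, p)
                        assert abs(got - want) < 1e-10
                if p >= 4:
                    break  # exhaustive at p<4; spot rows beyond to stay fast
            if p >= 4:
                break

    def test_full_length_lists_reduce_to_plain_distance(self):
        t1 = RankedList((0, 1, 2, 3), p=4)
        t2 = RankedList((2, 0, 3, 1), p=4)
        d = canberra_full(t1, t2)
        assert np.isclose(canberra_partial_complete(t1, t2, 4), d)
        assert np.isclose(canberra_core(t1, t2, 4), d)

    def test_identical_tops_closer_than_disjoint_tops(self):
        same = canberra_partial_complete(RankedList((0, 1), 4), RankedList((0, 1), 4), 4)
        disj = canberra_partial_complete(RankedList((0, 1), 4), RankedList((2, 3), 4), 4)
        assert same < disj

    def test_core_bounded_by_complete_on_random_pairs(self):
        rng = np.random.default_rng(0)
        p = 30
        for _ in range(100):
            l1, l2 = rng.integers(1, p, size=2)
            t1 = RankedList(tuple(rng.permutation(p)[:l1]), p)
            t2 = RankedList(tuple(rng.permutation(p)[:l2]), p)
            comp = canberra_partial_complete(t1, t2, p)
            core = canberra_core(t1, t2, p)
            assert core <= comp + 1e-12

    def test_core_subtracts_both_unlisted_term(self):
        # independent check of the subtraction rule via enumeration: average
        # the contribution of features listed in neither list over all
        # completion pairs, subtract from the enumerated complete distance
        p = 5
        t1 = RankedList((0, 1), p)
        t2 = RankedList((1, 3), p)
        unlisted_both = {2, 4}
        rest1 = [f for f in range(p) if f not in t1.ids]
        rest2 = [f for f in range(p) if f not in t2.ids]
        total, count = 0.0, 0
        for c1 in permutations(rest1):
            full1 = list(t1.ids) + list(c1)
            r1 = {f: i + 1 for i, f in enumerate(full1)}
            for c2 in permutations(rest2):
                full2 = list(t2.ids) + list(c2)
                r2 = {f: i + 1 for i, f in enumerate(full2)}
                total += sum(
                    abs(r1[f] - r2[f]) / (r1[f] + r2[f]) for f in unlisted_both
                )
                count += 1
        want_core = canberra_enumerated(t1, t2, p) - total / count
        assert abs(canberra_core(t1, t2, p) - want_core) < 1e-10


class TestExpectation:
    def test_small_cases_exact(self):
        assert expected_canberra(1) == 0.0
        assert np.isclose(expected_canberra(2), 1 / 3)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(1)
        p = 50
        vals = [
            canberra_full(tuple(rng.permutation(p)), tuple(rng.permutation(p)))
            for _ in range(3000)
        ]
        mc = np.mean(vals)
        assert abs(mc - expected_canberra(p)) / expected_canberra(p) < 0.02

    def test_continuous_limit_slope(self):
        p = 2000
        assert abs(expected_canberra(p) / p - (2 * np.log(2) - 1)) < 2e-3


class TestStability:
    def test_identical_lists_give_zero(self):
        lists = [RankedList((0, 1, 2, 3), 4)] * 3
        assert stability_indicator(lists).value == 0.0

    def test_random_lists_give_about_one(self):
        rng = np.random.default_rng(2)
        p = 300
        lists = [tuple(rng.permutation(p)) for _ in range(40)]
        rep = stability_indicator(lists, p=p)
        assert abs(rep.value - 1.0) < 0.05

    def test_requires_two_lists(self):
        with pytest.raises(ValueError):
            stability_indicator([RankedList((0, 1), 2)])

    def test_core_distance_mode_on_partial_lists(self):
        lists = [RankedList((0, 1), 10), RankedList((0, 2), 10), RankedList((5, 6), 10)]
        rep = stability_indicator(lists, p=10, distance="core")
        assert rep.value >= 0
        assert rep.distance == "core"


class TestMcc:
    def test_perfect_and_degenerate(self):
        assert mcc(ConfusionCounts(10, 10, 0, 0)) == 1.0
        assert mcc(ConfusionCounts(0, 0, 10, 10)) == -1.0
        assert mcc(ConfusionCounts(10, 0, 10, 0)) == 0.0  # one predicted class

    def test_worked_example(self):
        val = mcc(ConfusionCounts(40, 35, 15, 10))
        assert np.isclose(val, 1250 / np.sqrt(55 * 50 * 45 * 50))

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equals_pearson_correlation_of_label_vectors(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        val = mcc(c)
        assert -1.0 <= val <= 1.0
        # class-swap invariance
        assert np.isclose(val, mcc(ConfusionCounts(tn, tp, fn, fp)))
        truth = np.array([1] * (tp + fn) + [0] * (tn + fp))
        pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        if truth.size >= 2 and truth.std() > 0 and pred.std() > 0:
            assert np.isclose(val, np.corrcoef(truth, pred)[0, 1])


class TestSelectionQuality:
    def test_precision_recall_arithmetic(self):
        truth = set(range(155))
        sel = set(range(40)) | set(range(1000, 1010))
        prec, rec = precision_recall(sel, truth)
        assert np.isclose(prec, 40 / 50)
        assert np.isclose(rec, 40 / 155)
        assert precision_recall(set(), truth) == (0.0, 0.0)
        assert precision_recall(truth, truth) == (1.0, 1.0)

    def test_aupr_extremes(self):
        p = 50
        truth = set(range(10))
        perfect = tuple(range(p))  # truth first
        assert np.isclose(aupr(RankedList(perfect, p), truth), 1.0)
        reverse = tuple(range(p - 1, -1, -1))
        assert aupr(RankedList(reverse, p), truth) < 1.0

    def test_aupr_of_random_ranking_near_prevalence(self):
        rng = np.random.default_rng(3)
        p, k = 2000, 31
        truth = set(range(k))
        vals = [
            aupr(RankedList(tuple(rng.permutation(p)), p), truth) for _ in range(50)
        ]
        assert abs(np.mean(vals) - k / p) < 0.01

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            aupr(RankedList((0, 1), 2), set())
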