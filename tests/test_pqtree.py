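"""PQ-tree model: parsing, frontiers, consistent sets and the S-score."""

import math

import pytest
from hypothesis import given, strategies as st

import pqfinder as pq
from pqfinder.pqtree import CapacityError, ParseError, PQTreeError


# -- parsing and serialization ----------------------------------------------

class TestParse:
    def test_q_node_root(self):
        t = pq.parse_pqtree("[A B C]")
        assert t.root.kind == "Q"
        assert pq.frontier(t) == ("A", "B", "C")
        assert (t.m, t.m_p, t.m_q, t.gamma) == (3, 0, 1, 3)

    def test_published_q_only_tree_statistics(self, example_trees):
        t, _, _ = example_trees[0]
        assert (t.m, t.m_p, t.m_q, t.gamma) == (6, 0, 5, 2)

    def test_published_mixed_tree_statistics(self, example_trees):
        t, _, _ = example_trees[1]
        root = t.root
        assert root.kind == "P"
        assert [c.kind for c in root.children] == ["LEAF", "Q", "LEAF"]
        assert (t.m, t.m_p, t.m_q, t.gamma) == (5, 1, 1, 3)

    def test_single_token_is_one_leaf_tree(self):
        t = pq.parse_pqtree("X")
        assert t.m == 1 and t.root.is_leaf and t.gamma == 0

    @pytest.mark.parametrize("bad", ["", "  ", "[A [B]", "[A B))", "(A)", "()",
                                     "[A B] C", ")A B("])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(ParseError):
            pq.parse_pqtree(bad)

    @pytest.mark.parametrize("text", [
        "X",
        "(A B)",
        "[[1538 [3696 0845]] [0642 0745]]",
        "(1609 [1653 1175 0395] 3839)",
    ])
    def test_round_trip(self, text):
        assert pq.serialize_pqtree(pq.parse_pqtree(text)) == text


# random trees via the generator round-trip through text
@given(st.integers(0, 10_000))
def test_parse_serialize_round_trip_random(seed):
    t = pq.random_pqtree(pq.TreeGenParams(
        n_leaves=1 + seed % 9, p_node_prob=(seed % 7) / 6, seed=seed,
        duplicate_prob=0.3,
    ))
    text = pq.serialize_pqtree(t)
    assert pq.serialize_pqtree(pq.parse_pqtree(text)) == text


def test_frontier_drops_brackets(example_trees):
    t, _, _ = example_trees[0]
    assert pq.frontier(t) == ("0683", "0411", "0410", "0559", "4177", "0583")
    assert pq.frontier(example_trees[1][0]) == (
        "1609", "1653", "1175", "0395", "3839")


# -- consistent sets --------------------------------------------------------

class TestEnumeration:
    def test_p_node_all_orders(self):
        fs = pq.enumerate_consistent(pq.parse_pqtree("(A B)"))
        assert {"".join(f) for f in fs} == {"AB", "BA"}

    def test_q_node_two_orientations(self):
        fs = pq.enumerate_consistent(pq.parse_pqtree("[A B C]"))
        assert {"".join(f) for f in fs} == {"ABC", "CBA"}

    def test_one_deletion_closure(self):
        fs = pq.enumerate_consistent(pq.parse_pqtree("[A B C]"), d=1)
        assert {"".join(f) for f in fs} == {
            "ABC", "CBA", "AB", "BC", "AC", "CB", "BA", "CA"}

    def test_duplicate_labels_deduplicate(self, example_trees):
        t, _, _ = example_trees[5]   # contains the repeated label 3485
        assert len(pq.enumerate_consistent(t)) == 8

    def test_capacity_guard(self):
        t = pq.parse_pqtree("(a b c d e f g h)")
        with pytest.raises(CapacityError):
            pq.enumerate_consistent(t, cap=1000)

    @pytest.mark.parametrize("seed", range(12))
    def test_deletion_bound_monotone_and_lengths(self, seed):
        t = pq.random_pqtree(pq.TreeGenParams(
            n_leaves=2 + seed % 5, seed=seed, duplicate_prob=0.2,
            p_node_prob=0.5))
        f0 = pq.enumerate_consistent(t, 0)
        f1 = pq.enumerate_consistent(t, 1)
        f2 = pq.enumerate_consistent(t, 2)
        assert f0.members <= f1.members <= f2.members
        base = sorted(pq.frontier(t))
        for f in f0:
            assert len(f) == t.m and sorted(f) == base


class TestCounts:
    @pytest.mark.parametrize("text,expected", [
        ("(A B C)", 6),
        ("[[0683 [[0411 0410] [0559 4177]]] 0583]", 32),
        ("(1609 1869 [[1129 1172] 1879] 0524)", 96),
    ])
    def test_closed_form_examples(self, text, expected):
        t = pq.parse_pqtree(text)
        assert pq.count_consistent_closed_form(t) == expected
        assert len(pq.enumerate_consistent(t)) == expected

    def test_closed_form_rejects_duplicates(self, example_trees):
        with pytest.raises(PQTreeError):
            pq.count_consistent_closed_form(example_trees[5][0])

    @pytest.mark.parametrize("seed", range(30))
    def test_closed_form_matches_enumeration_random(self, seed):
        t = pq.random_pqtree(pq.TreeGenParams(
            n_leaves=2 + seed % 6, seed=1000 + seed,
            p_node_prob=(seed % 5) / 4, alphabet_size=1000))
        if pq.count_frontier_multiset(t) > 5040:
            return
        assert pq.count_consistent_closed_form(t) == len(
            pq.enumerate_consistent(t))

    @pytest.mark.parametrize("text,expected", [
        ("(A B C)", 6),
        ("[[0596 0599] [[3485 3485] 0015]]", 60),
        ("[[0683 [[0411 0410] [0559 4177]]] 0583]", 720),
    ])
    def test_frontier_multiset_count(self, text, expected):
        assert pq.count_frontier_multiset(pq.parse_pqtree(text)) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_frontier_multiset_equals_distinct_permutations(self, seed):
        from itertools import permutations
        t = pq.random_pqtree(pq.TreeGenParams(
            n_leaves=2 + seed % 5, seed=seed, duplicate_prob=0.5,
            alphabet_size=3))
        labels = pq.frontier(t)
        assert pq.count_frontier_multiset(t) == len(set(permutations(labels)))


# -- the S-score ------------------------------------------------------------

class TestSScore:
    def test_published_values(self, example_trees):
        for t, text, expected in example_trees:
            rep = pq.s_score(t)
            assert rep.s_score == expected, text
            assert rep.s_score == rep.numerator / rep.denominator

    def test_duplication_rows_route_through_enumeration(self, example_trees):
        for idx in (5, 6):
            rep = pq.s_score(example_trees[idx][0])
            assert rep.used_enumeration

    def test_flat_p_node_is_least_specific(self):
        rep = pq.s_score(pq.parse_pqtree("(a b c d e)"))
        assert rep.s_score == 1.0 and not rep.used_enumeration
        assert pq.s_score(pq.parse_pqtree("x")).s_score == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_s_score_at_least_one(self, seed):
        t = pq.random_pqtree(pq.TreeGenParams(
            n_leaves=2 + seed % 6, seed=200 + seed, duplicate_prob=0.25,
            p_node_prob=(seed % 3) / 2))
        rep = pq.s_score(t)
        assert rep.s_score >= 1.0
        # for duplicate-free trees the score is 1 exactly when the tree is
        # unconstrained (a flat P-node or a single leaf); label repeats can
        # collapse distinct reorderings and reach 1 on other shapes
        root = t.root
        flat_unconstrained = not root.is_leaf and all(
            c.is_leaf for c in root.children
        ) and (root.kind == "P" or len(root.children) == 2)
        distinct = len(set(pq.frontier(t))) == t.m
        if distinct and rep.s_score == 1.0:
            assert flat_unconstrained or t.m == 1

    def test_numerator_is_factorial_without_duplicates(self, example_trees):
        t, _, _ = example_trees[0]
        assert pq.s_score(t).numerator == math.factorial(t.m)
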