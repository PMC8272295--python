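"""Alignment and search dynamic programs: examples, invariants, traceback."""

import numpy as np
import pytest

import pqfinder as pq
from pqfinder.scoring import NEG_INF
from pqfinder.search import _Engine, derivation_window
from conftest import random_instance

EX = pq.exact_scorer(1.0)


def cfg(d_T=0, d_S=0, scorer=EX, delta=pq.DeletionCost()):
    return pq.SearchConfig(d_T, d_S, scorer, delta)


class TestDerivationWindow:
    def test_leaf(self):
        t = pq.parse_pqtree("X")
        assert derivation_window(t.root, 3, 0, 0) == (1, 3)

    def test_mixed_deletions(self):
        t = pq.parse_pqtree("(a b c d e f g)")   # span 7
        assert derivation_window(t.root, 3, 2, 1) == (6, 8)

    def test_fully_deleted_subtree_is_empty(self):
        t = pq.parse_pqtree("(a b)")
        assert derivation_window(t.root, 1, 2, 0) == (0, 0)


class TestLeafInitialization:
    def test_match_and_char_deletion(self):
        eng = _Engine(pq.parse_pqtree("A"), pq.TargetSequence("t", ("A", "B")),
                      cfg(1, 1))
        leaf_id = eng.root_id
        assert eng.A[leaf_id, 1, 0, 0] == 1.0
        assert eng.A[leaf_id, 1, 0, 1] == 1.0   # B deleted, A matched
        assert eng.A[leaf_id, 2, 1, 0] == 0.0   # leaf deleted

    def test_no_finite_substitution(self):
        eng = _Engine(pq.parse_pqtree("A"), pq.TargetSequence("t", ("B", "B")),
                      cfg(0, 0))
        assert eng.A[eng.root_id, 1, 0, 0] == NEG_INF


class TestAlign:
    def test_in_order_q(self):
        d = pq.pq_align(pq.parse_pqtree("[A B]"), "AB", cfg())
        assert d.score == 2.0
        assert {str(p) for p in d.mapping} == {"A@1>1", "B@2>2"}

    def test_p_node_reorder(self):
        assert pq.pq_align(pq.parse_pqtree("(A B)"), "BA", cfg()).score == 2.0

    def test_q_node_forbids_middle_swap(self):
        assert pq.pq_align(pq.parse_pqtree("[A B C]"), "ACB", cfg()) is None

    def test_string_deletion(self):
        d = pq.pq_align(pq.parse_pqtree("[A B C]"), "AXBC", cfg(0, 1))
        assert d.score == 3.0
        assert any(str(p) == "del_string@2" for p in d.mapping)

    def test_length_guard(self):
        t = pq.parse_pqtree("[A B C]")
        assert pq.pq_align(t, "AB", cfg(0, 0)) is None      # n < m - d_T
        assert pq.pq_align(t, "ABCX", cfg(0, 0)) is None    # n > m + d_S

    def test_tree_deletion_traceback(self):
        d = pq.pq_align(pq.parse_pqtree("(A B)"), "B", cfg(1, 0))
        assert d.score == 1.0
        assert {str(p) for p in d.mapping} == {"B@2>1", "del_tree@1"}


class TestSearch:
    def test_embedded_p_node(self):
        d = pq.pq_search(pq.parse_pqtree("(A B)"), "XABY", cfg())
        assert (d.s, d.e, d.score) == (2, 3, 2.0)

    def test_q_reversal(self):
        d = pq.pq_search(pq.parse_pqtree("[A B C]"), "ZCBA", cfg())
        assert (d.s, d.e, d.score) == (2, 4, 3.0)

    def test_intruding_gene(self):
        d = pq.pq_search(pq.parse_pqtree("[A B C]"), "ABZC", cfg(1, 1))
        assert (d.s, d.e, d.score, d.del_T, d.del_S) == (1, 4, 3.0, 0, 1)

    def test_prefers_fewer_deletions_on_score_tie(self):
        # an exact occurrence later in the string beats an equal-scoring
        # deletion-bearing one earlier
        d = pq.pq_search(pq.parse_pqtree("[A B C]"), "ABZCABC", cfg(1, 1))
        assert (d.s, d.e, d.del_T, d.del_S) == (5, 7, 0, 0)

    def test_report_all_covers_every_feasible_substring(self):
        best, all_d = pq.pq_search(
            pq.parse_pqtree("(A B)"), "ABBA", cfg(), report_all=True)
        # "BB" admits no derivation of (A B); the two feasible substrings do
        intervals = {(d.s, d.e) for d in all_d}
        assert intervals == {(1, 2), (3, 4)}
        assert best.s == 1

    def test_search_on_empty_target(self):
        assert pq.pq_search(pq.parse_pqtree("(A B)"), (), cfg(2, 0)) is None


class TestMembership:
    def test_examples(self):
        t = pq.parse_pqtree("[A B C]")
        assert pq.is_member(t, "ABC")
        assert not pq.is_member(t, "ACB")
        assert not pq.is_member(t, "AB")
        p = pq.parse_pqtree("(A B C)")
        from itertools import permutations
        assert all(pq.is_member(p, perm) for perm in permutations("ABC"))

    @pytest.mark.parametrize("seed", range(15))
    def test_membership_agrees_with_enumeration_exhaustively(self, seed):
        from itertools import permutations
        t = pq.random_pqtree(pq.TreeGenParams(
            n_leaves=2 + seed % 5, seed=500 + seed, duplicate_prob=0.2,
            p_node_prob=(seed % 3) / 2, alphabet_size=4))
        members = pq.enumerate_consistent(t, 0).members
        for cand in set(permutations(pq.frontier(t))):
            assert pq.is_member(t, cand) == (cand in members)


class TestInvariants:
    def test_monotone_in_deletion_budgets(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            T, S, c = random_instance(rng, max_d=0)
            scores = {}
            for dT in range(3):
                for dS in range(3):
                    d = pq.pq_search(T, S, cfg(dT, dS, c.scorer))
                    scores[dT, dS] = NEG_INF if d is None else d.score
            for dT in range(3):
                for dS in range(3):
                    if dT:
                        assert scores[dT, dS] >= scores[dT - 1, dS]
                    if dS:
                        assert scores[dT, dS] >= scores[dT, dS - 1]

    def test_equivalent_trees_score_identically(self):
        rng = np.random.default_rng(33)
        for _ in range(25):
            T, S, c = random_instance(rng)
            T2 = pq.PQTree(_shuffle_equivalent(T.root, rng))
            d1 = pq.pq_search(T, S, c)
            d2 = pq.pq_search(T2, S, c)
            if d1 is None:
                assert d2 is None
            else:
                assert d1.score == d2.score

    def test_derived_length_identity_and_score_audit(self):
        rng = np.random.default_rng(55)
        for _ in range(200):
            T, S, c = random_instance(rng, with_delta=bool(rng.integers(2)))
            best, all_d = pq.pq_search(T, S, c, report_all=True)
            for d in all_d:
                assert d.e - d.s + 1 == T.m - d.del_T + d.del_S
                assert pq.recompute_score(d.mapping, S, c.scorer, c.delta) == d.score
                _check_one_to_one(d, T, S)

    def test_mapped_string_is_quasi_consistent(self):
        # applying the mapping's substitutions/deletions to the derived
        # substring must give a member of C_{del_T}(T)
        rng = np.random.default_rng(77)
        checked = 0
        while checked < 40:
            T, S, c = random_instance(rng, max_leaves=6)
            d = pq.pq_search(T, S, c)
            if d is None:
                continue
            sub = {p.string_index: p for p in d.mapping
                   if p.string_index is not None}
            derived = []
            for idx in range(d.s, d.e + 1):
                p = sub[idx]
                if p.kind == "SUB":
                    derived.append(p.leaf_label)
            members = pq.enumerate_consistent(T, d.del_T, cap=10 ** 6).members
            assert tuple(derived) in members
            checked += 1


def _shuffle_equivalent(node, rng):
    if node.is_leaf:
        return node
    children = [_shuffle_equivalent(c, rng) for c in node.children]
    if node.kind == "P":
        order = rng.permutation(len(children))
        children = [children[j] for j in order]
    elif rng.random() < 0.5:
        children = children[::-1]
    return pq.PQNode(node.kind, children=tuple(children))


def _check_one_to_one(d, T, S):
    leaf_pos = [p.leaf_pos for p in d.mapping if p.leaf_pos is not None]
    str_idx = [p.string_index for p in d.mapping if p.string_index is not None]
    assert len(leaf_pos) == len(set(leaf_pos))
    assert len(str_idx) == len(set(str_idx))
    assert sorted(str_idx) == list(range(d.s, d.e + 1))
    assert all(1 <= p <= T.m for p in leaf_pos)
    subs = [p for p in d.mapping if p.kind == "SUB"]
    assert len(subs) == T.m - d.del_T
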