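"""Dynamic programs for PQ-tree alignment and PQ-tree search.

Given a query PQ-tree ``T``, a gene-order string ``S``, a substitution
scoring function ``h`` and deletion bounds ``d_T`` (missing genes, deleted
from the tree) and ``d_S`` (intruding genes, deleted from the string), the
search finds the substring of ``S`` and the one-to-one leaf-to-character
mapping of highest total score such that, after applying the mapping's
substitutions and deletions, the substring becomes a frontier reachable from
``T`` by legal reorderings and at most ``d_T`` leaf deletions.

The main table ``A[x, i, k_T, k_S]`` holds the best score of a derivation of
the subtree rooted at ``x`` to the substring starting at index ``i`` with
exactly ``k_T`` deletions from the tree and ``k_S`` from the string; the
derived substring length is forced to ``span(x) - k_T + k_S``.  Leaves are
initialized directly; internal nodes are filled in postorder by one of two
per-node procedures:

* **P-mapping** (P-nodes): a subset dynamic program over the node's children.
  ``P[C, k_T, k_S]`` is the best partial derivation using exactly the
  children in ``C`` to a prefix of the window; the last window character is
  either deleted or consumed by the derivation of one child in ``C``, and
  whole-child deletions are absorbed by the initialization entries.
* **Q-mapping** (Q-nodes): children must be consumed in left-to-right or
  right-to-left order, so each orientation is a bounded-gap alignment over
  the child sequence; the better orientation wins.

All external coordinates are 1-based inclusive; an empty derived string is
encoded as ``e = s - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal

import numpy as np

from .pqtree import LEAF, P, PQNode, PQTree, validate_label
from .scoring import (
    NEG_INF,
    DeletionCost,
    SubstitutionScorer,
    ZERO_DELETION_COST,
    exact_scorer,
    max_attainable_score,
)

__all__ = [
    "TargetSequence",
    "SearchConfig",
    "MappingPair",
    "Derivation",
    "SearchHit",
    "derivation_window",
    "pq_align",
    "pq_search",
    "is_member",
    "recompute_score",
]


@dataclass(frozen=True)
class TargetSequence:
    """A named gene-order string; ``genes`` are indexed 1-based inclusive."""

    id: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        for g in self.genes:
            validate_label(g)

    @property
    def n(self) -> int:
        return len(self.genes)

    def __getitem__(self, idx: int) -> str:
        """1-based character access, ``S[i]``."""
        if not 1 <= idx <= self.n:
            raise IndexError(f"index {idx} outside 1..{self.n}")
        return self.genes[idx - 1]

    def substring(self, s: int, e: int) -> tuple[str, ...]:
        """``S[s:e]`` inclusive; empty when ``e == s - 1``."""
        return self.genes[s - 1:e]


@dataclass(frozen=True)
class SearchConfig:
    """Bounds and scoring for one search run."""

    d_T: int = 1
    d_S: int = 3
    scorer: SubstitutionScorer = field(default_factory=exact_scorer)
    delta: DeletionCost = ZERO_DELETION_COST

    def __post_init__(self) -> None:
        if self.d_T < 0 or self.d_S < 0:
            raise ValueError("deletion bounds must be non-negative")


SUB = "SUB"
CHAR_DEL = "CHAR_DEL"
LEAF_DEL = "LEAF_DEL"


@dataclass(frozen=True)
class MappingPair:
    """One element of a one-to-one mapping: a substitution of a tree leaf by
    a string character, a character deletion (intruding gene), or a leaf
    deletion (missing gene).  ``leaf_pos`` is the 1-based position of the
    leaf in the tree's frontier; ``string_index`` is 1-based in the target."""

    kind: Literal["SUB", "CHAR_DEL", "LEAF_DEL"]
    leaf_pos: int | None = None
    leaf_label: str | None = None
    string_index: int | None = None

    def __str__(self) -> str:
        if self.kind == SUB:
            return f"{self.leaf_label}@{self.leaf_pos}>{self.string_index}"
        if self.kind == CHAR_DEL:
            return f"del_string@{self.string_index}"
        return f"del_tree@{self.leaf_pos}"


@dataclass(frozen=True)
class Derivation:
    """A scored derivation of a subtree to ``S[s:e]`` (``e = s - 1`` encodes
    the empty string), with deletion counts and, after traceback, the
    one-to-one mapping that yields it."""

    s: int
    e: int
    del_T: int
    del_S: int
    score: float
    mapping: tuple[MappingPair, ...] | None = None

    @property
    def length(self) -> int:
        return self.e - self.s + 1


@dataclass(frozen=True)
class SearchHit:
    """A reported approximate instance of the query in one target."""

    target_id: str
    derivation: Derivation
    score_fraction: float


def derivation_window(
    x: PQNode, i: int, k_T: int, k_S: int
) -> tuple[int, int]:
    """Length and end index of the string derived from ``x`` starting at
    ``i`` with ``k_T`` tree deletions and ``k_S`` string deletions:
    ``L = span(x) - k_T + k_S``, ``end = i + L - 1``.  A negative length
    signals an impossible combination to callers."""
    length = x.span - k_T + k_S
    return length, i + length - 1


def recompute_score(
    mapping: Iterable[MappingPair],
    S: TargetSequence,
    scorer: SubstitutionScorer,
    delta: DeletionCost = ZERO_DELETION_COST,
) -> float:
    """Audit a mapping: sum of substitution scores minus deletion costs."""
    total = 0.0
    for pair in mapping:
        if pair.kind == SUB:
            total += scorer.score(pair.leaf_label, S[pair.string_index])
        elif pair.kind == CHAR_DEL:
            total -= delta.string_cost(S[pair.string_index])
        else:
            total -= delta.tree_cost(pair.leaf_label)
    return total


# ---------------------------------------------------------------------------
# Node indexing
# ---------------------------------------------------------------------------

@dataclass
class _NodeRec:
    kind: str
    span: int
    label: str | None
    child_ids: list[int]
    leaf_pos: int | None          # 1-based frontier position (leaves only)
    leaf_positions: list[int]     # frontier positions of all leaves below
    leaf_labels: list[str]


def _index_tree(tree: PQTree) -> tuple[list[_NodeRec], int]:
    """Postorder-number the nodes; returns (records, root id)."""
    records: list[_NodeRec] = []
    counter = [0]

    def visit(node: PQNode) -> int:
        if node.kind == LEAF:
            counter[0] += 1
            rec = _NodeRec(LEAF, 1, node.label, [], counter[0],
                           [counter[0]], [node.label])
        else:
            cids = [visit(c) for c in node.children]
            positions = [p for c in cids for p in records[c].leaf_positions]
            labels = [l for c in cids for l in records[c].leaf_labels]
            rec = _NodeRec(node.kind, node.span, None, cids, None,
                           positions, labels)
        records.append(rec)
        return len(records) - 1

    root_id = visit(tree.root)
    return records, root_id


@lru_cache(maxsize=None)
def _subsets_by_size(gamma: int) -> tuple[int, ...]:
    return tuple(sorted(range(1 << gamma), key=lambda c: (c.bit_count(), c)))


# ---------------------------------------------------------------------------
# The engine
# ---------------------------------------------------------------------------

class _Engine:
    """Fills the main table for one (tree, target, config) triple and
    reconstructs mappings on demand."""

    def __init__(self, tree: PQTree, S: TargetSequence, cfg: SearchConfig):
        self.tree = tree
        self.S = S
        self.cfg = cfg
        self.d_T = min(cfg.d_T, tree.m)
        self.d_S = min(cfg.d_S, S.n)
        self.nodes, self.root_id = _index_tree(tree)
        n = S.n
        # A[x, i, k_T, k_S]; i indexed 1..n directly.
        self.A = np.full(
            (len(self.nodes), n + 2, self.d_T + 1, self.d_S + 1), NEG_INF
        )
        self._sdel = [0.0] + [cfg.delta.string_cost(g) for g in S.genes]
        self._fill()

    # -- deletion-cost helpers ------------------------------------------

    def _tree_del_sum(self, node_id: int) -> float:
        rec = self.nodes[node_id]
        return sum(self.cfg.delta.tree_cost(l) for l in rec.leaf_labels)

    # -- filling ---------------------------------------------------------

    def _fill(self) -> None:
        n = self.S.n
        for node_id, rec in enumerate(self.nodes):
            if rec.kind == LEAF:
                self._fill_leaf(node_id)
            else:
                d_Tx = min(self.d_T, rec.span)
                min_len = rec.span - d_Tx
                i_max = n - min_len + 1 if min_len >= 1 else n
                for i in range(1, max(i_max, 0) + 1):
                    self._fill_internal(node_id, i)

    def _fill_leaf(self, node_id: int) -> None:
        rec = self.nodes[node_id]
        S, h = self.S, self.cfg.scorer
        label = rec.label
        tdel = self.cfg.delta.tree_cost(label)
        n = S.n
        for i in range(1, n + 1):
            # window deletion-cost prefix over S[i : i+k_S]
            for k_S in range(self.d_S + 1):
                # deleted leaf: derives k_S deleted characters
                if self.d_T >= 1 and i + k_S - 1 <= n:
                    self.A[node_id, i, 1, k_S] = -tdel - sum(
                        self._sdel[j] for j in range(i, i + k_S)
                    )
                # mapped leaf: one of S[i..i+k_S] substituted, rest deleted
                if i + k_S <= n:
                    window_cost = sum(self._sdel[j] for j in range(i, i + k_S + 1))
                    best = NEG_INF
                    for ip in range(i, i + k_S + 1):
                        v = h.score(label, S[ip])
                        if v > NEG_INF:
                            v = v - (window_cost - self._sdel[ip])
                            if v > best:
                                best = v
                    self.A[node_id, i, 0, k_S] = best

    # window helpers

    def _window(self, node_id: int, i: int) -> int:
        """Length of the longest window of S starting at i usable by this
        node: span + d_S characters, clipped at n."""
        rec = self.nodes[node_id]
        return min(self.S.n, i + rec.span + self.d_S - 1) - i + 1

    def _fill_internal(self, node_id: int, i: int) -> None:
        rec = self.nodes[node_id]
        if rec.kind == P:
            table, _ = self._p_mapping(node_id, i)
            gamma = len(rec.child_ids)
            full = (1 << gamma) - 1
            self.A[node_id, i, :, :] = table[full]
        else:
            tables, _ = self._q_mapping(node_id, i)
            gamma = len(rec.child_ids)
            best = np.maximum(tables[0][gamma], tables[1][gamma])
            self.A[node_id, i, :, :] = best

    # -- P-node mapping --------------------------------------------------

    def _p_mapping(self, node_id: int, i: int):
        """Subset DP over the children of a P-node for window start ``i``.

        Returns (table, backpointers) where ``table[C, k_T, k_S]`` is the
        best score of a partial derivation using exactly the children in
        bitmask ``C`` to the prefix of length ``sum(span(c in C)) - k_T +
        k_S`` of the window, and backpointers record the winning case.
        """
        rec = self.nodes[node_id]
        cids = rec.child_ids
        gamma = len(cids)
        spans = [self.nodes[c].span for c in cids]
        len_w = self._window(node_id, i)
        d_T, d_S = self.d_T, self.d_S
        table = np.full(((1 << gamma), d_T + 1, d_S + 1), NEG_INF)
        bp: dict[tuple[int, int, int], tuple] = {}
        A = self.A
        n = self.S.n

        span_of = [0] * (1 << gamma)
        for C in range(1, 1 << gamma):
            low = C & -C
            span_of[C] = span_of[C ^ low] + spans[low.bit_length() - 1]

        for C in _subsets_by_size(gamma):
            span_C = span_of[C]
            for k_S in range(d_S + 1):
                for k_T in range(d_T + 1):
                    L = span_C - k_T + k_S
                    if k_T > span_C or k_S > L or L < 0 or L > len_w:
                        continue
                    if L == 0 and k_S == 0:
                        # every child in C wholly deleted (node deletions
                        # are captured here, not by an explicit case)
                        cost = sum(
                            self._tree_del_sum(cids[ci])
                            for ci in range(gamma) if C >> ci & 1
                        )
                        table[C, k_T, k_S] = -cost
                        bp[(C, k_T, k_S)] = ("init",)
                        continue
                    best = NEG_INF
                    tag: tuple | None = None
                    # case 1: the prefix-final character is deleted
                    if k_S >= 1:
                        prev = table[C, k_T, k_S - 1]
                        if prev > NEG_INF:
                            cand = prev - self._sdel[i + L - 1]
                            if cand > best:
                                best, tag = cand, ("chardel",)
                    # case 2: the prefix-final character is consumed by the
                    # derivation of one child in C
                    for ci in range(gamma):
                        if not C >> ci & 1:
                            continue
                        cid = cids[ci]
                        Crem = C ^ (1 << ci)
                        for kpT in range(min(k_T, spans[ci]) + 1):
                            for kpS in range(k_S + 1):
                                clen = spans[ci] - kpT + kpS
                                if clen < 1 or clen > L:
                                    continue
                                ip = i + L - clen
                                if ip < 1 or ip > n:
                                    continue
                                sc = A[cid, ip, kpT, kpS]
                                if sc == NEG_INF:
                                    continue
                                prev = table[Crem, k_T - kpT, k_S - kpS]
                                if prev == NEG_INF:
                                    continue
                                cand = prev + sc
                                if cand > best:
                                    best = cand
                                    tag = ("child", ci, kpT, kpS, ip)
                    if best > NEG_INF:
                        table[C, k_T, k_S] = best
                        bp[(C, k_T, k_S)] = tag
        return table, bp

    # -- Q-node mapping --------------------------------------------------

    def _q_mapping(self, node_id: int, i: int):
        """Two-orientation bounded-gap alignment over a Q-node's children.

        For each orientation, ``table[j, k_T, k_S]`` is the best score of
        deriving the first ``j`` children (in orientation order) to the
        prefix of length ``sum(spans[:j]) - k_T + k_S`` of the window.
        """
        rec = self.nodes[node_id]
        len_w = self._window(node_id, i)
        d_T, d_S = self.d_T, self.d_S
        A = self.A
        n = self.S.n
        tables = []
        bps = []
        for orient in (0, 1):
            cids = rec.child_ids if orient == 0 else rec.child_ids[::-1]
            gamma = len(cids)
            spans = [self.nodes[c].span for c in cids]
            pre = np.concatenate(([0], np.cumsum(spans)))
            table = np.full((gamma + 1, d_T + 1, d_S + 1), NEG_INF)
            bp: dict[tuple[int, int, int], tuple] = {}
            table[0, 0, 0] = 0.0
            bp[(0, 0, 0)] = ("base",)
            for k_S in range(1, d_S + 1):
                if k_S > len_w or table[0, 0, k_S - 1] == NEG_INF:
                    break
                table[0, 0, k_S] = table[0, 0, k_S - 1] - self._sdel[i + k_S - 1]
                bp[(0, 0, k_S)] = ("a",)
            for j in range(1, gamma + 1):
                cid = cids[j - 1]
                spj = spans[j - 1]
                for k_S in range(d_S + 1):
                    for k_T in range(d_T + 1):
                        L = pre[j] - k_T + k_S
                        if k_T > pre[j] or k_S > L or L < 0 or L > len_w:
                            continue
                        best = NEG_INF
                        tag: tuple | None = None
                        # (a) trailing character of the prefix is deleted
                        if k_S >= 1 and L >= 1:
                            prev = table[j, k_T, k_S - 1]
                            if prev > NEG_INF:
                                cand = prev - self._sdel[i + L - 1]
                                if cand > best:
                                    best, tag = cand, ("a",)
                        # (b) child j derives a suffix of the prefix
                        for kpT in range(min(k_T, spj) + 1):
                            for kpS in range(k_S + 1):
                                clen = spj - kpT + kpS
                                if clen < 1 or clen > L:
                                    continue
                                ip = i + L - clen
                                if ip < 1 or ip > n:
                                    continue
                                sc = A[cid, ip, kpT, kpS]
                                if sc == NEG_INF:
                                    continue
                                prev = table[j - 1, k_T - kpT, k_S - kpS]
                                if prev == NEG_INF:
                                    continue
                                cand = prev + sc
                                if cand > best:
                                    best = cand
                                    tag = ("b", kpT, kpS, ip)
                        # (c) child j wholly deleted
                        if k_T >= spj:
                            prev = table[j - 1, k_T - spj, k_S]
                            if prev > NEG_INF:
                                cand = prev - self._tree_del_sum(cid)
                                if cand > best:
                                    best, tag = cand, ("c",)
                        if best > NEG_INF:
                            table[j, k_T, k_S] = best
                            bp[(j, k_T, k_S)] = tag
            tables.append(table)
            bps.append(bp)
        return tables, bps

    # -- traceback -------------------------------------------------------

    def trace(self, node_id: int, i: int, k_T: int, k_S: int) -> list[MappingPair]:
        """Reconstruct the one-to-one mapping behind ``A[x, i, k_T, k_S]``."""
        if self.A[node_id, i, k_T, k_S] == NEG_INF:
            raise ValueError("cannot trace an infeasible table entry")
        rec = self.nodes[node_id]
        if rec.kind == LEAF:
            return self._trace_leaf(node_id, i, k_T, k_S)
        if rec.kind == P:
            return self._trace_p(node_id, i, k_T, k_S)
        return self._trace_q(node_id, i, k_T, k_S)

    def _trace_leaf(self, node_id, i, k_T, k_S) -> list[MappingPair]:
        rec = self.nodes[node_id]
        S, h = self.S, self.cfg.scorer
        pairs: list[MappingPair] = []
        if k_T == 1:
            pairs.append(MappingPair(LEAF_DEL, rec.leaf_pos, rec.label))
            for j in range(i, i + k_S):
                pairs.append(MappingPair(CHAR_DEL, string_index=j))
            return pairs
        window_cost = sum(self._sdel[j] for j in range(i, i + k_S + 1))
        best, best_ip = NEG_INF, None
        for ip in range(i, i + k_S + 1):
            v = h.score(rec.label, S[ip])
            if v > NEG_INF:
                v = v - (window_cost - self._sdel[ip])
                if v > best:
                    best, best_ip = v, ip
        pairs.append(MappingPair(SUB, rec.leaf_pos, rec.label, best_ip))
        for j in range(i, i + k_S + 1):
            if j != best_ip:
                pairs.append(MappingPair(CHAR_DEL, string_index=j))
        return pairs

    def _delete_subtree(self, node_id: int) -> list[MappingPair]:
        rec = self.nodes[node_id]
        return [
            MappingPair(LEAF_DEL, pos, lab)
            for pos, lab in zip(rec.leaf_positions, rec.leaf_labels)
        ]

    def _trace_p(self, node_id, i, k_T, k_S) -> list[MappingPair]:
        rec = self.nodes[node_id]
        cids = rec.child_ids
        gamma = len(cids)
        spans = [self.nodes[c].span for c in cids]
        _, bp = self._p_mapping(node_id, i)
        C = (1 << gamma) - 1
        pairs: list[MappingPair] = []
        while True:
            tag = bp[(C, k_T, k_S)]
            if tag[0] == "init":
                for ci in range(gamma):
                    if C >> ci & 1:
                        pairs.extend(self._delete_subtree(cids[ci]))
                return pairs
            if tag[0] == "chardel":
                span_C = sum(spans[ci] for ci in range(gamma) if C >> ci & 1)
                L = span_C - k_T + k_S
                pairs.append(MappingPair(CHAR_DEL, string_index=i + L - 1))
                k_S -= 1
            else:
                _, ci, kpT, kpS, ip = tag
                pairs.extend(self.trace(cids[ci], ip, kpT, kpS))
                C ^= 1 << ci
                k_T -= kpT
                k_S -= kpS

    def _trace_q(self, node_id, i, k_T, k_S) -> list[MappingPair]:
        rec = self.nodes[node_id]
        gamma = len(rec.child_ids)
        tables, bps = self._q_mapping(node_id, i)
        # deterministic: prefer the left-to-right orientation on ties
        if tables[0][gamma, k_T, k_S] >= tables[1][gamma, k_T, k_S]:
            orient = 0
        else:
            orient = 1
        cids = rec.child_ids if orient == 0 else rec.child_ids[::-1]
        spans = [self.nodes[c].span for c in cids]
        bp = bps[orient]
        j = gamma
        pairs: list[MappingPair] = []
        while not (j == 0 and k_T == 0 and k_S == 0):
            tag = bp[(j, k_T, k_S)]
            if tag[0] == "a":
                L = sum(spans[:j]) - k_T + k_S
                pairs.append(MappingPair(CHAR_DEL, string_index=i + L - 1))
                k_S -= 1
            elif tag[0] == "b":
                _, kpT, kpS, ip = tag
                pairs.extend(self.trace(cids[j - 1], ip, kpT, kpS))
                k_T -= kpT
                k_S -= kpS
                j -= 1
            elif tag[0] == "c":
                pairs.extend(self._delete_subtree(cids[j - 1]))
                k_T -= spans[j - 1]
                j -= 1
            else:  # base
                break
        return pairs

    # -- extraction ------------------------------------------------------

    def derivation(self, i: int, k_T: int, k_S: int) -> Derivation:
        score = float(self.A[self.root_id, i, k_T, k_S])
        L = self.tree.m - k_T + k_S
        mapping = tuple(
            sorted(
                self.trace(self.root_id, i, k_T, k_S),
                key=lambda p: (
                    p.string_index if p.string_index is not None else 0,
                    p.leaf_pos if p.leaf_pos is not None else 0,
                ),
            )
        )
        return Derivation(i, i + L - 1, k_T, k_S, score, mapping)

    def root_entries(self, min_length: int = 1):
        """Yield (i, k_T, k_S, score) for every finite root entry whose
        derived string has at least ``min_length`` characters."""
        n = self.S.n
        m = self.tree.m
        for k_T in range(self.d_T + 1):
            for k_S in range(self.d_S + 1):
                L = m - k_T + k_S
                if L < min_length:
                    continue
                for i in range(1, n - L + 2):
                    sc = self.A[self.root_id, i, k_T, k_S]
                    if sc > NEG_INF:
                        yield i, k_T, k_S, float(sc)


_TIE_KEY = "maximize score, then minimize del_S, del_T, start index"


def _best_entry(entries) -> tuple[int, int, int, float] | None:
    best = None
    best_key = None
    for i, k_T, k_S, sc in entries:
        key = (-sc, k_S, k_T, i)
        if best_key is None or key < best_key:
            best, best_key = (i, k_T, k_S, sc), key
    return best


def pq_align(
    T: PQTree, S: TargetSequence | Iterable[str], cfg: SearchConfig
) -> Derivation | None:
    """Best derivation of ``T`` to the whole of ``S'`` (Problem: optimization
    PQ-tree alignment), or ``None`` if no finite derivation exists.  Returns
    immediately when the string length is outside ``[m - d_T, m + d_S]``."""
    S = _as_target(S)
    n, m = S.n, T.m
    d_T = min(cfg.d_T, m)
    if n < m - d_T or n > m + cfg.d_S:
        return None
    if n == 0:
        # the whole tree deleted onto the empty string
        cost = sum(cfg.delta.tree_cost(x.label) for x in T.leaves())
        mapping = tuple(
            MappingPair(LEAF_DEL, pos, x.label)
            for pos, x in enumerate(T.leaves(), start=1)
        )
        return Derivation(1, 0, m, 0, -cost, mapping)
    eng = _Engine(T, S, cfg)
    entries = [
        (i, k_T, k_S, sc)
        for i, k_T, k_S, sc in eng.root_entries(min_length=n)
        if i == 1 and m - k_T + k_S == n
    ]
    best = _best_entry(entries)
    if best is None:
        return None
    return eng.derivation(*best[:3])


def pq_search(
    T: PQTree,
    S: TargetSequence | Iterable[str],
    cfg: SearchConfig,
    report_all: bool = False,
):
    """Best derivation of ``T`` to any substring of ``S`` (PQ-tree search).

    Ties are broken by maximizing the score, then minimizing string
    deletions, then tree deletions, then the start index.  With
    ``report_all`` the return value is ``(best, all_optima)`` where
    ``all_optima`` lists the best derivation for every feasible
    ``(start, k_T, k_S)`` combination — the per-substring alignment optima.
    """
    S = _as_target(S)
    if S.n == 0:
        return (None, []) if report_all else None
    eng = _Engine(T, S, cfg)
    entries = list(eng.root_entries())
    best = _best_entry(entries)
    best_d = eng.derivation(*best[:3]) if best is not None else None
    if not report_all:
        return best_d
    all_d = [eng.derivation(i, k_T, k_S) for i, k_T, k_S, _ in entries]
    return best_d, all_d


def is_member(T: PQTree, S: TargetSequence | Iterable[str]) -> bool:
    """Decide whether the gene order ``S`` belongs to the consistent set
    ``C(T)``: alignment with identity matching and no deletions."""
    S = _as_target(S)
    if S.n != T.m:
        return False
    cfg = SearchConfig(d_T=0, d_S=0, scorer=exact_scorer(1.0))
    return pq_align(T, S, cfg) is not None


def _as_target(S: TargetSequence | Iterable[str]) -> TargetSequence:
    if isinstance(S, TargetSequence):
        return S
    return TargetSequence("target", tuple(S))


def hit_from_derivation(
    T: PQTree,
    target: TargetSequence,
    d: Derivation,
    scorer: SubstitutionScorer,
) -> SearchHit:
    """Wrap a derivation as a reported hit with its score fraction."""
    return SearchHit(
        target_id=target.id,
        derivation=d,
        score_fraction=d.score / max_attainable_score(T, scorer),
    )
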