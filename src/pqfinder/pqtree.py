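"""PQ-tree data model, bracket-notation parsing, frontiers and the S-score.

A PQ-tree is a rooted ordered tree with three node kinds: P-nodes, whose
children may be permuted freely; Q-nodes, whose children may only be kept in
order or reversed as a block; and leaves, each carrying a gene-identifier
label.  The set of leaf-label sequences reachable by these legal reorderings
is the *consistent set* ``C(T)``; it is the grammar of gene orders the tree
admits.  The S-score of a tree compares ``|C(T)|`` against the number of
orders an unconstrained (flat P-node) tree over the same genes would admit —
the more constrained the tree, the higher the score.

Bracket notation: square brackets enclose the children of a Q-node, round
brackets those of a P-node, and bare whitespace-separated tokens are leaves,
e.g. ``(1609 [1653 1175 0395] 3839)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterator, Sequence

__all__ = [
    "PQNode",
    "PQTree",
    "FrontierSet",
    "SScoreReport",
    "PQTreeError",
    "ParseError",
    "CapacityError",
    "parse_pqtree",
    "serialize_pqtree",
    "frontier",
    "enumerate_consistent",
    "count_consistent_closed_form",
    "count_frontier_multiset",
    "s_score",
]

P = "P"
Q = "Q"
LEAF = "LEAF"

#: Characters that may never occur inside a leaf label.
_FORBIDDEN = set("()[]") | set(" \t\r\n")

#: Default guard on the number of frontiers materialised by enumeration.
DEFAULT_ENUMERATION_CAP = 1_000_000


class PQTreeError(ValueError):
    """Base class for structural errors in PQ-tree handling."""


class ParseError(PQTreeError):
    """Raised when bracket notation cannot be parsed."""


class CapacityError(PQTreeError):
    """Raised when an enumeration would exceed its caller-supplied cap."""


def validate_label(token: str) -> str:
    if not token or any(c in _FORBIDDEN for c in token):
        raise PQTreeError(f"invalid gene label: {token!r}")
    return token


@dataclass(frozen=True)
class PQNode:
    """A node of a PQ-tree: a P-node, a Q-node, or a labeled leaf."""

    kind: str
    label: str | None = None
    children: tuple["PQNode", ...] = ()
    span: int = field(init=False)

    def __post_init__(self) -> None:
        if self.kind == LEAF:
            if self.label is None or self.children:
                raise PQTreeError("a leaf must have a label and no children")
            validate_label(self.label)
            object.__setattr__(self, "span", 1)
        elif self.kind in (P, Q):
            if self.label is not None:
                raise PQTreeError("internal nodes carry no label")
            if len(self.children) < 2:
                raise PQTreeError(
                    f"{self.kind}-node needs >= 2 children, got {len(self.children)}"
                )
            object.__setattr__(self, "span", sum(c.span for c in self.children))
        else:
            raise PQTreeError(f"unknown node kind: {self.kind!r}")

    @property
    def is_leaf(self) -> bool:
        return self.kind == LEAF

    def leaves(self) -> Iterator["PQNode"]:
        """Yield the leaves of the subtree in left-to-right order."""
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


def leaf(label: str) -> PQNode:
    return PQNode(LEAF, label=label)


def pnode(*children: PQNode) -> PQNode:
    return PQNode(P, children=tuple(children))


def qnode(*children: PQNode) -> PQNode:
    return PQNode(Q, children=tuple(children))


@dataclass(frozen=True)
class PQTree:
    """A rooted PQ-tree together with its summary statistics.

    Attributes
    ----------
    root:
        The root node.
    m:
        Number of leaves (the span of the root).
    m_p, m_q:
        Number of P-nodes and Q-nodes.
    gamma:
        Maximum number of children over internal nodes (0 for a single leaf).
    """

    root: PQNode
    m: int = field(init=False)
    m_p: int = field(init=False)
    m_q: int = field(init=False)
    gamma: int = field(init=False)

    def __post_init__(self) -> None:
        m_p = m_q = gamma = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.kind == P:
                m_p += 1
            elif node.kind == Q:
                m_q += 1
            if not node.is_leaf:
                gamma = max(gamma, len(node.children))
                stack.extend(node.children)
        object.__setattr__(self, "m", self.root.span)
        object.__setattr__(self, "m_p", m_p)
        object.__setattr__(self, "m_q", m_q)
        object.__setattr__(self, "gamma", gamma)

    def leaves(self) -> list[PQNode]:
        return list(self.root.leaves())

    def __str__(self) -> str:
        return serialize_pqtree(self)


@dataclass(frozen=True)
class FrontierSet:
    """A set of frontiers of trees quasi-equivalent to some tree with <= d
    leaf deletions."""

    members: frozenset[tuple[str, ...]]
    d: int

    def __contains__(self, item: Sequence[str]) -> bool:
        return tuple(item) in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[tuple[str, ...]]:
        return iter(self.members)


@dataclass(frozen=True)
class SScoreReport:
    """The S-score of a tree and the two counts it is the ratio of."""

    numerator: int
    denominator: int
    s_score: float
    used_enumeration: bool


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "()[]":
            tokens.append((c, i))
            i += 1
        else:
            j = i
            while j < len(text) and not text[j].isspace() and text[j] not in "()[]":
                j += 1
            tokens.append((text[i:j], i))
            i = j
    return tokens


def parse_pqtree(text: str) -> PQTree:
    """Parse bracket notation into a :class:`PQTree`.

    Square brackets enclose a Q-node's children, round brackets a P-node's.
    A single bare token parses to a one-leaf tree.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty input")

    def parse_node(pos: int) -> tuple[PQNode, int]:
        tok, at = tokens[pos]
        if tok in "([":
            close = ")" if tok == "(" else "]"
            kind = P if tok == "(" else Q
            children: list[PQNode] = []
            pos += 1
            while True:
                if pos >= len(tokens):
                    raise ParseError(f"unbalanced bracket opened at position {at}")
                nxt, nat = tokens[pos]
                if nxt in ")]":
                    if nxt != close:
                        raise ParseError(f"mismatched bracket at position {nat}")
                    if len(children) < 2:
                        raise ParseError(
                            f"internal node at position {at} has "
                            f"{len(children)} child(ren); need >= 2"
                        )
                    return PQNode(kind, children=tuple(children)), pos + 1
                child, pos = parse_node(pos)
                children.append(child)
        if tok in ")]":
            raise ParseError(f"unexpected closing bracket at position {at}")
        try:
            return leaf(tok), pos + 1
        except PQTreeError as exc:
            raise ParseError(str(exc)) from exc

    node, pos = parse_node(0)
    if pos != len(tokens):
        raise ParseError(
            f"trailing content at position {tokens[pos][1]}: {tokens[pos][0]!r}"
        )
    return PQTree(node)


def serialize_pqtree(tree: PQTree | PQNode) -> str:
    """Serialize a tree back to bracket notation (single spaces, no trailing
    whitespace); the exact inverse of :func:`parse_pqtree`."""
    node = tree.root if isinstance(tree, PQTree) else tree

    def render(x: PQNode) -> str:
        if x.is_leaf:
            return x.label  # type: ignore[return-value]
        inner = " ".join(render(c) for c in x.children)
        return f"({inner})" if x.kind == P else f"[{inner}]"

    return render(node)


def frontier(tree: PQTree | PQNode) -> tuple[str, ...]:
    """The sequence of leaf labels read from left to right."""
    node = tree.root if isinstance(tree, PQTree) else tree
    return tuple(x.label for x in node.leaves())  # type: ignore[misc]


# ---------------------------------------------------------------------------
# Consistent-set enumeration and counting
# ---------------------------------------------------------------------------

def _enumerate_node(node: PQNode) -> set[tuple[str, ...]]:
    if node.is_leaf:
        return {(node.label,)}  # type: ignore[arg-type]
    child_sets = [sorted(_enumerate_node(c)) for c in node.children]
    out: set[tuple[str, ...]] = set()
    if node.kind == Q:
        orders = [child_sets, list(reversed(child_sets))]
    else:
        orders = [list(perm) for perm in permutations(child_sets)]
    for order in orders:
        partial: list[tuple[str, ...]] = [()]
        for cset in order:
            partial = [pre + opt for pre in partial for opt in cset]
        out.update(partial)
    return out


def _closed_form_upper_bound(node: PQNode) -> int:
    """|C(T)| ignoring duplicate-label collapses (an upper bound in general,
    exact for duplicate-free trees)."""
    if node.is_leaf:
        return 1
    sub = math.prod(_closed_form_upper_bound(c) for c in node.children)
    own = 2 if node.kind == Q else math.factorial(len(node.children))
    return own * sub


def enumerate_consistent(
    tree: PQTree, d: int = 0, cap: int = DEFAULT_ENUMERATION_CAP
) -> FrontierSet:
    """Materialise ``C_d(T)``: frontiers of all trees quasi-equivalent to
    ``T`` with up to ``d`` leaf deletions (and smoothing).

    Because reordering and deletion commute, ``C_d(T)`` equals the set of
    strings obtained by deleting at most ``d`` characters from members of
    ``C(T)``; that is how the set is generated here.

    Raises :class:`CapacityError` if the projected size exceeds ``cap``.
    """
    if d < 0:
        raise PQTreeError("d must be non-negative")
    d = min(d, tree.m)
    projected = _closed_form_upper_bound(tree.root) * sum(
        math.comb(tree.m, k) for k in range(d + 1)
    )
    if projected > cap:
        raise CapacityError(
            f"projected enumeration size {projected} exceeds cap {cap}"
        )
    base = _enumerate_node(tree.root)
    if d == 0:
        return FrontierSet(frozenset(base), 0)
    out: set[tuple[str, ...]] = set()
    for f in base:
        layer = {f}
        out |= layer
        for _ in range(d):
            layer = {
                f2[:i] + f2[i + 1:] for f2 in layer for i in range(len(f2))
            }
            out |= layer
    return FrontierSet(frozenset(out), d)


def count_consistent_closed_form(tree: PQTree) -> int:
    """``|C(T)|`` for a duplicate-free tree: ``2^{m_q} * prod |children(x)|!``
    over P-nodes ``x``.

    Raises :class:`PQTreeError` if any leaf label repeats (the closed form
    over-counts then; callers must enumerate instead).
    """
    labels = frontier(tree)
    if len(set(labels)) != len(labels):
        raise PQTreeError("tree has duplicate leaf labels; enumerate C(T) instead")
    return _closed_form_upper_bound(tree.root)


def count_frontier_multiset(tree: PQTree) -> int:
    """Number of distinct permutations of the frontier multiset:
    ``|F(T)|! / prod_l a(l,T)!`` over distinct labels ``l``."""
    labels = frontier(tree)
    counts: dict[str, int] = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    denom = math.prod(math.factorial(a) for a in counts.values())
    return math.factorial(len(labels)) // denom


def s_score(tree: PQTree, cap: int = DEFAULT_ENUMERATION_CAP) -> SScoreReport:
    """Specificity score of a tree.

    The numerator counts the gene orders an unconstrained flat P-node over the
    same leaves would admit; the denominator is ``|C(T)|``.  A more specific
    (more constrained) tree yields a higher score; a flat P-node over distinct
    genes scores exactly 1.  When labels repeat, ``|C(T)|`` is obtained by
    enumeration with deduplication rather than the closed form.
    """
    labels = frontier(tree)
    numerator = count_frontier_multiset(tree)
    has_dup = len(set(labels)) != len(labels)
    if has_dup:
        denominator = len(enumerate_consistent(tree, 0, cap))
    else:
        denominator = count_consistent_closed_form(tree)
    return SScoreReport(
        numerator=numerator,
        denominator=denominator,
        s_score=numerator / denominator,
        used_enumeration=has_dup,
    )
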