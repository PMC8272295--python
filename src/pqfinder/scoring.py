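"""Substitution scoring functions and deletion costs.

The search is governed by a substitution scoring function ``h``: for a tree
leaf label and a target-string gene, ``h`` returns the score of substituting
one for the other, or ``-inf`` when the substitution is forbidden.  Three
scorers are provided: exact identity matching, an explicit pairwise table,
and a semantic scorer built from free-text functional descriptions of gene
families (COGs), where similarity is the cosine between tf-idf bag-of-words
vectors of the two descriptions.

Deletion costs default to zero, mirroring the usual search setting in which
deletions are bounded but not penalized.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .pqtree import PQTree

__all__ = [
    "NEG_INF",
    "SubstitutionScorer",
    "ExactScorer",
    "TableScorer",
    "CogSimilarityScorer",
    "DeletionCost",
    "ScorerParams",
    "exact_scorer",
    "table_scorer",
    "cog_similarity_scorer",
    "max_attainable_score",
]

NEG_INF = float("-inf")


class SubstitutionScorer:
    """Interface for substitution scoring functions ``h``.

    ``score(tree_label, string_label)`` returns a finite real score or
    ``-inf`` when the substitution is forbidden.  ``string_alphabet`` lists
    the known target-side labels (used to compute the best attainable score
    per leaf); scorers with an open alphabet override ``best_score``.
    """

    def score(self, tree_label: str, string_label: str) -> float:
        raise NotImplementedError

    def string_alphabet(self) -> Iterable[str]:
        raise NotImplementedError

    def best_score(self, tree_label: str) -> float:
        """Highest finite score attainable by ``tree_label`` against any
        known string label; ``-inf`` if there is none."""
        best = NEG_INF
        for s in self.string_alphabet():
            v = self.score(tree_label, s)
            if v > best:
                best = v
        return best


@dataclass(frozen=True)
class ExactScorer(SubstitutionScorer):
    """Identity matching: ``match_score`` on equal labels, ``-inf`` otherwise.

    With deletion bounds set to zero this reduces the search to plain
    consistent-set membership.
    """

    match_score: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.match_score):
            raise ValueError("match_score must be finite")

    def score(self, tree_label: str, string_label: str) -> float:
        return self.match_score if tree_label == string_label else NEG_INF

    def string_alphabet(self) -> Iterable[str]:
        return ()

    def best_score(self, tree_label: str) -> float:
        return self.match_score


class TableScorer(SubstitutionScorer):
    """A scorer backed by an explicit (tree_label, string_label) -> score
    table; direction matters (tree label first).  Unlisted pairs return the
    configurable default (``-inf`` unless stated otherwise)."""

    def __init__(
        self,
        rows: Iterable[tuple[str, str, float]],
        default: float = NEG_INF,
    ) -> None:
        table: dict[tuple[str, str], float] = {}
        for t, s, v in rows:
            key = (t, s)
            if key in table:
                raise ValueError(f"duplicate substitution pair {key}")
            table[key] = float(v)
        self._table = table
        self._default = default
        self._string_labels = sorted({s for (_, s) in table})

    def score(self, tree_label: str, string_label: str) -> float:
        return self._table.get((tree_label, string_label), self._default)

    def string_alphabet(self) -> Iterable[str]:
        return self._string_labels


@dataclass(frozen=True)
class ScorerParams:
    """Constants of the semantic scorer.

    ``same_id_score`` rewards identical annotated gene families above any
    cosine value (cosine <= 1 < 1.1); ``unannotated_score`` is used when
    either family lacks a functional description; ``zero_similarity_score``
    penalizes description pairs that share no informative words; the
    ``n_stop_words`` most frequent tokens across all descriptions are
    removed before vectorization.
    """

    same_id_score: float = 1.1
    unannotated_score: float = -0.1
    zero_similarity_score: float = -0.2
    n_stop_words: int = 30
    extra_stop_words: tuple[str, ...] = ()


_TOKEN_RE = re.compile(r"[0-9a-z]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


class CogSimilarityScorer(SubstitutionScorer):
    """Semantic similarity between gene families from their functional
    descriptions.

    Each non-empty description becomes a bag-of-words vector weighted by
    tf-idf (smooth idf ``ln((1+N)/(1+df)) + 1`` by default) and normalized to
    unit Euclidean norm; the score of two distinct annotated families is the
    cosine similarity of their vectors, in [0, 1].  Identical annotated ids
    score ``same_id_score``; pairs involving an unannotated id score
    ``unannotated_score``; an exact-zero cosine is replaced by
    ``zero_similarity_score``.  Stop-words are the ``n_stop_words`` most
    frequent tokens over all descriptions (plus any explicit extras).
    """

    def __init__(
        self,
        descriptions: Mapping[str, str],
        params: ScorerParams = ScorerParams(),
        smooth_idf: bool = True,
    ) -> None:
        if not descriptions:
            raise ValueError("description table is empty")
        self.params = params
        self._annotated: dict[str, int] = {}
        docs: list[str] = []
        for cid, desc in descriptions.items():
            if desc and desc.strip():
                self._annotated[cid] = len(docs)
                docs.append(desc)
        self._known = set(descriptions)
        self._vectors: np.ndarray | None = None
        self.stop_words: frozenset[str] = frozenset(params.extra_stop_words)
        if docs:
            counts: Counter[str] = Counter()
            for doc in docs:
                counts.update(_tokenize(doc))
            top = [w for w, _ in counts.most_common(params.n_stop_words)]
            self.stop_words = self.stop_words | frozenset(top)
            vocab = sorted(set(counts) - self.stop_words)
            if vocab:
                vec = TfidfVectorizer(
                    analyzer=lambda doc: [
                        t for t in _tokenize(doc) if t not in self.stop_words
                    ],
                    vocabulary=vocab,
                    norm="l2",
                    smooth_idf=smooth_idf,
                )
                self._vectors = vec.fit_transform(docs).toarray()

    def _is_annotated(self, cid: str) -> bool:
        return cid in self._annotated

    def score(self, tree_label: str, string_label: str) -> float:
        p = self.params
        if tree_label == string_label and self._is_annotated(tree_label):
            return p.same_id_score
        if not (self._is_annotated(tree_label) and self._is_annotated(string_label)):
            return p.unannotated_score
        if self._vectors is None:
            return p.zero_similarity_score
        u = self._vectors[self._annotated[tree_label]]
        v = self._vectors[self._annotated[string_label]]
        cos = float(np.dot(u, v))
        if cos == 0.0:
            return p.zero_similarity_score
        return min(cos, 1.0)

    def string_alphabet(self) -> Iterable[str]:
        return sorted(self._known)


@dataclass(frozen=True)
class DeletionCost:
    """Per-label deletion costs: ``tree_cost`` for deleting a tree leaf (a
    missing gene), ``string_cost`` for deleting a target character (an
    intruding gene).  Both default to zero everywhere."""

    tree_table: Mapping[str, float] = field(default_factory=dict)
    string_table: Mapping[str, float] = field(default_factory=dict)
    default_tree: float = 0.0
    default_string: float = 0.0

    def __post_init__(self) -> None:
        for v in (*self.tree_table.values(), *self.string_table.values(),
                  self.default_tree, self.default_string):
            if v < 0:
                raise ValueError("deletion costs must be non-negative")

    def tree_cost(self, label: str) -> float:
        return self.tree_table.get(label, self.default_tree)

    def string_cost(self, label: str) -> float:
        return self.string_table.get(label, self.default_string)


ZERO_DELETION_COST = DeletionCost()


def exact_scorer(match_score: float = 1.0) -> ExactScorer:
    return ExactScorer(match_score)


def table_scorer(
    rows: Iterable[tuple[str, str, float]], default: float = NEG_INF
) -> TableScorer:
    return TableScorer(rows, default)


def cog_similarity_scorer(
    descriptions: Mapping[str, str], params: ScorerParams = ScorerParams()
) -> CogSimilarityScorer:
    return CogSimilarityScorer(descriptions, params)


def max_attainable_score(tree: PQTree, scorer: SubstitutionScorer) -> float:
    """The highest score any derivation of ``tree`` can reach: the sum over
    leaves of the best finite substitution score each leaf can obtain, i.e. a
    deletion-free derivation where every leaf gets its best partner.  With
    non-negative deletion costs this upper-bounds every derivation score.

    Raises ``ValueError`` if some leaf has no finite score against any label
    in the scorer's known alphabet.
    """
    total = 0.0
    for x in tree.leaves():
        best = scorer.best_score(x.label)  # type: ignore[arg-type]
        if best == NEG_INF:
            raise ValueError(
                f"leaf label {x.label!r} has no finite substitution score"
            )
        total += best
    return total
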