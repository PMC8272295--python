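"""Generators for random PQ-trees and gene-order corpora with planted hits.

The planting procedure emulates the evaluation setting of a gene-cluster
search: a frontier is sampled from the query tree by legal reorderings
(uniform child permutation at P-nodes, a fair coin flip at Q-nodes), a known
number of genes are removed (missing genes), foreign genes are inserted
(intruding genes), substitution noise may replace genes by scorer-related
labels, and the result is embedded in a random background drawn from a
disjoint alphabet so the planted occurrence is unambiguous.  Every event is
recorded in a ground-truth object whose score is recomputable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pqtree import LEAF, PQNode, PQTree, leaf, pnode, qnode
from .scoring import NEG_INF, DeletionCost, SubstitutionScorer, ZERO_DELETION_COST
from .search import TargetSequence

__all__ = [
    "TreeGenParams",
    "PlantParams",
    "GroundTruth",
    "random_pqtree",
    "sample_frontier",
    "plant_instance",
]


@dataclass(frozen=True)
class TreeGenParams:
    """Shape controls for random PQ-tree generation.

    Defaults reflect the small-to-mid range of real gene-cluster trees:
    single-digit leaf counts, maximum node degree 4, an even mix of P- and
    Q-nodes, and no label duplication unless asked for.
    """

    n_leaves: int = 6
    max_degree: int = 4
    p_node_prob: float = 0.5
    alphabet_size: int = 50
    duplicate_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.n_leaves > 1 and self.max_degree < 2:
            raise ValueError("max_degree must be >= 2 for multi-leaf trees")
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")


@dataclass(frozen=True)
class PlantParams:
    """Noise controls for planting one instance into a background string."""

    k_T: int = 0              # genes deleted from the sampled frontier
    k_S: int = 0              # foreign genes inserted into the instance
    n_background: int = 50    # total target length
    sub_noise: float = 0.0    # per-gene probability of a scored substitution
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_T, self.k_S, self.n_background) < 0:
            raise ValueError("plant parameters must be non-negative")
        if not 0.0 <= self.sub_noise <= 1.0:
            raise ValueError("sub_noise must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Everything known about a planted instance."""

    start: int                           # 1-based inclusive interval in the
    end: int                             # target containing the instance
    frontier: tuple[str, ...]            # the sampled gene order
    deleted_leaves: tuple[tuple[int, str], ...]   # (frontier pos, label)
    inserted_indices: tuple[int, ...]    # absolute target indices
    substituted: tuple[tuple[int, str, str], ...] # (abs index, old, new)
    score: float                         # planted derivation score
    del_T: int = field(init=False)
    del_S: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "del_T", len(self.deleted_leaves))
        object.__setattr__(self, "del_S", len(self.inserted_indices))


def random_pqtree(params: TreeGenParams) -> PQTree:
    """Draw a random PQ-tree: leaf counts are split recursively into 2..γ
    parts, each internal node is a P-node with probability ``p_node_prob``,
    and labels are fresh draws from the alphabet unless ``duplicate_prob``
    triggers reuse.  Deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    used: list[str] = []

    def fresh_label() -> str:
        if used and rng.random() < params.duplicate_prob:
            return used[rng.integers(len(used))]
        lab = f"g{rng.integers(params.alphabet_size):04d}"
        used.append(lab)
        return lab

    def build(n: int) -> PQNode:
        if n == 1:
            return leaf(fresh_label())
        k = int(rng.integers(2, min(params.max_degree, n) + 1))
        # random composition of n into k positive parts
        cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
        parts = np.diff(np.concatenate(([0], cuts, [n])))
        children = tuple(build(int(p)) for p in parts)
        kind_p = rng.random() < params.p_node_prob
        return pnode(*children) if kind_p else qnode(*children)

    return PQTree(build(params.n_leaves))


def sample_frontier(
    tree: PQTree, seed: int | np.random.Generator = 0
) -> tuple[str, ...]:
    """Sample a member of ``C(T)``: permute each P-node's children uniformly
    and reverse each Q-node's with probability 1/2, then read the frontier."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def walk(node: PQNode) -> list[str]:
        if node.kind == LEAF:
            return [node.label]
        children = list(node.children)
        if node.kind == "P":
            order = rng.permutation(len(children))
            children = [children[j] for j in order]
        elif rng.random() < 0.5:
            children = children[::-1]
        out: list[str] = []
        for c in children:
            out.extend(walk(c))
        return out

    return tuple(walk(tree.root))


def _finite_partners(scorer: SubstitutionScorer, label: str) -> list[str]:
    return [
        s
        for s in scorer.string_alphabet()
        if s != label and scorer.score(label, s) > NEG_INF
    ]


def plant_instance(
    tree: PQTree,
    scorer: SubstitutionScorer,
    params: PlantParams,
    delta: DeletionCost = ZERO_DELETION_COST,
    target_id: str = "synthetic",
) -> tuple[TargetSequence, GroundTruth]:
    """Embed one noisy, tree-guided instance of ``tree`` in a random
    background string and record the ground truth.

    The planted derivation maps each surviving frontier gene to itself (or
    to its substituted partner), deletes the ``k_T`` removed genes from the
    tree and the ``k_S`` inserted genes from the string; its score is the
    sum of the substitution scores minus the deletion costs, recorded in the
    ground truth.
    """
    rng = np.random.default_rng(params.seed)
    m = tree.m
    if params.k_T > m:
        raise ValueError("cannot delete more genes than the tree has leaves")
    instance_len = m - params.k_T + params.k_S
    if instance_len > params.n_background:
        raise ValueError("planted instance does not fit in the background")

    fr = sample_frontier(tree, rng)
    # delete k_T uniformly chosen frontier positions (missing genes)
    del_pos = sorted(rng.choice(m, size=params.k_T, replace=False).tolist())
    deleted = tuple((p + 1, fr[p]) for p in del_pos)
    kept = [(p + 1, fr[p]) for p in range(m) if p + 1 not in {d[0] for d in deleted}]

    # substitution noise on the surviving genes
    substituted: list[tuple[int, str, str]] = []
    noisy: list[tuple[str, str]] = []   # (original label, emitted label)
    for _, lab in kept:
        emit = lab
        if params.sub_noise > 0 and rng.random() < params.sub_noise:
            partners = _finite_partners(scorer, lab)
            if partners:
                emit = partners[rng.integers(len(partners))]
        noisy.append((lab, emit))

    # insert k_S foreign genes at uniform positions (intruding genes)
    bg_alphabet = [f"bg{j:04d}" for j in range(max(params.n_background, 1))]
    slots = sorted(
        rng.integers(0, len(noisy) + 1, size=params.k_S).tolist(), reverse=True
    )
    instance: list[tuple[str | None, str]] = [(lab, emit) for lab, emit in noisy]
    for slot in slots:
        instance.insert(slot, (None, bg_alphabet[rng.integers(len(bg_alphabet))]))

    offset = int(rng.integers(0, params.n_background - instance_len + 1))
    start = offset + 1
    end = offset + instance_len

    genes: list[str] = [
        bg_alphabet[rng.integers(len(bg_alphabet))]
        for _ in range(params.n_background)
    ]
    inserted_idx: list[int] = []
    score = 0.0
    for j, (orig, emit) in enumerate(instance):
        abs_idx = start + j
        genes[abs_idx - 1] = emit
        if orig is None:
            inserted_idx.append(abs_idx)
            score -= delta.string_cost(emit)
        else:
            score += scorer.score(orig, emit)
            if orig != emit:
                substituted.append((abs_idx, orig, emit))
    for _, lab in deleted:
        score -= delta.tree_cost(lab)

    target = TargetSequence(target_id, tuple(genes))
    truth = GroundTruth(
        start=start,
        end=end,
        frontier=fr,
        deleted_leaves=deleted,
        inserted_indices=tuple(inserted_idx),
        substituted=tuple(substituted),
        score=score,
    )
    return target, truth
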