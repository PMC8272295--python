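"""Shared fixtures: published example trees and random-instance factories."""

from __future__ import annotations

import numpy as np
import pytest

import pqfinder as pq

# Bracket strings of published example gene-cluster trees with their known
# specificity scores (COG-identifier leaves).
EXAMPLE_TREES = [
    ("[[0683 [[0411 0410] [0559 4177]]] 0583]", 22.5),
    ("(1609 [1653 1175 0395] 3839)", 10.0),
    ("[[1538 [3696 0845]] [0642 0745]]", 7.5),
    ("[[2115 1070] [4213 [1129 4214]]]", 7.5),
    ("[1960 [[2011 1135] [2141 1464]]]", 7.5),
    ("[[0596 0599] [[3485 3485] 0015]]", 7.5),
    ("[[[1129 1172 1172] 1879] 3254]", 7.5),
    ("(1609 1869 [[1129 1172] 1879] 0524)", 7.5),
    ("(0683 [0559 4177] [0411 0410] 0318)", 7.5),
    ("(3839 0673 [[0395 1175] 1653])", 5.0),
]


@pytest.fixture(scope="session")
def example_trees():
    return [(pq.parse_pqtree(text), text, score) for text, score in EXAMPLE_TREES]


def dyadic_table_scorer(rng: np.random.Generator, labels, density=0.6,
                        lo=-32, hi=65):
    """Random scorer over dyadic rationals (multiples of 1/64) with a finite
    diagonal, so that sums compare float-exactly across algorithms."""
    rows = [(l, l, float(rng.integers(1, hi)) / 64) for l in labels]
    for a in labels:
        for b in labels:
            if a != b and rng.random() < density:
                rows.append((a, b, float(rng.integers(lo, hi)) / 64))
    return pq.table_scorer(rows)


def random_instance(rng: np.random.Generator, max_leaves=8, max_n=20,
                    max_d=2, with_delta=False, duplicate_prob=0.2):
    """One random (tree, target, config) search instance, oracle-sized."""
    T = pq.random_pqtree(pq.TreeGenParams(
        n_leaves=int(rng.integers(2, max_leaves + 1)),
        max_degree=4,
        p_node_prob=float(rng.random()),
        alphabet_size=8,
        duplicate_prob=duplicate_prob,
        seed=int(rng.integers(2 ** 31)),
    ))
    alpha = [f"g{j:04d}" for j in range(8)] + ["zz"]
    n = int(rng.integers(1, max_n + 1))
    S = pq.TargetSequence(
        "t", tuple(alpha[rng.integers(len(alpha))] for _ in range(n))
    )
    labels = sorted({x.label for x in T.leaves()} | set(S.genes))
    scorer = dyadic_table_scorer(rng, labels)
    if with_delta:
        delta = pq.DeletionCost(
            tree_table={l: float(rng.integers(0, 33)) / 64 for l in labels},
            string_table={l: float(rng.integers(0, 33)) / 64 for l in labels},
        )
    else:
        delta = pq.DeletionCost()
    cfg = pq.SearchConfig(
        d_T=int(rng.integers(0, max_d + 1)),
        d_S=int(rng.integers(0, max_d + 1)),
        scorer=scorer,
        delta=delta,
    )
    return T, S, cfg
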