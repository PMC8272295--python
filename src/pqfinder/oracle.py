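"""Naive reference algorithm: enumerate the consistent set, then align.

For each frontier in ``C(T)`` and each candidate substring of the target,
solve a small bounded-deletion alignment (substitutions scored by ``h``,
deletions from the frontier and from the substring costed by ``delta``), and
take the best.  Exponential in the tree size, so useful only for small
consistent sets — as a correctness oracle for the polynomial search and as
the complexity baseline.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

from .pqtree import DEFAULT_ENUMERATION_CAP, PQTree, enumerate_consistent, frontier
from .scoring import NEG_INF
from .search import (
    CHAR_DEL,
    LEAF_DEL,
    SUB,
    MappingPair,
    SearchConfig,
    TargetSequence,
    _as_target,
    _best_entry,
)

__all__ = ["NaiveResult", "naive_align", "naive_search", "naive_mapping"]


class NaiveResult(NamedTuple):
    score: float
    s: int
    e: int
    del_T: int
    del_S: int


def _align_exact(
    F: tuple[str, ...],
    sub: tuple[str, ...],
    cfg: SearchConfig,
    d_T: int,
    d_S: int,
) -> dict[tuple[int, int], float]:
    """Best global alignment score of frontier ``F`` vs ``sub`` for every
    exact deletion-count pair ``(k_T, k_S)``; only pairs consistent with the
    two lengths are finite."""
    m, n = len(F), len(sub)
    h = cfg.scorer.score
    tdel = cfg.delta.tree_cost
    sdel = cfg.delta.string_cost
    # N[p][q][kT][kS]
    N = [
        [
            [[NEG_INF] * (d_S + 1) for _ in range(d_T + 1)]
            for _ in range(n + 1)
        ]
        for _ in range(m + 1)
    ]
    N[0][0][0][0] = 0.0
    for p in range(m + 1):
        for q in range(n + 1):
            for kT in range(d_T + 1):
                for kS in range(d_S + 1):
                    best = N[p][q][kT][kS]
                    if p >= 1 and q >= 1:
                        prev = N[p - 1][q - 1][kT][kS]
                        if prev > NEG_INF:
                            v = h(F[p - 1], sub[q - 1])
                            if v > NEG_INF and prev + v > best:
                                best = prev + v
                    if p >= 1 and kT >= 1:
                        prev = N[p - 1][q][kT - 1][kS]
                        if prev > NEG_INF:
                            v = prev - tdel(F[p - 1])
                            if v > best:
                                best = v
                    if q >= 1 and kS >= 1:
                        prev = N[p][q - 1][kT][kS - 1]
                        if prev > NEG_INF:
                            v = prev - sdel(sub[q - 1])
                            if v > best:
                                best = v
                    N[p][q][kT][kS] = best
    return {
        (kT, kS): N[m][n][kT][kS]
        for kT in range(d_T + 1)
        for kS in range(d_S + 1)
        if N[m][n][kT][kS] > NEG_INF
    }


def _frontier_set(T: PQTree, cap: int) -> list[tuple[str, ...]]:
    return sorted(enumerate_consistent(T, 0, cap).members)


def _align_counts(
    frontiers: list[tuple[str, ...]],
    sub: tuple[str, ...],
    cfg: SearchConfig,
    d_T: int,
    d_S: int,
) -> dict[tuple[int, int], float]:
    out: dict[tuple[int, int], float] = {}
    for F in frontiers:
        for key, sc in _align_exact(F, sub, cfg, d_T, d_S).items():
            if sc > out.get(key, NEG_INF):
                out[key] = sc
    return out


def naive_align(
    T: PQTree,
    S: TargetSequence | Iterable[str],
    cfg: SearchConfig,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> float | None:
    """Best score of deriving ``T`` to the whole of ``S'`` by brute force:
    max over frontiers in ``C(T)`` of the bounded-deletion alignment score.
    ``None`` when no finite alignment exists."""
    S = _as_target(S)
    m = T.m
    d_T = min(cfg.d_T, m)
    d_S = min(cfg.d_S, S.n)
    if S.n < m - d_T or S.n > m + d_S:
        return None
    counts = _align_counts(_frontier_set(T, cap), S.genes, cfg, d_T, d_S)
    if not counts:
        return None
    return max(counts.values())


def naive_search(
    T: PQTree,
    S: TargetSequence | Iterable[str],
    cfg: SearchConfig,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> NaiveResult | None:
    """Brute-force PQ-tree search: best alignment over every substring of
    ``S`` with admissible length, ties broken exactly as the dynamic
    program's (score, then fewest string deletions, fewest tree deletions,
    smallest start)."""
    S = _as_target(S)
    m, n = T.m, S.n
    d_T = min(cfg.d_T, m)
    d_S = min(cfg.d_S, n)
    frontiers = _frontier_set(T, cap)
    entries = []
    min_len = max(1, m - d_T)
    max_len = m + d_S
    for i in range(1, n + 1):
        for length in range(min_len, min(max_len, n - i + 1) + 1):
            sub = S.substring(i, i + length - 1)
            for (kT, kS), sc in _align_counts(
                frontiers, sub, cfg, d_T, d_S
            ).items():
                if m - kT + kS == length:
                    entries.append((i, kT, kS, sc))
    best = _best_entry(entries)
    if best is None:
        return None
    i, kT, kS, sc = best
    return NaiveResult(sc, i, i + (m - kT + kS) - 1, kT, kS)


def naive_mapping(
    T: PQTree,
    S: TargetSequence | Iterable[str],
    s: int,
    k_T: int,
    k_S: int,
    cfg: SearchConfig,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> tuple[MappingPair, ...]:
    """Reconstruct a best one-to-one mapping for the substring starting at
    ``s`` with exactly ``(k_T, k_S)`` deletions, by brute force.

    The first frontier (in sorted order) attaining the best score is traced;
    at score ties within the alignment, substitution is preferred over tree
    deletion over string deletion.  Leaves with repeated labels are assigned
    tree frontier positions left to right.
    """
    S = _as_target(S)
    m = T.m
    length = m - k_T + k_S
    sub = S.substring(s, s + length - 1)
    frontiers = _frontier_set(T, cap)
    target_counts = _align_counts(frontiers, sub, cfg, k_T, k_S)
    if (k_T, k_S) not in target_counts:
        raise ValueError("no feasible alignment for the requested entry")
    goal = target_counts[(k_T, k_S)]
    for F in frontiers:
        counts = _align_exact(F, sub, cfg, k_T, k_S)
        if counts.get((k_T, k_S)) == goal:
            return _trace_alignment(T, F, sub, s, k_T, k_S, cfg)
    raise AssertionError("unreachable: some frontier attains the maximum")


def _trace_alignment(
    T: PQTree,
    F: tuple[str, ...],
    sub: tuple[str, ...],
    s: int,
    k_T: int,
    k_S: int,
    cfg: SearchConfig,
) -> tuple[MappingPair, ...]:
    m, n = len(F), len(sub)
    h = cfg.scorer.score
    tdel = cfg.delta.tree_cost
    sdel = cfg.delta.string_cost
    full = _align_exact(F, sub, cfg, k_T, k_S)

    # recompute the full table once more to walk it
    d_T, d_S = k_T, k_S
    N = [
        [
            [[NEG_INF] * (d_S + 1) for _ in range(d_T + 1)]
            for _ in range(n + 1)
        ]
        for _ in range(m + 1)
    ]
    N[0][0][0][0] = 0.0
    for p in range(m + 1):
        for q in range(n + 1):
            for kT in range(d_T + 1):
                for kS in range(d_S + 1):
                    best = N[p][q][kT][kS]
                    if p >= 1 and q >= 1 and N[p - 1][q - 1][kT][kS] > NEG_INF:
                        v = h(F[p - 1], sub[q - 1])
                        if v > NEG_INF:
                            best = max(best, N[p - 1][q - 1][kT][kS] + v)
                    if p >= 1 and kT >= 1 and N[p - 1][q][kT - 1][kS] > NEG_INF:
                        best = max(best, N[p - 1][q][kT - 1][kS] - tdel(F[p - 1]))
                    if q >= 1 and kS >= 1 and N[p][q - 1][kT][kS - 1] > NEG_INF:
                        best = max(best, N[p][q - 1][kT][kS - 1] - sdel(sub[q - 1]))
                    N[p][q][kT][kS] = best

    # assign tree frontier positions to the (possibly repeated) labels of F
    tree_positions: dict[str, list[int]] = {}
    for pos, lab in enumerate(frontier(T), start=1):
        tree_positions.setdefault(lab, []).append(pos)
    taken = {lab: 0 for lab in tree_positions}

    def claim(lab: str) -> int:
        idx = taken[lab]
        taken[lab] += 1
        return tree_positions[lab][idx]

    steps: list[tuple[str, int, int]] = []  # (kind, p, q) in forward order
    p, q, kT, kS = m, n, k_T, k_S
    assert N[p][q][kT][kS] == full[(k_T, k_S)]
    while p > 0 or q > 0:
        cur = N[p][q][kT][kS]
        if p >= 1 and q >= 1 and N[p - 1][q - 1][kT][kS] > NEG_INF:
            v = h(F[p - 1], sub[q - 1])
            if v > NEG_INF and N[p - 1][q - 1][kT][kS] + v == cur:
                steps.append((SUB, p, q))
                p, q = p - 1, q - 1
                continue
        if p >= 1 and kT >= 1 and N[p - 1][q][kT - 1][kS] - tdel(F[p - 1]) == cur:
            steps.append((LEAF_DEL, p, q))
            p, kT = p - 1, kT - 1
            continue
        steps.append((CHAR_DEL, p, q))
        q, kS = q - 1, kS - 1
    steps.reverse()
    pairs: list[MappingPair] = []
    for kind, p, q in steps:
        if kind == SUB:
            pairs.append(MappingPair(SUB, claim(F[p - 1]), F[p - 1], s + q - 1))
        elif kind == LEAF_DEL:
            pairs.append(MappingPair(LEAF_DEL, claim(F[p - 1]), F[p - 1]))
        else:
            pairs.append(MappingPair(CHAR_DEL, string_index=s + q - 1))
    return tuple(
        sorted(
            pairs,
            key=lambda pr: (
                pr.string_index if pr.string_index is not None else 0,
                pr.leaf_pos if pr.leaf_pos is not None else 0,
            ),
        )
    )
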