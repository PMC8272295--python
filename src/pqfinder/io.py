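"""File formats, run configuration and the search driver.

Formats
-------
Gene orders
    FASTA-like text: a ``>`` header line with the record id, followed by one
    or more lines of whitespace-separated gene identifier tokens.
PQ-tree files
    One bracket-notation tree per line; ``#`` comment lines ignored.
Score table
    TSV with a header row and columns ``tree_label``, ``string_label``,
    ``score`` (direction matters: tree label first).
Description table
    TSV with a header row and columns ``id``, ``description``; empty
    descriptions mark unannotated gene families.
Deletion-cost table
    TSV with a header row and columns ``kind`` (``tree`` or ``string``),
    ``label``, ``cost``.
Hit report
    TSV (and mirrored JSON records) with one row per reported substring:
    target id, 1-based inclusive interval, score, score fraction, deletion
    counts and the one-to-one mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import oracle as _oracle
from .pqtree import PQTree, parse_pqtree, s_score
from .scoring import (
    DeletionCost,
    SubstitutionScorer,
    ZERO_DELETION_COST,
    cog_similarity_scorer,
    exact_scorer,
    max_attainable_score,
    table_scorer,
)
from .search import (
    Derivation,
    SearchConfig,
    SearchHit,
    TargetSequence,
    pq_search,
)

__all__ = [
    "read_gene_orders",
    "write_gene_orders",
    "read_trees",
    "read_score_table",
    "read_descriptions",
    "read_deletion_costs",
    "build_scorer",
    "RunConfig",
    "run_search",
    "hits_to_dataframe",
    "write_hits",
]

HIT_COLUMNS = [
    "target_id", "start", "end", "score", "score_fraction",
    "del_T", "del_S", "mapping",
]


def read_gene_orders(path: str | Path) -> list[TargetSequence]:
    """Parse a FASTA-like gene-order file into target sequences."""
    records: list[TargetSequence] = []
    seen: set[str] = set()
    current_id: str | None = None
    tokens: list[str] = []

    def flush() -> None:
        nonlocal current_id, tokens
        if current_id is None:
            return
        if not tokens:
            raise ValueError(f"empty record: {current_id!r}")
        records.append(TargetSequence(current_id, tuple(tokens)))
        current_id, tokens = None, []

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            rid = line[1:].strip()
            if not rid:
                raise ValueError(f"malformed header on line {lineno}")
            if rid in seen:
                raise ValueError(f"duplicate record id {rid!r} on line {lineno}")
            seen.add(rid)
            current_id = rid
        else:
            if current_id is None:
                raise ValueError(f"gene tokens before any header (line {lineno})")
            tokens.extend(line.split())
    flush()
    return records


def write_gene_orders(path: str | Path, records: Iterable[TargetSequence]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{' '.join(rec.genes)}\n")


def read_trees(path: str | Path) -> list[PQTree]:
    """One bracket-notation tree per line; '#' comment lines ignored."""
    trees = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            trees.append(parse_pqtree(line))
    return trees


def read_score_table(path: str | Path):
    df = pd.read_csv(path, sep="\t", dtype={"tree_label": str, "string_label": str})
    missing = {"tree_label", "string_label", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    return table_scorer(
        list(df[["tree_label", "string_label", "score"]].itertuples(index=False))
    )


def read_descriptions(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"id", "description"} - set(df.columns)
    if missing:
        raise ValueError(f"description table missing columns: {sorted(missing)}")
    ids = df["id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in description table")
    return dict(zip(ids, df["description"].tolist()))


def read_deletion_costs(path: str | Path) -> DeletionCost:
    df = pd.read_csv(path, sep="\t", dtype={"kind": str, "label": str})
    missing = {"kind", "label", "cost"} - set(df.columns)
    if missing:
        raise ValueError(f"deletion-cost table missing columns: {sorted(missing)}")
    tree = {r.label: float(r.cost) for r in df.itertuples() if r.kind == "tree"}
    string = {r.label: float(r.cost) for r in df.itertuples() if r.kind == "string"}
    return DeletionCost(tree_table=tree, string_table=string)


def build_scorer(spec: str) -> SubstitutionScorer:
    """Build a scorer from its CLI spec: ``exact``, ``exact:<score>``,
    ``table:<path>`` or ``cog:<path>``."""
    if spec == "exact":
        return exact_scorer(1.0)
    kind, _, arg = spec.partition(":")
    if kind == "exact" and arg:
        return exact_scorer(float(arg))
    if kind == "table":
        return read_score_table(arg)
    if kind == "cog":
        return cog_similarity_scorer(read_descriptions(arg))
    raise ValueError(f"unknown scorer spec: {spec!r}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one search run.

    Defaults mirror the plasmid-search setting: one allowed missing gene
    (``d_T=1``), up to three intruding genes (``d_S=3``), and acceptance of
    derivations scoring above 0.75 of the query's best attainable score.
    ``strict`` is the conservative preset: identity matching only and no
    deletions at all.
    """

    tree: str | Path = ""
    targets: str | Path = ""
    scorer: str = "exact"
    d_T: int = 1
    d_S: int = 3
    threshold: float = 0.75
    delta: str | Path | None = None
    engine: str = "dp"
    strict: bool = False
    best_per_target: bool = False
    seed: int = 0
    out_tsv: str | Path | None = None
    out_json: str | Path | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.d_T < 0 or self.d_S < 0:
            raise ValueError("deletion bounds must be non-negative")
        if self.engine not in ("dp", "naive"):
            raise ValueError("engine must be 'dp' or 'naive'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _load_tree(source: str | Path) -> PQTree:
    text = str(source)
    if any(b in text for b in "([") or not Path(text).exists():
        return parse_pqtree(text)
    trees = read_trees(text)
    if len(trees) != 1:
        raise ValueError(f"expected exactly one tree in {text}, got {len(trees)}")
    return trees[0]


def _search_one_target(
    tree: PQTree,
    target: TargetSequence,
    cfg: SearchConfig,
    engine: str,
) -> list[Derivation]:
    """Best derivation per substring (grouped over deletion-count combos),
    via either engine."""
    per_interval: dict[tuple[int, int], tuple[tuple, Derivation]] = {}

    def consider(d: Derivation) -> None:
        key = (d.s, d.e)
        rank = (-d.score, d.del_S, d.del_T)
        old = per_interval.get(key)
        if old is None or rank < old[0]:
            per_interval[key] = (rank, d)

    if engine == "dp":
        _, all_d = pq_search(tree, target, cfg, report_all=True)
        for d in all_d:
            consider(d)
    else:
        m, n = tree.m, target.n
        d_T = min(cfg.d_T, m)
        d_S = min(cfg.d_S, n)
        frontiers = _oracle._frontier_set(tree, cap=10**6)
        for i in range(1, n + 1):
            for length in range(max(1, m - d_T), min(m + d_S, n - i + 1) + 1):
                sub = target.substring(i, i + length - 1)
                counts = _oracle._align_counts(frontiers, sub, cfg, d_T, d_S)
                for (kT, kS), sc in counts.items():
                    if m - kT + kS != length:
                        continue
                    mapping = _oracle.naive_mapping(tree, target, i, kT, kS, cfg)
                    consider(Derivation(i, i + length - 1, kT, kS, sc, mapping))
    return [d for _, d in sorted(per_interval.values(), key=lambda t: (t[1].s, t[1].e))]


def run_search(cfg: RunConfig, log=None) -> list[SearchHit]:
    """Run one full search: load inputs, search every target, report every
    substring whose best derivation reaches the score threshold."""
    tree = _load_tree(cfg.tree)
    scorer = exact_scorer(1.0) if cfg.strict else build_scorer(cfg.scorer)
    delta = read_deletion_costs(cfg.delta) if cfg.delta else ZERO_DELETION_COST
    d_T, d_S = (0, 0) if cfg.strict else (cfg.d_T, cfg.d_S)
    search_cfg = SearchConfig(d_T=d_T, d_S=d_S, scorer=scorer, delta=delta)
    targets = read_gene_orders(cfg.targets)

    if log is not None:
        rep = s_score(tree)
        log(
            f"query tree: m={tree.m} m_p={tree.m_p} m_q={tree.m_q} "
            f"gamma={tree.gamma} S-score={rep.s_score:g}"
        )

    best_attainable = max_attainable_score(tree, scorer)
    cutoff = cfg.threshold * best_attainable
    hits: list[SearchHit] = []
    for target in targets:
        target_hits = [
            SearchHit(target.id, d, d.score / best_attainable)
            for d in _search_one_target(tree, target, search_cfg, cfg.engine)
            if d.score >= cutoff
        ]
        if cfg.best_per_target and target_hits:
            target_hits = [
                max(
                    target_hits,
                    key=lambda h: (
                        h.derivation.score,
                        -h.derivation.del_S,
                        -h.derivation.del_T,
                        -h.derivation.s,
                    ),
                )
            ]
        hits.extend(target_hits)

    if cfg.out_tsv:
        write_hits(cfg.out_tsv, hits, fmt="tsv")
    if cfg.out_json:
        write_hits(cfg.out_json, hits, fmt="json")
    return hits


def hits_to_dataframe(hits: Sequence[SearchHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        d = h.derivation
        mapping = ";".join(str(p) for p in d.mapping) if d.mapping else ""
        rows.append(
            {
                "target_id": h.target_id,
                "start": d.s,
                "end": d.e,
                "score": d.score,
                "score_fraction": h.score_fraction,
                "del_T": d.del_T,
                "del_S": d.del_S,
                "mapping": mapping,
            }
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits(path: str | Path, hits: Sequence[SearchHit], fmt: str = "tsv") -> None:
    df = hits_to_dataframe(hits)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        Path(path).write_text(json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
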