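# pqfinder

Approximate search for **known gene clusters** in new genomes, with the
cluster's admissible gene orders represented as a **PQ-tree**.

Groups of genes that stay co-located across many genomes (gene clusters,
often operons) are rearranged, eroded and invaded as genomes evolve — and
plasmids in particular shuffle chromosomal clusters aggressively. A PQ-tree
trained from the known gene orders of a cluster captures which rearrangements
are biologically plausible: the children of a **P-node** may appear in any
order, the children of a **Q-node** only in left-to-right or right-to-left
order, and leaves carry gene-family identifiers (e.g. COG ids). `pqfinder`
searches a target gene-order string for substrings that can be *derived*
from the query tree via

* tree-constrained rearrangements (P-node permutations, Q-node reversals),
* scored gene-to-gene **substitutions** `h(σ_t, σ_s)` (identity, a score
  table, or semantic tf-idf/cosine similarity of functional descriptions),
* up to `d_T` deletions from the tree (missing genes) and `d_S` deletions
  from the string (intruding genes), optionally costed by `δ`.

## The algorithm

For a tree with `m` leaves, `m_p` P-nodes, `m_q` Q-nodes and maximum degree
`γ`, the search fills a table `A[x, i, k_T, k_S]` — the best score of
deriving the subtree at node `x` to the substring starting at `i` with
exactly `k_T` tree deletions and `k_S` string deletions (its length is
forced to `span(x) − k_T + k_S`). Internal nodes are solved by a subset
dynamic program over children (P-nodes) or a two-orientation bounded-gap
alignment (Q-nodes), giving `O(n γ d_T² d_S² (m_p·2^γ + m_q))` time overall
— polynomial whenever the node degree is bounded, versus the brute-force
`O(2^{m_q} (γ!)^{m_p} · …)` enumeration, which is also implemented here as
an independent oracle (`--engine naive`).

The **S-score** ranks query trees by specificity: `|C(T̃)| / |C(T)|`, where
`C(T)` is the set of gene orders the tree admits and `T̃` is the flat
P-node over the same genes. Without duplicated genes
`|C(T)| = 2^{m_q} · ∏_{P-nodes} |children|!` and `|C(T̃)| = m!`; with
duplications `C(T)` is enumerated and deduplicated, and
`|C(T̃)| = m! / ∏_ℓ a(ℓ)!` over label multiplicities.

## Worked example

```sh
$ pqfinder sscore "[[0683 [[0411 0410] [0559 4177]]] 0583]" \
                  "[[0596 0599] [[3485 3485] 0015]]"
tree	numerator	denominator	s_score
[[0683 [[0411 0410] [0559 4177]]] 0583]	720	32	22.5
[[0596 0599] [[3485 3485] 0015]]	60	8	7.5
```

The first query (an amino-acid transport cluster, six genes, all-Q
topology) admits only 32 of the 720 = 6! conceivable gene orders — a highly
specific query (S-score 22.5). The second contains a duplicated family
(3485), so its consistent set is enumerated with deduplication: 8 distinct
orders out of 60 distinct permutations of the multiset, S-score 7.5.

```sh
$ pqfinder simulate --tree "(A B [C D E])" --replicates 3 --n-background 20 \
      --seed 5 --out corpus.txt --truth truth.json
$ pqfinder search "(A B [C D E])" --targets corpus.txt --strict
target_id	start	end	score	score_fraction	del_T	del_S	mapping
sim000	13	17	5.0	1.0	0	0	C@3>13;D@4>14;E@5>15;A@1>16;B@2>17
sim001	11	15	5.0	1.0	0	0	A@1>11;B@2>12;E@5>13;D@4>14;C@3>15
sim002	7	11	5.0	1.0	0	0	B@2>7;A@1>8;E@5>9;D@4>10;C@3>11
```

Each row is one accepted instance: its 1-based interval in the target, the
derivation score, the fraction of the query's best attainable score, the
deletion counts, and the leaf-to-gene mapping (`C@3>13` = the 3rd leaf,
gene family C, maps to target position 13). In replicate `sim000` the
search correctly recognises the planted order `C D E A B` — a legal
rearrangement of the query (the P-node permutes `A`, `B` and the Q-block)
that never has to be listed explicitly.

Defaults for a sensitive search mirror the plasmid-survey setting:
`--dt 1 --ds 3 --threshold 0.75` with the semantic scorer
(`--scorer cog:descriptions.tsv`); `--strict` is the conservative preset
(identity matching, no deletions).

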