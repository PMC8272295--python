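# Methods

## Model

A query gene cluster is represented as a PQ-tree `T`: leaves carry
gene-family identifiers (COG ids in practice; any whitespace-free token
without brackets is accepted), a P-node admits every permutation of its
children, and a Q-node admits only the written order or its reversal. The
*frontier* `F(T)` is the left-to-right leaf-label sequence; the *consistent
set* `C(T)` is the set of frontiers of all trees obtainable by legal
reorderings. Deletions generalize this to quasi-consistency: `C_d(T)`
additionally allows up to `d` leaf deletions (with smoothing of emptied
internal nodes, which is not counted). Because reordering and deletion
commute, `C_d(T)` is generated here as "delete ≤ d characters from members
of `C(T)`", which is how the enumeration module materialises it.

A *derivation* of a subtree to a substring `S[s:e]` is a one-to-one mapping
whose pairs are substitutions `(leaf, character)` with finite score
`h(label, σ)`, character deletions (intruding genes) and leaf deletions
(missing genes); applying the substitutions and deletions to `S[s:e]` must
give a member of `C_{del_T}(T)`. Its score is the sum of substitution
scores minus the deletion costs `δ`. The derived length is structurally
`span(x) − k_T + k_S`, so deletion counts per table entry are exact, not
bounds.

## Search algorithm

The main table `A[x, i, k_T, k_S]` is filled over the tree in postorder.
Leaves are initialized directly: a deleted leaf derives `k_S` deleted
characters at score `−δ`-cost; a kept leaf maps one character of the window
`S[i : i+k_S]` (the best-scoring one) and deletes the rest. Entries whose
deletion counts are inconsistent with the window (`k_T > span`,
`k_S > length`, end beyond the target, negative length) are invalid and
stay `−∞`.

**P-nodes** are solved by a subset dynamic program: `P[C, k_T, k_S]` is the
best partial derivation that uses exactly the child subset `C` to a prefix
of the window. The last character of that prefix is either deleted
(`P[C, k_T, k_S−1] − δ`) or consumed by the derivation of one child in `C`,
looked up in the child's already-computed table entries at the matching end
point. Whole-child deletions need no explicit case: they surface through
the initialization entries (`prefix length 0, k_S = 0` scores the summed
leaf-deletion cost), reached when the remaining budget equals the remaining
subset's span. Subsets are processed in ascending size, then ascending
`k_S`. Cost per node and start index: `O(d_T² d_S² γ 2^γ)`.

**Q-nodes** force children to be consumed in the written or the reversed
order, so each orientation reduces to a bounded-gap alignment over the
child sequence: `Q[j, k_T, k_S]` covers the first `j` children in
orientation order, with cases (a) trailing character deleted, (b) child `j`
derives a suffix of the prefix, (c) child `j` wholly deleted. The base row
`Q[0, 0, k_S]` chains leading character deletions. The two orientations are
computed independently and the maximum taken (ties prefer left-to-right).
Cost: `O(d_T² d_S² γ)` per node and start index. This recurrence is this
package's construction, chosen as the ordered analogue of the P-node
recursion; it is validated exhaustively against the brute-force oracle
rather than against a published formula.

The best hit maximizes the root entry over all starts and deletion counts;
ties minimize string deletions, then tree deletions, then the start index,
and within an entry the first-written recursion case wins — output is fully
deterministic. Traceback re-runs the per-node table for the nodes on the
winning path (cheap: once per node) and emits the mapping; the mapping's
recomputed score equals the table score exactly.

Deletion penalties default to zero, matching the usual search setting in
which deletions are bounded but free. When a cost table is supplied, `δ` is
subtracted at each point where a deletion enters: leaf initialization, the
char-deletion cases, and whole-child deletion. With `δ ≡ 0` the recurrences
reduce exactly to the unpenalized algorithm.

## Scorers

* `exact` — identity matching; with zero deletion bounds this reduces the
  search to consistent-set membership.
* `table` — explicit directional `(tree label, string label) → score` TSV.
* `cog` — semantic similarity from functional descriptions. Descriptions
  are lower-cased, split on non-alphanumeric characters, stripped of the 30
  most frequent tokens (configurable, with an explicit-override list), and
  vectorized with tf-idf (`idf(t) = ln((1+N)/(1+df(t))) + 1`, vectors
  normalized to unit Euclidean norm, via scikit-learn); the score of two
  distinct annotated families is the cosine of their vectors, in [0, 1].
  Identical annotated ids score 1.1 (above any cosine), pairs involving an
  unannotated id score −0.1, and an exact-zero cosine is penalized to −0.2.
  The three constants and the cosine range are fixed; the numeric cosine
  values depend on the tf-idf dialect and stop-word list and are therefore
  implementation-defined.

The acceptance threshold compares a hit's score to the query's *best
attainable score*: the sum over leaves of each leaf's best finite
substitution score (a deletion-free upper bound whenever `δ ≥ 0`). The
sensitive-search defaults are `d_T = 1`, `d_S = 3`, threshold 0.75; the
`--strict` preset (identity scorer, no deletions) is the conservative
benchmark mode.

## S-score

Specificity of a query: `|C(T̃)| / |C(T)|` with `T̃` the flat P-node over
the same leaves. Duplicate-free trees use the closed forms
(`2^{m_q} · ∏ |children|!` and `m!`); trees with repeated labels enumerate
`C(T)` with set semantics and count distinct frontier permutations
(`m!/∏ a(ℓ)!`). Enumeration refuses to materialise more than a
caller-supplied cap (default 10⁶ frontiers) and reports a capacity error
instead of exhausting memory. Two-child nodes keep their written kind when
round-tripping; a 2-child P contributes `2! = 2`, the same factor as a
2-child Q, so S-scores are unaffected by that choice.

## Oracle

The naive algorithm enumerates `C(T)` and solves a four-index
bounded-deletion alignment (frontier position × string position × exact
deletion counts) for every frontier and every admissible substring, with
the same operation set and tie-break as the search DP so that scores and
intervals are directly comparable. It is exponential in tree size and
intended only for small consistent sets; the `--engine naive` flag runs the
whole search pipeline through it for cross-checking.

## Synthetic data

The generator emulates the evaluation setting of a cluster search. Random
trees: leaf counts split recursively into 2–γ parts (default γ = 4), each
internal node P with probability 0.5, labels fresh unless a duplication
probability triggers reuse — matching the small-to-mid range of real
cluster trees (single-digit leaf counts). Planting: a frontier is sampled
by uniform P-node permutation and fair Q-node coin flips (uniform over node
operations, not over `C(T)`, which differ only when labels repeat — membership
is what the tests rely on), `k_T` genes are removed, `k_S` foreign genes
inserted, optional substitution noise applied using scorer-related labels,
and the instance is embedded at a uniform offset in a background drawn from
a disjoint alphabet (default length 50) so the planted occurrence is
unambiguous. The ground truth records every event and a recomputable
planted score.

What this does *not* emulate: real gene-content biases, tandem
duplications, strand/orientation, correlated intruders, or homology noise
between background and query families. Passing the planted-recovery tests
therefore shows algorithmic correctness under the stated noise model, not
biological sensitivity on real replicons.

## Numerical and design choices

* All scores are IEEE doubles; forbidden substitutions are `−∞`. Tests use
  dyadic rational scores (multiples of 1/64) so cross-algorithm equalities
  are exact.
* Coordinates are 1-based inclusive everywhere; an empty derived string is
  encoded as `e = s − 1`. Zero-length derivations are never reported as
  search hits.
* `d_T` is clipped to the leaf count and `d_S` to the target length.
* The full 4-D main table is kept in memory (`O(d_T d_S m' n)` floats);
  per-node tables are transient and re-derived during traceback.
* Problem sizes in the test and acceptance runs — trees of up to 8 leaves,
  targets up to length 20, deletion bounds up to 2, 500 oracle-comparison
  instances, 100 planted replicates — were chosen so that the brute-force
  oracle side stays exhaustive while the whole suite completes in about a
  minute.

## Known limitations

* Tree construction from gene-order sets is out of scope; queries are read
  in bracket notation.
* The oracle (and hence the S-score denominator for duplicated trees) is
  limited by the enumeration cap.
* The semantic scorer's cosine values are reproducible within this package
  but not guaranteed to match other tf-idf dialects.
* All above-threshold (possibly overlapping) substrings are reported;
  `--best-per-target` keeps one hit per record.
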