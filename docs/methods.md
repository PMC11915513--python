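# Methods

## Model

A query `Q` is split into `p` parts; a search scheme is a set of
searches `(π, L, U)` where `π` orders the parts under the connectivity
property (each next part extends the contiguous matched block by one on
the left or right, so the search maps onto left/right extensions of a
bidirectional FM-index) and `L`, `U` are cumulative error bounds checked
as each part completes. An error configuration `(e_0, …, e_{p−1})`
assigns errors to parts; a search covers it when every prefix sum along
`π` lies within `[L_t, U_t]`. Completeness of a scheme guarantees
lossless search: every way of spreading at most `k` errors over the
parts is admitted by some search.

### Error-configuration modes

Configurations are enumerated in two modes. The literal definition fixes
the total at exactly `k`; published per-search coverage sets, however,
include configurations with fewer errors, and losslessness for distance
*at most* `k` requires covering them. Completeness therefore defaults to
**at-most** mode (all sums `0..k`); **exact** mode is available for the
literal definition. Enumeration is capped at 5·10⁶ configurations by
default; the cap is an explicit argument everywhere it matters.

## Constructions

All constructions are verified valid and complete by enumeration in the
test suite (k ≤ 6 for every strategy, k ≤ 8 for the heuristic at
`p = k+2`, Monte-Carlo spot checks for k ≤ 15).

* **backtracking(k)** — one search, one part, bounds `0..k`.
* **pigeonhole(k)** — `p = k+1`; search `i` seeds part `i` exactly
  (upper bound 0), then allows up to `k` errors while extending left
  first, then right. Coverage sets overlap, so the scheme is redundant.
* **pigeonhole_opt(k)** — same orders; search `i` additionally demands
  at least one error in every part left of the seed (cumulative lower
  bound `1, 2, …, i` while extending left) and caps the upper bound at
  `k−i+1` at the first left part, growing by one per part up to `k`.
  Coverage sets are disjoint for `k ≤ 2`; for `k ≥ 3` some overlap
  remains.
* **suffix_filter(k)** — `p = k+1`; search `i` seeds part `i`, extends
  right under the strong-match staircase (at most `t` cumulative errors
  after the `t`-th right step, capped at `k`), then extends left with
  upper bound `k` and a cumulative lower bound of 1: an error-free left
  extension would already have been found by an earlier search. The
  staircase upper bounds follow from the strong-match criterion; the
  left-side lower bound of exactly 1 is the choice that reproduces the
  published per-search coverage sets for `k = 2`.
* **zero_one_star(k)** — `p = k+2`; one search per pair (start part `a`,
  block length `j`): part `a` exact, the next `j` parts with exactly one
  error each (lower = upper along the staircase), part `a+j+1` exact
  again, the remaining `k−j` errors free in the remaining parts. The
  full triangular family has `(k+1)(k+2)/2` searches; this library emits
  it in full (for `k = 2`: six searches).
* **zero_one_star_opt(k)** — merges all searches sharing a start part
  (they have identical orders) by elementwise min of lower and max of
  upper bounds, giving `k+1` searches; the merge widens the coverage of
  each search (extra search paths) in exchange for fewer searches.

### The matrix heuristic

`heuristic(k, p)` (requires `p > k`) emits `k+1` searches. Search `i`
has order `(i, …, p−1, i−1, …, 0)` and lower bounds
`(0 ×(p−i−1), (k−i) ×(i+1))`. Upper bounds are read off a
`(k+1) × p` matrix `M`: the top-left `k × k` block starts as
`m[j][i] = (j−i) mod k`, the bottom row of that block is `k`, and the
columns `i ≥ k` hold `k−j`. Each row must be non-increasing left of its
diagonal entry and non-decreasing right of it; an adjustment step
repeatedly finds the leftmost column breaking this and rearranges its
permutable entries (rows `0..k−1`, diagonal excluded). The upper bound
of search `i` is then `U_i[t] = min(L_i[t−1] + M[i][π_i[t]], k)`.

Two points were genuinely open and are this package's own choices:

* **Block formula.** The construction description and its worked example
  disagree on the top-left block (`(j+i) mod k` vs. the printed matrix);
  only `(j−i) mod k` reproduces the printed matrix for `k = 3`, so the
  example wins. The two coincide for `k = 2`.
* **Column rearrangement tie-break.** Many rearrangements satisfy the
  row conditions locally, but they are not equivalent downstream: taking
  the lexicographically first feasible one produces an *incomplete*
  scheme at `k = 4, p = 5`, and reverse-lexicographic fails at
  `k = 5, p = 6`. The rearrangement used places the largest values above
  the diagonal in descending order and the remainder below in ascending
  order — the pattern the construction's own worked cases settle into
  (each column reading `k−1, k−2, …` above the diagonal and `1, 2, …`
  below). With this rule the adjustment reproduces the published `k = 3`
  matrix verbatim and yields valid, complete schemes for every tested
  `(k, p)` (exhaustively `k ≤ 6` at `p = k+1..k+3` and `k ≤ 8` at
  `p = k+2`; sampled for `k ≤ 15`). A lex-largest feasible arrangement
  (computed greedily with a matching-feasibility check rather than by
  factorial enumeration) is the fallback, and the iteration carries a
  budget of `10·k·p + 100` column fixes; in practice it terminates
  within a handful (checked up to `k = 64`).

## Node count

For a search with bounds inflated to character level, the dynamic
program `n(l, d) = n(l−1, d) + b·n(l−1, d−1)` (with `n(0,0) = 1` and
states outside `[lo_l, hi_l]` zeroed) counts trie nodes per level;
the node count is the sum over all levels and searches, an exact integer
computed in arbitrary precision.

* **Inflation.** Within the `t`-th searched part the upper bound is
  `U_t`; under Hamming distance it additionally cannot exceed the
  previous level's bound plus one (each character contributes at most
  one error). The lower bound `L_t` applies at the part's final
  character — a lower bound is enforceable only once the part is
  complete; earlier characters keep the previous part's bound. The
  published all-zero lower-bound example cannot discriminate this
  convention; it is the conservative choice.
* **Branch factor.** `b = σ−1` for Hamming (substitutions). For edit
  distance `b = 2σ`: `σ−1` substitutions, `σ` insertions and one
  deletion, each consuming one level and one error. This is the unique
  simple recurrence that reproduces the published backtracking series
  for `|Q| = 50, σ = 4` at every `k` from 1 to 6 (10250, 1343050, …),
  and it also reproduces, after rounding to the printed precision,
  essentially every published node-count cell for the other strategies.

## Weighted node count

At depth `l` a trie over `σ` letters has `σ^l` branches but a text of
length `|T|` contains at most `|T|−l` distinct `l`-mers, so below
`l* = ⌈log_σ|T|⌉` (minimal `l` with `σ^l ≥ |T|`) most branches die.
Levels `l ≤ l*` contribute their full node count; deeper levels are
scaled by a pluggable weight policy, by default
`min(1, (|T|−l)/σ^l)` — the expected populated fraction of level `l`
under the distinct-`l`-mer cap. The published table of weighted counts
was produced with a fuller expression that is not recoverable from the
main text, so exact equality with those values is *not* promised; the
default policy reproduces their magnitudes (e.g. ≈1137 vs. the published
1082.60 for backtracking at `k = 1`) and, more importantly, their
qualitative content: weighted counts separate backtracking from the
filter schemes by a factor ≥ 10 (≈35× here, ≈34× published) where plain
node counts differ by less than 2×. Weighted counts are floats; tests
compare them at 1e−9 relative tolerance where exact identities hold.

## Execution and oracle

The bidirectional FM-index keeps synchronized intervals in the suffix
orders of the text and its reverse (suffix arrays via prefix doubling,
`O(n log² n)`; plain cumulative rank tables). A single sentinel,
lexicographically smallest, terminates the text; matches never span it.
This is a deliberately simple implementation sized for verification
work on texts up to a few megabases, not a production read mapper.

Scheme execution walks each search's parts in order, extending
character-wise (left or right as dictated by the order), branching over
match/substitution for Hamming plus insertion/deletion for edit
distance, pruning when accumulated errors exceed the current part's
upper bound and discarding states below the lower bound when a part
completes. Under edit distance, after a part that touches an outer end
of the query completes, additional text characters on that side may be
consumed as deletions — without this, alignments that delete the first
or last character of a text range would be unreachable, and the output
would miss ranges the oracle reports. Hits are located through the
forward suffix array; edit hits reached through several alignments are
deduplicated to the minimal distance per `(start, end)` range
(`keep_duplicates=True` preserves per-search hits so redundancy is
observable). Coordinates are 0-based half-open; with edit distance one
match region generally yields several overlapping ranges (e.g. with a
flanking character deleted), all of which are reported, matching the
oracle's definition.

`brute_force_search` is the independent oracle: Hamming slides the query
over the text; edit computes a full DP table per start position
(vectorized over starts) and reports every non-empty range within
distance `k`. The test suite additionally cross-checks this oracle
against a plain per-window DP and against edlib, and checks scheme
execution against it — exhaustively at small scale and on a 10-kb text
with 100 simulated reads per setting for `k ∈ {0, 1, 2}`, both
distances, every construction.

## Synthetic data

The generator emulates the evaluation setup the metrics assume: an
i.i.d. uniform text over `{A, C, G, T}` and reads of fixed length 50
(the typical seed length of FM-index-based mappers) carrying an exact,
independently verified number of errors. Verification re-computes the
Hamming or Levenshtein distance to the origin window and re-samples if
random edits collapsed (bounded at 100 retries; the mechanism of the
original read simulator is not published, so exactness-plus-determinism
is the contract implemented). Texts for the execution tests are 10 kb —
large enough that random 50-mers are unique and spurious seed hits
occur, small enough for exhaustive oracle comparison; this scale choice
is the package's own. What passing these tests shows is losslessness and
bound-correctness of scheme execution; a uniform random text has no
repeat structure, so they say nothing about performance or hit
multiplicity on self-similar genomes, and the weighted node count
likewise ignores reference self-similarity.

## Known limitations

* The FM-index is pure Python; build time and memory limit it to small
  texts. No reverse-complement handling: query both strands yourself.
* Edit-distance execution branches over single operations; the banded
  multi-configuration optimization used by the fastest executors is out
  of scope.
* Optimum-scheme computation (ILP) is out of scope; externally published
  schemes can be loaded from canonical JSON but are not derived. For
  choosing `p`: `p = k+2` gives the lowest node count for `k ≥ 3`,
  `p = k+1` for `k ≤ 2` (the CLI defaults follow this).
* The weighted node count uses the default weight policy above; supply
  your own policy for a different text model.
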