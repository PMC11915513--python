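# searchschemes

Search schemes for lossless approximate string matching in bidirectional
FM-indices: constructions, validation, node-count metrics, and execution.

## The problem

Read mappers and other sequence-analysis tools constantly need every
substring of a reference text `T` whose Hamming or edit distance to a
query `Q` is at most `k`. A bidirectional FM-index can start matching at
any position of `Q` and extend the match to the left or right one
character at a time. A **search scheme** exploits this: the query is cut
into `p` parts and each *search* of the scheme is a triplet `(π, L, U)` —
a part order `π` (a permutation of `0..p-1` in which each next part is
adjacent to the block already matched) together with cumulative lower and
upper error bounds `L` and `U` checked as each part completes. A scheme is
*complete* when every distribution of up to `k` errors over the parts (an
*error configuration*) satisfies the bounds of at least one search, which
makes the search lossless, and *non-redundant* when no configuration is
covered twice.

This package is for people who design, compare, or verify such schemes.
It provides:

* **Constructions** (`searchschemes.generators`) — backtracking,
  pigeonhole and optimized pigeonhole, suffix filter, 01\*0 seeds and
  their merged variant, and a matrix-based heuristic that builds `k+1`
  searches for any `k < p` and matches known optimum schemes where those
  exist.
* **Validation** (`searchschemes.schemes`) — validity of each triplet,
  completeness and redundancy by explicit enumeration of error
  configurations, with witness reporting.
* **Metrics** (`searchschemes.metrics`) — the *node count* (worst-case
  number of backtracking-trie nodes, i.e. index extension steps) and the
  *weighted node count*, which down-weights trie levels deeper than
  `⌈log_σ|T|⌉` because a text of length `|T|` has at most `|T|−l`
  distinct `l`-mers; this corrects the node count's severe
  underestimation of plain backtracking on genome-scale texts.
* **Execution** (`searchschemes.index`, `searchschemes.search`) — a
  bidirectional FM-index for desk-scale texts, scheme execution for
  Hamming and edit distance, and a brute-force oracle for verification.
* **Simulation** (`searchschemes.simulate`) — uniform random texts and
  fixed-length reads carrying an exactly verified number of errors.

## Worked example

```python
from searchschemes import (
    BiFMIndex, SimulationConfig, check_scheme, heuristic, node_count,
    scheme_search, simulate_text, uniform_partition,
)

scheme = heuristic(2, 4)          # 3 searches, 4 parts, up to 2 errors
for s in scheme:
    print(s)
report = check_scheme(scheme)
print("complete:", report.complete, "non-redundant:", report.nonredundant)
print("node count:", node_count(scheme, uniform_partition(50, 4), 4, "edit"))

text = simulate_text(SimulationConfig(text_length=10_000, seed=1))
index = BiFMIndex(text)
query = text[4000:4020] + "A" + text[4021:4050]  # one substitution
hits = scheme_search(index, query, scheme, distance="edit")
print(min(hits, key=lambda o: o.distance))
```

prints

```
(0123, 0002, 0122)
(1230, 0011, 0112)
(2310, 0000, 0022)
complete: True non-redundant: True
node count: 736943
Occurrence(query_id='query', start=4000, end=4050, distance=1, search_index=2)
```

The three triplets are the search orders with their cumulative bounds
(e.g. `(1230, 0011, 0112)`: match part 1, extend right through parts 2
and 3, then left into part 0; after the third part at least one and at
most one error, etc.). The node count 736943 is the worst-case number of
extension steps for 50-character queries over a 4-letter alphabet under
edit distance — the quantity used to rank schemes. The occurrence lists
the matched text range, its edit distance, and the search that found it.

The same functionality is available from the shell:

```bash
searchschemes generate --strategy heuristic -k 2 -p 4 -o scheme.json
searchschemes validate scheme.json
searchschemes nodecount --strategy backtracking --strategy heuristic \
    -k 1 -k 2 --query-length 50 --sigma 4 --dist edit
searchschemes simulate --text-length 10000 --errors 2 --seed 1 -o sim
searchschemes search --reference sim_ref.fa --reads sim_reads.fa \
    --scheme scheme.json --dist edit -o hits.tsv
```

Formats: schemes are canonical JSON
(`{"name", "k", "p", "searches": [{"pi", "L", "U"}]}`, sorted keys,
round-tripping byte-identically); references and reads are plain FASTA;
hits are TSV with columns `query_id  start  end  distance  search_index`
in 0-based half-open coordinates. `fixtures/` ships canonical files for
the documented example schemes.

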