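"""Node count and weighted node count of search schemes.

The *node count* of a scheme is the total number of nodes of the
backtracking tries its searches traverse in the worst case, for a given
query length, alphabet size and distance metric — an upper bound on the
number of index extension steps.  It is computed by a small dynamic
program over states ``(level l, accumulated errors d)`` windowed by the
search's bounds inflated from part granularity to character granularity.

The *weighted node count* corrects the node count's main blind spot: a
text of length ``|T|`` contains at most ``|T| - l`` distinct ``l``-mers,
so below depth ``ceil(log_sigma |T|)`` a real index cannot branch into
all ``sigma^l`` paths.  Deep levels are therefore down-weighted by the
expected fraction of the trie that is actually populated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

from .generators import Partition
from .schemes import Search, SearchScheme, SchemeError

__all__ = [
    "InflatedBounds",
    "CountTable",
    "TextModel",
    "inflate_bounds",
    "count_table",
    "node_count",
    "weighted_node_count",
    "default_weight_policy",
]

Distance = Literal["hamming", "edit"]


@dataclass(frozen=True)
class InflatedBounds:
    """Per-character cumulative error bounds along a search's character order."""

    lo: tuple[int, ...]
    hi: tuple[int, ...]


@dataclass
class CountTable:
    """Node counts per (level, accumulated errors) state of one search."""

    n: dict[tuple[int, int], int]
    distance: Distance
    sigma: int

    def total(self) -> int:
        return sum(self.n.values())


@dataclass(frozen=True)
class TextModel:
    """Length of the indexed text and the derived branching-depth threshold."""

    text_length: int

    def threshold(self, sigma: int) -> int:
        """Minimal ``l`` with ``sigma**l >= |T|`` — the depth below which
        not every branch of the trie can exist in the text."""
        l, power = 0, 1
        while power < self.text_length:
            l += 1
            power *= sigma
        return l


def _branch_factor(sigma: int, distance: Distance) -> int:
    # Number of error-introducing branches per node consuming one level:
    # Hamming has sigma-1 substitutions; edit adds sigma insertions and
    # one deletion (sigma-1 + sigma + 1 = 2*sigma).
    return sigma - 1 if distance == "hamming" else 2 * sigma


def inflate_bounds(
    search: Search, partition: Partition, distance: Distance = "hamming"
) -> InflatedBounds:
    """Inflate part-level bounds ``L``/``U`` to character level.

    Characters are laid out in search order (concatenation of the parts
    as the search visits them).  For edit distance the upper bound is
    the part bound throughout; for Hamming it additionally cannot grow
    faster than one error per character.  The lower bound of a part
    becomes enforceable only once the part is complete, so it applies
    at the part's final character.
    """
    if partition.p != search.p:
        raise SchemeError(
            f"partition has {partition.p} parts, search expects {search.p}"
        )
    lo: list[int] = []
    hi: list[int] = []
    for t, part in enumerate(search.order):
        size = partition.sizes[part]
        prev_l = search.lower[t - 1] if t > 0 else 0
        for j in range(size):
            if distance == "hamming":
                prev_h = hi[-1] if hi else 0
                hi.append(min(search.upper[t], prev_h + 1))
            else:
                hi.append(search.upper[t])
            lo.append(search.lower[t] if j == size - 1 else prev_l)
    return InflatedBounds(tuple(lo), tuple(hi))


def count_table(
    search: Search,
    partition: Partition,
    sigma: int,
    distance: Distance = "hamming",
) -> CountTable:
    """Dynamic program over (level, errors) states for one search.

    ``n(l, d)`` counts trie nodes at depth ``l`` with ``d`` accumulated
    errors: ``n(l, d) = n(l-1, d) + b * n(l-1, d-1)`` with branch factor
    ``b`` and ``n(0, 0) = 1``, zeroing states outside the inflated
    bound window at each level.  Counts are exact integers.
    """
    if sigma < 2:
        raise SchemeError("sigma must be >= 2")
    bounds = inflate_bounds(search, partition, distance)
    b = _branch_factor(sigma, distance)
    table: dict[tuple[int, int], int] = {}
    prev = {0: 1}
    for l in range(1, partition.query_length + 1):
        lo, hi = bounds.lo[l - 1], bounds.hi[l - 1]
        cur: dict[int, int] = {}
        for d in range(lo, hi + 1):
            v = prev.get(d, 0) + b * prev.get(d - 1, 0)
            if v:
                cur[d] = v
                table[(l, d)] = v
        prev = cur
    return CountTable(table, distance, sigma)


def node_count(
    scheme: SearchScheme,
    partition: Partition,
    sigma: int,
    distance: Distance = "hamming",
) -> int:
    """Total trie nodes traversed by all searches of ``scheme``."""
    return sum(
        count_table(s, partition, sigma, distance).total() for s in scheme
    )


def default_weight_policy(level: int, model: TextModel, sigma: int) -> float:
    """Fraction of depth-``level`` trie nodes populated by a random text:
    at most ``|T| - level`` distinct ``level``-mers exist among
    ``sigma**level`` possible ones."""
    return min(1.0, max(0.0, (model.text_length - level)) / sigma**level)


def weighted_node_count(
    scheme: SearchScheme,
    partition: Partition,
    sigma: int,
    distance: Distance = "hamming",
    model: TextModel | None = None,
    weight_policy: Callable[[int, TextModel, int], float] = default_weight_policy,
) -> float:
    """Node count with deep levels down-weighted for a finite text.

    Levels up to ``model.threshold(sigma)`` contribute their full node
    count; deeper levels are scaled by ``weight_policy(level, model,
    sigma)`` in ``(0, 1]``.  Converges to :func:`node_count` as
    ``|T| -> infinity``.
    """
    if model is None:
        raise SchemeError("weighted_node_count requires a TextModel")
    if model.text_length < partition.query_length:
        raise SchemeError("text shorter than the query")
    lstar = model.threshold(sigma)
    total = 0.0
    for s in scheme:
        for (l, _d), v in count_table(s, partition, sigma, distance).n.items():
            total += v if l <= lstar else v * weight_policy(l, model, sigma)
    return total
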