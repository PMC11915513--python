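"""Constructions of search schemes for classic filtration strategies.

Implemented strategies, each emitting a valid (and, as checked by the
test suite, complete) scheme for ``k`` errors:

``backtracking``
    A single search over one part with bounds ``0..k`` — plain
    backtracking in the index, the baseline every filter improves on.
``pigeonhole`` / ``pigeonhole_opt``
    Split into ``k+1`` parts; some part carries no error, so each of
    ``k+1`` searches starts exact at a different part.  The optimized
    variant tightens the bounds so previously-found matches are not
    re-discovered (disjoint coverage for ``k <= 2``).
``suffix_filter``
    Seed each part, extend right under the strong-match staircase
    (cumulative errors over the last ``s`` factors stay below ``s``),
    then extend left requiring at least one error overall.
``zero_one_star`` / ``zero_one_star_opt``
    Split into ``k+2`` parts; some block of adjacent parts reads
    ``0 1...1 0`` in per-part errors.  One search per (start part,
    block length) pair; the optimized variant merges the searches that
    share a start part by taking elementwise min/max bounds.
``heuristic``
    The matrix-based construction: ``k+1`` searches whose upper bounds
    are read off an adjusted ``(k+1) x p`` matrix.  On par with known
    optimum schemes and applicable to any ``k < p``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .schemes import Search, SearchScheme, SchemeError, make_search

__all__ = [
    "Partition",
    "HeuristicMatrix",
    "uniform_partition",
    "backtracking",
    "pigeonhole",
    "pigeonhole_opt",
    "suffix_filter",
    "zero_one_star",
    "zero_one_star_opt",
    "heuristic",
    "build_matrix",
    "adjust_matrix",
    "GENERATORS",
]


@dataclass(frozen=True)
class Partition:
    """Part lengths (in characters) of a partitioned query."""

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.sizes or any(s < 1 for s in self.sizes):
            raise SchemeError(f"all part sizes must be >= 1, got {self.sizes}")

    @property
    def p(self) -> int:
        return len(self.sizes)

    @property
    def query_length(self) -> int:
        return sum(self.sizes)

    def offsets(self) -> tuple[int, ...]:
        """Start offset of each part within the query."""
        out, acc = [], 0
        for s in self.sizes:
            out.append(acc)
            acc += s
        return tuple(out)


def uniform_partition(query_length: int, p: int) -> Partition:
    """Split ``query_length`` characters into ``p`` near-equal parts.

    Part sizes differ by at most one; the remainder goes to the
    leftmost parts, so e.g. 50 characters in 4 parts give (13,13,12,12).
    """
    if not 1 <= p <= query_length:
        raise SchemeError(f"need 1 <= p <= query_length, got p={p}, |Q|={query_length}")
    base, extra = divmod(query_length, p)
    return Partition(tuple(base + 1 if i < extra else base for i in range(p)))


def backtracking(k: int) -> SearchScheme:
    """Single-search scheme: one part, ``0..k`` errors anywhere."""
    if k < 0:
        raise SchemeError("k must be non-negative")
    s = make_search((0,), (0,), (k,))
    return SearchScheme(f"backtracking_k{k}", k, 1, (s,))


def _pigeonhole_order(i: int, p: int) -> tuple[int, ...]:
    # seed part i, then extend left through i-1..0, then right to p-1
    return (i,) + tuple(range(i - 1, -1, -1)) + tuple(range(i + 1, p))


def pigeonhole(k: int) -> SearchScheme:
    """Plain pigeonhole scheme: ``k+1`` searches, each seeding one exact part."""
    if k < 1:
        raise SchemeError("pigeonhole needs k >= 1")
    p = k + 1
    searches = []
    for i in range(p):
        order = _pigeonhole_order(i, p)
        upper = (0,) + (k,) * (p - 1)
        searches.append(make_search(order, (0,) * p, upper))
    return SearchScheme(f"pigeonhole_k{k}", k, p, tuple(searches))


def pigeonhole_opt(k: int) -> SearchScheme:
    """Pigeonhole with tightened bounds.

    Search ``i`` requires at least one error in every part left of its
    seed (those were already searched exactly), raising the cumulative
    lower bound by one per left part; the upper bound while moving left
    starts at ``k - i + 1`` and grows by one per part, capped at ``k``.
    """
    if k < 1:
        raise SchemeError("pigeonhole_opt needs k >= 1")
    p = k + 1
    searches = []
    for i in range(p):
        order = _pigeonhole_order(i, p)
        lower = [0]
        upper = [0]
        for step in range(1, i + 1):  # extending left through parts i-1 .. 0
            lower.append(step)
            upper.append(min(k - i + step, k))
        for _ in range(i + 1, p):  # extending right through parts i+1 .. p-1
            lower.append(lower[-1])
            upper.append(k)
        searches.append(make_search(order, lower, upper))
    return SearchScheme(f"pigeonhole_opt_k{k}", k, p, tuple(searches))


def suffix_filter(k: int) -> SearchScheme:
    """Suffix-filter scheme: seed, staircase right, then left with >= 1 error.

    Right extension follows the strong-match criterion — after the
    ``t``-th right step at most ``t`` cumulative errors (capped at
    ``k``); left parts allow up to ``k`` but require at least one error
    overall, since an error-free left side was found by an earlier seed.
    """
    if k < 1:
        raise SchemeError("suffix_filter needs k >= 1")
    p = k + 1
    searches = []
    for i in range(p):
        order = tuple(range(i, p)) + tuple(range(i - 1, -1, -1))
        n_right = p - i  # seed plus right extensions
        lower = [0] * n_right + [1] * i
        upper = [min(t, k) for t in range(n_right)] + [k] * i
        searches.append(make_search(order, lower, upper))
    return SearchScheme(f"suffix_filter_k{k}", k, p, tuple(searches))


def _zero_one_star_search(k: int, a: int, j: int) -> Search:
    """The (start part ``a``, block length ``j``) search over ``p = k+2`` parts.

    Part ``a`` is matched exactly, the next ``j`` parts with exactly one
    error each, part ``a+j+1`` again exactly; the remaining ``k - j``
    errors may fall anywhere in the remaining parts.
    """
    p = k + 2
    order = tuple(range(a, p)) + tuple(range(a - 1, -1, -1))
    lower = [0]
    upper = [0]
    for t in range(1, j + 1):  # the j one-error parts
        lower.append(t)
        upper.append(t)
    lower.append(j)  # part a+j+1, again error-free
    upper.append(j)
    while len(lower) < p:  # remaining parts absorb the leftover errors
        lower.append(j)
        upper.append(k)
    return make_search(order, lower, upper)


def zero_one_star(k: int) -> SearchScheme:
    """01*0-seed scheme: ``(k+1)(k+2)/2`` searches over ``k+2`` parts."""
    if k < 1:
        raise SchemeError("zero_one_star needs k >= 1")
    p = k + 2
    searches = tuple(
        _zero_one_star_search(k, a, j)
        for a in range(k + 1)
        for j in range(k - a + 1)
    )
    return SearchScheme(f"zero_one_star_k{k}", k, p, searches)


def zero_one_star_opt(k: int) -> SearchScheme:
    """Merged 01*0 scheme: one search per start part, min/max bounds.

    All 01*0 searches starting at part ``a`` share a part order, so they
    merge into one search with elementwise min lower / max upper bounds.
    The merge widens coverage (extra search paths) but cuts the number
    of searches from ``(k+1)(k+2)/2`` to ``k+1``.
    """
    if k < 1:
        raise SchemeError("zero_one_star_opt needs k >= 1")
    p = k + 2
    searches = []
    for a in range(k + 1):
        group = [_zero_one_star_search(k, a, j) for j in range(k - a + 1)]
        order = group[0].order
        lower = tuple(min(s.lower[t] for s in group) for t in range(p))
        upper = tuple(max(s.upper[t] for s in group) for t in range(p))
        searches.append(make_search(order, lower, upper))
    return SearchScheme(f"zero_one_star_opt_k{k}", k, p, tuple(searches))


# ---------------------------------------------------------------------------
# Matrix-based heuristic construction
# ---------------------------------------------------------------------------


@dataclass
class HeuristicMatrix:
    """The ``(k+1) x p`` matrix of per-part error allowances.

    Rows correspond to searches, columns to query parts.  Row ``i`` must
    be non-increasing moving left from the diagonal entry ``m[i][i]``
    and non-decreasing moving right of it; the adjustment step permutes
    columns of the top-left ``k x k`` block until this holds.
    """

    k: int
    p: int
    rows: list[list[int]] = field(default_factory=list)

    def copy(self) -> "HeuristicMatrix":
        return HeuristicMatrix(self.k, self.p, [row[:] for row in self.rows])

    def row_conditions_ok(self) -> bool:
        return self._first_violating_column() is None

    def _first_violating_column(self) -> int | None:
        """Leftmost column holding an element that breaks row monotonicity.

        A failed pair attributes the violation to its outer element (the
        one farther from the row's diagonal).  Outer columns inside the
        fixed right block (``>= k``) cannot be permuted, so the blame is
        clamped to column ``k - 1``.
        """
        worst: int | None = None
        for i in range(self.k + 1):
            row = self.rows[i]
            for j in range(i - 1, -1, -1):  # left of diagonal: m[i][j+1] <= m[i][j]
                if row[j + 1] > row[j]:
                    c = j  # outer = farther left
                    if worst is None or c < worst:
                        worst = c
            for j in range(i + 1, self.p):  # right: m[i][j-1] <= m[i][j]
                if row[j - 1] > row[j]:
                    c = min(j, self.k - 1)  # clamp into the permutable block
                    if worst is None or c < worst:
                        worst = c
        return worst


def build_matrix(k: int, p: int) -> HeuristicMatrix:
    """Initial matrix: ``m[j][i] = (j - i) mod k`` in the top-left ``k x k``
    block, ``k`` along the bottom row of that block, and ``k - j`` in the
    columns ``>= k``."""
    if not p > k >= 1:
        raise SchemeError(f"need p > k >= 1, got k={k}, p={p}")
    rows = []
    for j in range(k + 1):
        row = []
        for i in range(p):
            if i >= k:
                row.append(k - j)
            elif j == k:
                row.append(k)
            else:
                row.append((j - i) % k)
        rows.append(row)
    return HeuristicMatrix(k, p, rows)


def _lex_largest_assignment(
    values: list[int], los: list[int], his: list[int]
) -> list[int] | None:
    """Lexicographically largest arrangement of ``values`` into slots with
    per-slot bounds ``los[i] <= x <= his[i]``, or None if infeasible.

    Equivalent to trying all permutations in reverse lexicographic order
    and keeping the first feasible one, but runs in polynomial time:
    pick the largest remaining value for each slot in turn, accepting it
    only if the rest can still be matched (greedy matching check).
    Descending arrangements preserve the staircase structure of the
    matrix columns; see the methods note for why this tie-break is used.
    """

    def feasible(vals: list[int], lo: list[int], hi: list[int]) -> bool:
        # match slots in order of increasing upper bound with the smallest
        # usable remaining value; classic greedy for interval bipartite matching
        vals = sorted(vals)
        order = sorted(range(len(lo)), key=lambda i: (hi[i], lo[i]))
        used = [False] * len(vals)
        for i in order:
            found = False
            for vi, v in enumerate(vals):
                if not used[vi] and lo[i] <= v <= hi[i]:
                    used[vi] = True
                    found = True
                    break
            if not found:
                return False
        return True

    result: list[int] = []
    remaining = sorted(values, reverse=True)
    for i in range(len(los)):
        placed = False
        tried: set[int] = set()
        for vi, v in enumerate(remaining):
            if v in tried or not los[i] <= v <= his[i]:
                tried.add(v)
                continue
            tried.add(v)
            rest = remaining[:vi] + remaining[vi + 1 :]
            if feasible(rest, los[i + 1 :], his[i + 1 :]):
                result.append(v)
                remaining = rest
                placed = True
                break
        if not placed:
            return None
    return result


def adjust_matrix(
    m: HeuristicMatrix, max_iterations: int | None = None
) -> HeuristicMatrix:
    """Permute columns of the top-left block until row monotonicity holds.

    Repeatedly takes the leftmost violating column ``c`` and rearranges
    its permutable entries (rows ``0..k-1`` excluding the diagonal entry
    ``m[c][c]``) into the lexicographically largest arrangement that
    removes the violations at ``c``; iterates to a fixpoint.  Raises
    :class:`SchemeError` if the iteration budget is exhausted.
    """
    k, p = m.k, m.p
    m = m.copy()
    if max_iterations is None:
        max_iterations = 10 * k * p + 100
    for _ in range(max_iterations):
        c = m._first_violating_column()
        if c is None:
            return m
        if c >= k:
            raise SchemeError(f"column {c} violates monotonicity but is fixed")
        slots = [i for i in range(k) if i != c]
        values = [m.rows[i][c] for i in slots]
        los, his = [], []
        for i in slots:
            lo = 0
            hi = k
            if i > c:  # column c is left-outer for row i: m[i][c] >= m[i][c+1]
                lo = max(lo, m.rows[i][c + 1])
            if i < c and c - 1 >= 0:
                # column c is right-outer for row i: m[i][c] >= m[i][c-1]
                lo = max(lo, m.rows[i][c - 1])
            if c == k - 1 and i <= c:
                # the next column is in the fixed block and cannot adapt later
                hi = min(hi, m.rows[i][c + 1])
            los.append(lo)
            his.append(hi)
        # Preferred arrangement: largest values descending above the
        # diagonal, the rest ascending below it.  This keeps each row's
        # staircase shape and is the arrangement the construction's own
        # worked cases settle into; fall back to the lexicographically
        # largest feasible arrangement if the bounds reject it.
        n_above = sum(1 for i in slots if i < c)
        vals_desc = sorted(values, reverse=True)
        candidate = vals_desc[:n_above] + sorted(vals_desc[n_above:])
        if all(lo <= v <= hi for v, lo, hi in zip(candidate, los, his)):
            assignment = candidate
        else:
            assignment = _lex_largest_assignment(values, los, his)
        if assignment is None:
            raise SchemeError(
                f"no feasible permutation for column {c} (k={k}, p={p})"
            )
        for i, v in zip(slots, assignment):
            m.rows[i][c] = v
    raise SchemeError(
        f"adjustment budget of {max_iterations} iterations exhausted (k={k}, p={p})"
    )


def heuristic(k: int, p: int) -> SearchScheme:
    """Matrix-based construction of a ``k+1``-search scheme over ``p > k`` parts.

    Search ``i`` seeds part ``i``, extends right to part ``p-1``, then
    left to part 0.  Lower bounds are zero until the left extension
    begins and ``k - i`` thereafter; upper bounds come from the adjusted
    matrix reordered along each search's part order, capped at ``k``.
    """
    if not p > k >= 0:
        raise SchemeError(f"need p > k >= 0, got k={k}, p={p}")
    if k == 0:
        s = make_search(tuple(range(p)), (0,) * p, (0,) * p)
        return SearchScheme(f"heuristic_k0_p{p}", 0, p, (s,))
    m = adjust_matrix(build_matrix(k, p))
    searches = []
    for i in range(k + 1):
        order = tuple(range(i, p)) + tuple(range(i - 1, -1, -1))
        lower = (0,) * (p - i - 1) + (k - i,) * (i + 1)
        m_ord = [m.rows[i][part] for part in order]
        upper = [min(m_ord[0], k)]
        for t in range(1, p):
            upper.append(min(lower[t - 1] + m_ord[t], k))
        searches.append(make_search(order, lower, upper))
    return SearchScheme(f"heuristic_k{k}_p{p}", k, p, tuple(searches))


#: Strategy name -> constructor taking (k) or (k, p); used by the CLI.
GENERATORS = {
    "backtracking": backtracking,
    "pigeonhole": pigeonhole,
    "pigeonhole-opt": pigeonhole_opt,
    "suffix-filter": suffix_filter,
    "01*0": zero_one_star,
    "01*0-opt": zero_one_star_opt,
    "heuristic": heuristic,
}
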