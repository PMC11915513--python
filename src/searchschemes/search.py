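"""Execution of search schemes on a bidirectional FM-index, plus oracles.

``scheme_search`` runs every search of a scheme: it seeds at the
search's first part and extends character-wise in part order, branching
over match/substitution (Hamming) or match/substitution/insertion/
deletion (edit distance), pruning any state whose accumulated errors
exceed the search's upper bound for the current part and discarding
states that miss a lower bound when a part completes.  For a complete
scheme the union over searches equals the answer of
``brute_force_search``, the exhaustive text-scan oracle.

Occurrences are text ranges in half-open 0-based coordinates.  Edit
distance can reach one text range through several alignments; by
default such hits are collapsed to the minimal distance per range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .generators import Partition, uniform_partition
from .index import BiFMIndex, BiInterval
from .schemes import Search, SearchScheme, SchemeError

__all__ = [
    "Occurrence",
    "scheme_search",
    "brute_force_search",
    "edit_distance",
]

Distance = Literal["hamming", "edit"]


@dataclass(frozen=True, order=True)
class Occurrence:
    """A matched text range with its distance to the query."""

    query_id: str
    start: int
    end: int
    distance: int
    search_index: int = 0


def _steps(search: Search, partition: Partition, query: str):
    """Per-part processing plan: (direction, chars in processing order,
    lower, upper, at_query_edge)."""
    offsets = partition.offsets()
    plan = []
    mx = mn = search.order[0]
    for t, part in enumerate(search.order):
        if t == 0:
            rightward = True
        elif part == mx + 1:
            rightward, mx = True, part
        else:
            rightward, mn = False, part
        lo_c = offsets[part]
        hi_c = lo_c + partition.sizes[part]
        chars = query[lo_c:hi_c] if rightward else query[lo_c:hi_c][::-1]
        edge = (rightward and part == partition.p - 1) or (
            not rightward and part == 0
        )
        plan.append((rightward, chars, search.lower[t], search.upper[t], edge))
    return plan


def _run_search(
    index: BiFMIndex,
    query: str,
    search: Search,
    partition: Partition,
    distance: Distance,
) -> set[tuple[int, int, int]]:
    """All (start, end, errors) hits of one search."""
    plan = _steps(search, partition, query)
    p = len(plan)
    alphabet = index.alphabet
    edit = distance == "edit"
    hits: set[tuple[int, int, int]] = set()
    # states: (at_boundary, t, j, errs, interval)
    stack = [(False, 0, 0, 0, index.root())]
    while stack:
        boundary, t, j, errs, iv = stack.pop()
        rightward, chars, lo_b, hi_b, edge = plan[t]
        ext = index.extend_right if rightward else index.extend_left
        if boundary:
            if edit and edge and errs + 1 <= hi_b:
                # a query-edge part may absorb trailing deletions: text
                # characters at the outer rim of the match aligned to gaps
                for c in alphabet:
                    niv = ext(iv, c)
                    if not niv.empty:
                        stack.append((True, t, j, errs + 1, niv))
            if errs >= lo_b:
                if t == p - 1:
                    for pos in index.locate(iv):
                        hits.add((pos, pos + iv.length, errs))
                else:
                    stack.append((False, t + 1, 0, errs, iv))
            continue
        if j == len(chars):
            stack.append((True, t, j, errs, iv))
            continue
        qc = chars[j]
        budget = errs < hi_b
        # match / substitution
        for c in alphabet if budget else qc:
            niv = ext(iv, c)
            if not niv.empty:
                stack.append((False, t, j + 1, errs + (c != qc), niv))
        if edit and budget:
            # insertion: query character aligned to a gap
            stack.append((False, t, j + 1, errs + 1, iv))
            # deletion: text character aligned to a gap
            for c in alphabet:
                niv = ext(iv, c)
                if not niv.empty:
                    stack.append((False, t, j, errs + 1, niv))
    return hits


def _dedup(occs: list[Occurrence]) -> list[Occurrence]:
    best: dict[tuple[str, int, int], Occurrence] = {}
    for o in occs:
        key = (o.query_id, o.start, o.end)
        cur = best.get(key)
        if cur is None or (o.distance, o.search_index) < (
            cur.distance,
            cur.search_index,
        ):
            best[key] = o
    return sorted(best.values())


def scheme_search(
    index: BiFMIndex,
    query: str,
    scheme: SearchScheme,
    partition: Partition | None = None,
    distance: Distance = "hamming",
    query_id: str = "query",
    keep_duplicates: bool = False,
) -> list[Occurrence]:
    """Find all occurrences of ``query`` within ``scheme.k`` errors.

    ``partition`` defaults to the uniform partition of the query into
    ``scheme.p`` parts.  With ``keep_duplicates`` the raw per-search
    hits are returned (one per search that found a range), which makes
    redundancy observable; otherwise hits are deduplicated to the
    minimal distance per text range.
    """
    if partition is None:
        partition = uniform_partition(len(query), scheme.p)
    if partition.p != scheme.p:
        raise SchemeError("partition does not match the scheme's part count")
    if partition.query_length != len(query):
        raise SchemeError("partition does not match the query length")
    raw: list[Occurrence] = []
    for si, search in enumerate(scheme.searches):
        per_search: dict[tuple[int, int], int] = {}
        for start, end, errs in _run_search(
            index, query, search, partition, distance
        ):
            key = (start, end)
            if key not in per_search or errs < per_search[key]:
                per_search[key] = errs
        raw.extend(
            Occurrence(query_id, s, e, d, si) for (s, e), d in per_search.items()
        )
    if keep_duplicates:
        return sorted(raw)
    return _dedup(raw)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance (unit costs)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_search(
    text: str,
    query: str,
    k: int,
    distance: Distance = "hamming",
    query_id: str = "query",
) -> list[Occurrence]:
    """Exhaustive scan: every text range within distance ``k`` of the query.

    Hamming slides the query over the text counting mismatches.  Edit
    computes, for every start position, the full DP row of global edit
    distances of the query against windows of every length up to
    ``len(query) + k`` (vectorized over start positions), and reports
    each non-empty range ``[start, end)`` with distance at most ``k``.
    """
    n, q = len(text), len(query)
    if q == 0:
        return []
    tarr = np.frombuffer(text.encode(), dtype=np.uint8)
    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    out: list[Occurrence] = []
    if distance == "hamming":
        if n >= q:
            win = np.lib.stride_tricks.sliding_window_view(tarr, q)
            mism = (win != qarr).sum(axis=1)
            for s in np.nonzero(mism <= k)[0]:
                out.append(Occurrence(query_id, int(s), int(s) + q, int(mism[s])))
        return sorted(out)
    # edit: windows of length q + k starting at every position, padded
    wlen = q + k
    padded = np.concatenate([tarr, np.zeros(wlen, dtype=np.uint8)])
    win = np.lib.stride_tricks.sliding_window_view(padded, wlen)[:n]
    # D[s, j] = edit distance of query[:i] vs text[s:s+j], updated per i
    prev = np.broadcast_to(np.arange(wlen + 1), (n, wlen + 1)).astype(np.int32)
    rows = [prev]
    for i in range(1, q + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = i
        sub = prev[:, :-1] + (win != qarr[i - 1])
        for j in range(1, wlen + 1):
            np.minimum(sub[:, j - 1], prev[:, j] + 1, out=cur[:, j])
            np.minimum(cur[:, j], cur[:, j - 1] + 1, out=cur[:, j])
        prev = cur
    final = prev  # distances for every (start, window length)
    lo_len = max(1, q - k)
    for j in range(lo_len, wlen + 1):
        ok = np.nonzero(final[:, j] <= k)[0]
        for s in ok:
            e = int(s) + j
            if e <= n:
                out.append(Occurrence(query_id, int(s), e, int(final[s, j])))
    return sorted(out)
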