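"""Core domain types for search schemes and their validation.

A *search scheme* prescribes how a query that has been split into ``p``
parts is matched in a bidirectional FM-index.  Each *search* is a triplet
``(pi, L, U)``: a permutation ``pi`` of the part indices giving the order
in which parts are matched, and cumulative lower/upper error bounds ``L``
and ``U`` checked after each part.  A scheme is *complete* for ``k``
errors if every distribution of errors over the parts (an *error
configuration*) satisfies the bounds of at least one search, and
*non-redundant* if of at most one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterator, Literal, Sequence

__all__ = [
    "Search",
    "SearchScheme",
    "ErrorConfiguration",
    "ValidationReport",
    "SchemeError",
    "make_search",
    "covers",
    "coverage_set",
    "check_scheme",
    "enumerate_configs",
]

#: An error configuration: per-part error counts, length p.
ErrorConfiguration = tuple

Mode = Literal["at-most", "exact"]

#: Default ceiling on the number of configurations enumerated at once.
DEFAULT_ENUM_CEILING = 5_000_000


class SchemeError(ValueError):
    """Raised when a search or scheme violates a structural invariant."""


@dataclass(frozen=True)
class Search:
    """One search of a scheme: part order with cumulative error bounds.

    ``order`` is a permutation of ``0..p-1`` satisfying the connectivity
    property (each next part extends the contiguous block searched so
    far by one on the left or right), so the search can be executed by
    left/right extensions in a bidirectional index.  ``lower[t]`` and
    ``upper[t]`` bound the total number of errors accumulated once the
    first ``t+1`` parts of ``order`` have been matched.
    """

    order: tuple[int, ...]
    lower: tuple[int, ...]
    upper: tuple[int, ...]

    @property
    def p(self) -> int:
        return len(self.order)

    def as_triplet(self) -> tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]:
        return (self.order, self.lower, self.upper)

    def __str__(self) -> str:  # compact (pi, L, U) notation, e.g. (102, 000, 022)
        def s(v: Sequence[int]) -> str:
            return "".join(map(str, v)) if all(x < 10 for x in v) else str(tuple(v))

        return f"({s(self.order)}, {s(self.lower)}, {s(self.upper)})"


@dataclass(frozen=True)
class SearchScheme:
    """A named collection of searches sharing one partition size ``p``."""

    name: str
    k: int
    p: int
    searches: tuple[Search, ...]

    def __post_init__(self) -> None:
        if self.k < 0:
            raise SchemeError(f"k must be non-negative, got {self.k}")
        for i, s in enumerate(self.searches):
            if s.p != self.p:
                raise SchemeError(
                    f"search {i} has {s.p} parts, scheme declares p={self.p}"
                )

    def __iter__(self) -> Iterator[Search]:
        return iter(self.searches)

    def __len__(self) -> int:
        return len(self.searches)


@dataclass
class ValidationReport:
    """Outcome of checking a scheme: validity, completeness, redundancy."""

    valid: bool
    complete: bool
    nonredundant: bool
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.valid and self.complete and self.nonredundant


def make_search(
    order: Sequence[int], lower: Sequence[int], upper: Sequence[int]
) -> Search:
    """Build a :class:`Search`, rejecting inputs that break any invariant.

    Raises :class:`SchemeError` naming the offending step for: ``order``
    not a connectivity-respecting permutation, non-monotone bounds, or
    ``upper[t] < lower[t]``.
    """
    order = tuple(int(x) for x in order)
    lower = tuple(int(x) for x in lower)
    upper = tuple(int(x) for x in upper)
    p = len(order)
    if p < 1:
        raise SchemeError("a search needs at least one part")
    if len(lower) != p or len(upper) != p:
        raise SchemeError(
            f"order, lower and upper must have equal length, got "
            f"{p}, {len(lower)}, {len(upper)}"
        )
    if sorted(order) != list(range(p)):
        raise SchemeError(f"order {order} is not a permutation of 0..{p - 1}")
    lo_part, hi_part = order[0], order[0]
    for t in range(1, p):
        nxt = order[t]
        if nxt == hi_part + 1:
            hi_part = nxt
        elif nxt == lo_part - 1:
            lo_part = nxt
        else:
            raise SchemeError(
                f"connectivity violated at step {t}: part {nxt} is neither "
                f"{hi_part}+1 nor {lo_part}-1"
            )
    for name, bounds in (("lower", lower), ("upper", upper)):
        for t in range(p):
            if bounds[t] < 0:
                raise SchemeError(f"{name} bound negative at step {t}")
            if t > 0 and bounds[t] < bounds[t - 1]:
                raise SchemeError(f"{name} bounds not monotone at step {t}")
    for t in range(p):
        if upper[t] < lower[t]:
            raise SchemeError(f"upper < lower at step {t}")
    return Search(order, lower, upper)


def covers(search: Search, config: Sequence[int]) -> bool:
    """True iff ``config`` satisfies the search's bounds at every prefix.

    The cumulative error count over the first ``t+1`` parts in search
    order must lie within ``[lower[t], upper[t]]`` for every ``t``.
    """
    if len(config) != search.p:
        raise SchemeError(
            f"configuration length {len(config)} != search p {search.p}"
        )
    total = 0
    for t, part in enumerate(search.order):
        total += config[part]
        if not search.lower[t] <= total <= search.upper[t]:
            return False
    return True


def enumerate_configs(
    k: int, p: int, mode: Mode = "at-most", ceiling: int = DEFAULT_ENUM_CEILING
) -> list[ErrorConfiguration]:
    """All error configurations over ``p`` parts, lexicographically.

    ``mode='exact'`` yields configurations summing to exactly ``k``
    (``C(k+p-1, p-1)`` of them); ``mode='at-most'`` yields all sums
    ``0..k`` (``C(k+p, p)`` of them).
    """
    if k < 0 or p < 1:
        raise SchemeError(f"need k >= 0 and p >= 1, got k={k}, p={p}")
    count = comb(k + p, p) if mode == "at-most" else comb(k + p - 1, p - 1)
    if count > ceiling:
        raise SchemeError(
            f"{count} configurations exceed the enumeration ceiling {ceiling}; "
            "raise it explicitly to proceed"
        )

    def gen(remaining: int, parts: int) -> Iterator[tuple[int, ...]]:
        if parts == 1:
            if mode == "exact":
                yield (remaining,)
            else:
                for e in range(remaining + 1):
                    yield (e,)
            return
        for e in range(remaining + 1):
            for rest in gen(remaining - e, parts - 1):
                yield (e,) + rest

    out = [cfg for cfg in gen(k, p)]
    out.sort()
    return out


def coverage_set(
    search: Search,
    k: int,
    mode: Mode = "at-most",
    ceiling: int = DEFAULT_ENUM_CEILING,
) -> set[ErrorConfiguration]:
    """The set of enumerated configurations covered by ``search``."""
    return {
        cfg
        for cfg in enumerate_configs(k, search.p, mode, ceiling)
        if covers(search, cfg)
    }


def _search_violations(search: Search, index: int) -> list[str]:
    try:
        make_search(search.order, search.lower, search.upper)
    except SchemeError as exc:
        return [f"search {index}: {exc}"]
    return []


def check_scheme(
    scheme: SearchScheme,
    k: int | None = None,
    mode: Mode = "at-most",
    ceiling: int = DEFAULT_ENUM_CEILING,
) -> ValidationReport:
    """Check validity, completeness and non-redundancy of a scheme.

    Completeness and redundancy are judged against the configurations
    enumerated for ``k`` (defaulting to ``scheme.k``) in the given mode.
    Witness configurations are recorded in ``violations``.
    """
    if k is None:
        k = scheme.k
    violations: list[str] = []
    valid = True
    for i, s in enumerate(scheme.searches):
        v = _search_violations(s, i)
        if v:
            valid = False
            violations.extend(v)

    complete = True
    nonredundant = True
    configs = enumerate_configs(k, scheme.p, mode, ceiling)
    witness_uncovered = None
    witness_double = None
    for cfg in configs:
        n = 0
        for s in scheme.searches:
            if covers(s, cfg):
                n += 1
                if n > 1:
                    break
        if n == 0:
            complete = False
            if witness_uncovered is None:
                witness_uncovered = cfg
        elif n > 1:
            nonredundant = False
            if witness_double is None:
                witness_double = cfg
    if witness_uncovered is not None:
        violations.append(f"uncovered configuration: {witness_uncovered}")
    if witness_double is not None:
        violations.append(f"doubly covered configuration: {witness_double}")
    return ValidationReport(valid, complete, nonredundant, violations)
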