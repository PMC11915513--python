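"""Bidirectional FM-index over small texts.

Maintains synchronized intervals in the suffix orders of the text and of
its reverse, so a matched substring can be extended by one character on
either side.  Built for desk-scale texts (up to a few megabases): the
suffix arrays come from a prefix-doubling construction and rank support
is a plain cumulative-count table per character.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["BiFMIndex", "BiInterval", "IndexError_"]


class IndexError_(ValueError):
    """Raised for characters outside the alphabet or malformed input."""


@dataclass(frozen=True)
class BiInterval:
    """Synchronized half-open ranges in the forward and reverse suffix orders.

    ``fwd_lo:fwd_hi`` ranges over suffixes of the text prefixed by the
    matched string W; ``rev_lo:rev_hi`` over suffixes of the reversed
    text prefixed by reverse(W).  Both ranges always have equal size.
    ``length`` is the number of text characters matched so far.
    """

    fwd_lo: int
    fwd_hi: int
    rev_lo: int
    rev_hi: int
    length: int

    @property
    def size(self) -> int:
        return self.fwd_hi - self.fwd_lo

    @property
    def empty(self) -> bool:
        return self.fwd_hi <= self.fwd_lo


def _suffix_array(s: Sequence[int]) -> list[int]:
    # prefix doubling (Manber-Myers flavour), O(n log^2 n)
    n = len(s)
    sa = list(range(n))
    rank = list(s)
    step = 1
    while True:
        def key(i: int) -> tuple[int, int]:
            return (rank[i], rank[i + step] if i + step < n else -1)

        sa.sort(key=key)
        new = [0] * n
        for j in range(1, n):
            new[sa[j]] = new[sa[j - 1]] + (key(sa[j]) != key(sa[j - 1]))
        rank = new
        if rank[sa[-1]] == n - 1:
            return sa
        step *= 2


class _Fm:
    """One direction: suffix array, BWT and rank support over int codes."""

    def __init__(self, codes: list[int], n_codes: int):
        self.sa = _suffix_array(codes)
        n = len(codes)
        bwt = [codes[i - 1] if i else codes[n - 1] for i in self.sa]
        # occ[c][i] = number of occurrences of code c in bwt[:i]
        self.occ = [[0] * (n + 1) for _ in range(n_codes)]
        for i, c in enumerate(bwt):
            for cc in range(n_codes):
                self.occ[cc][i + 1] = self.occ[cc][i] + (1 if cc == c else 0)
        counts = [0] * n_codes
        for c in codes:
            counts[c] += 1
        self.C = [0] * (n_codes + 1)
        for c in range(n_codes):
            self.C[c + 1] = self.C[c] + counts[c]


class BiFMIndex:
    """Bidirectional FM-index of ``text`` over an ordered ``alphabet``.

    A sentinel smaller than every alphabet character is appended
    internally; matches never span it.  The empty-pattern interval
    covers all ``len(text) + 1`` suffixes (including the sentinel
    suffix).
    """

    def __init__(self, text: str, alphabet: str = "ACGT"):
        if not text:
            raise IndexError_("text must be non-empty")
        self.text = text
        self.alphabet = "".join(sorted(set(alphabet)))
        self._code = {c: i + 1 for i, c in enumerate(self.alphabet)}  # 0 = sentinel
        try:
            codes = [self._code[c] for c in text]
        except KeyError as exc:
            raise IndexError_(f"character {exc} not in alphabet {self.alphabet!r}")
        n_codes = len(self.alphabet) + 1
        self._fwd = _Fm(codes + [0], n_codes)
        self._rev = _Fm(codes[::-1] + [0], n_codes)
        self.n = len(codes) + 1  # including sentinel

    # -- intervals ---------------------------------------------------------

    def root(self) -> BiInterval:
        return BiInterval(0, self.n, 0, self.n, 0)

    def _extend(self, fm_a: _Fm, fm_b: _Fm, a_lo: int, a_hi: int,
                b_lo: int, c: int) -> tuple[int, int, int, int]:
        # Backward-search step on fm_a; resynchronize the companion range
        # by the number of range occurrences of codes smaller than c.
        lo = fm_a.C[c] + fm_a.occ[c][a_lo]
        hi = fm_a.C[c] + fm_a.occ[c][a_hi]
        smaller = 0
        for cc in range(c):
            smaller += fm_a.occ[cc][a_hi] - fm_a.occ[cc][a_lo]
        nb_lo = b_lo + smaller
        return lo, hi, nb_lo, nb_lo + (hi - lo)

    def extend_left(self, iv: BiInterval, char: str) -> BiInterval:
        """Interval of ``char + W`` given the interval of ``W``."""
        c = self._code.get(char)
        if c is None:
            raise IndexError_(f"character {char!r} not in alphabet")
        if iv.empty:
            return iv
        f_lo, f_hi, r_lo, r_hi = self._extend(
            self._fwd, self._rev, iv.fwd_lo, iv.fwd_hi, iv.rev_lo, c
        )
        return BiInterval(f_lo, f_hi, r_lo, r_hi, iv.length + 1)

    def extend_right(self, iv: BiInterval, char: str) -> BiInterval:
        """Interval of ``W + char`` given the interval of ``W``."""
        c = self._code.get(char)
        if c is None:
            raise IndexError_(f"character {char!r} not in alphabet")
        if iv.empty:
            return iv
        r_lo, r_hi, f_lo, f_hi = self._extend(
            self._rev, self._fwd, iv.rev_lo, iv.rev_hi, iv.fwd_lo, c
        )
        return BiInterval(f_lo, f_hi, r_lo, r_hi, iv.length + 1)

    def locate(self, iv: BiInterval) -> list[int]:
        """Start positions in the text of the matched substring."""
        return sorted(self._fwd.sa[i] for i in range(iv.fwd_lo, iv.fwd_hi))

    # -- convenience -------------------------------------------------------

    def exact_search(self, pattern: str) -> list[int]:
        """All occurrence positions of ``pattern`` (exact match)."""
        iv = self.root()
        for ch in pattern:
            iv = self.extend_right(iv, ch)
            if iv.empty:
                return []
        return self.locate(iv)
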