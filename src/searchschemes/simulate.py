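"""Synthetic benchmark data: random texts and reads with an exact error count.

Emulates the evaluation setup the scheme metrics are calibrated for:
an i.i.d. uniform random text over {A,C,G,T} (a simple stand-in for a
reference genome) and fixed-length reads sampled from it, each carrying
an exactly known Hamming or edit distance to its text window of origin.
Random edits can cancel each other (e.g. an insertion next to a
deletion), so every emitted read is verified against its origin window
with an independent distance computation and re-sampled if the realized
distance is smaller than requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .search import edit_distance

__all__ = ["SimulationConfig", "SimulatedRead", "simulate_text", "simulate_reads"]

Distance = Literal["hamming", "edit"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run; ``seed`` fully determines outputs."""

    text_length: int
    read_length: int = 50
    read_count: int = 100
    errors_per_read: int = 0
    distance: Distance = "edit"
    alphabet: str = "ACGT"
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.errors_per_read >= self.read_length:
            raise ValueError("errors_per_read must be < read_length")
        if self.text_length < 1:
            raise ValueError("text_length must be >= 1")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    origin_start: int
    origin_end: int
    distance: int


def simulate_text(config: SimulationConfig, rng: np.random.Generator | None = None) -> str:
    """I.i.d. uniform random text over the configured alphabet."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    letters = np.array(list(config.alphabet))
    return "".join(letters[rng.integers(0, len(letters), config.text_length)])


def _mutate(
    window: str, ops: list[str], alphabet: str, rng: np.random.Generator
) -> str:
    out = list(window)
    for op in ops:
        if op == "sub":
            i = int(rng.integers(0, len(out)))
            choices = [c for c in alphabet if c != out[i]]
            out[i] = choices[int(rng.integers(0, len(choices)))]
        elif op == "ins":
            i = int(rng.integers(0, len(out) + 1))
            out.insert(i, alphabet[int(rng.integers(0, len(alphabet)))])
        else:  # del
            i = int(rng.integers(0, len(out)))
            del out[i]
    return "".join(out)


def simulate_reads(
    text: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SimulatedRead]:
    """Reads of fixed length with exactly ``errors_per_read`` errors.

    Each read derives from a random text window: for Hamming distance,
    ``e`` distinct positions are substituted; for edit distance a random
    mix of substitutions, insertions and deletions is applied to a
    window whose length compensates the indels so the read keeps its
    nominal length.  The realized distance is verified independently
    (mismatch count / Levenshtein DP) and the read re-sampled up to
    ``max_retries`` times if edits collapsed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    e = config.errors_per_read
    rl = config.read_length
    if len(text) < rl + e:
        raise ValueError("text too short for the requested reads")
    reads: list[SimulatedRead] = []
    for i in range(config.read_count):
        for _attempt in range(config.max_retries):
            if config.distance == "hamming" or e == 0:
                start = int(rng.integers(0, len(text) - rl + 1))
                window = text[start : start + rl]
                positions = rng.choice(rl, size=e, replace=False) if e else []
                out = list(window)
                for pos in positions:
                    choices = [c for c in config.alphabet if c != out[pos]]
                    out[pos] = choices[int(rng.integers(0, len(choices)))]
                seq = "".join(out)
                realized = sum(a != b for a, b in zip(seq, window))
            else:
                ops = [
                    ("sub", "ins", "del")[int(rng.integers(0, 3))] for _ in range(e)
                ]
                wlen = rl - ops.count("ins") + ops.count("del")
                start = int(rng.integers(0, len(text) - wlen + 1))
                window = text[start : start + wlen]
                seq = _mutate(window, ops, config.alphabet, rng)
                if len(seq) != rl:  # indel landed at an awkward spot; resample
                    continue
                realized = edit_distance(seq, window)
            if realized == e:
                reads.append(
                    SimulatedRead(f"read{i}", seq, start, start + len(window), e)
                )
                break
        else:
            raise RuntimeError(
                f"could not realize distance {e} after {config.max_retries} tries"
            )
    return reads
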