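"""File formats: canonical scheme JSON, FASTA, and hits TSV.

Scheme JSON is the interchange format for search schemes::

    {"name": str, "k": int, "p": int,
     "searches": [{"pi": [int...], "L": [int...], "U": [int...]}]}

Canonical form has sorted keys, two-space indentation and a trailing
newline; :func:`write_scheme` followed by :func:`load_scheme` (or vice
versa) round-trips canonical files byte-identically.  Loading validates
every search and reports violations instead of silently fixing them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .schemes import SearchScheme, SchemeError, make_search
from .search import Occurrence

__all__ = [
    "scheme_to_dict",
    "scheme_from_dict",
    "dumps_scheme",
    "load_scheme",
    "write_scheme",
    "read_fasta",
    "write_fasta",
    "write_hits_tsv",
]

HITS_COLUMNS = ("query_id", "start", "end", "distance", "search_index")


def scheme_to_dict(scheme: SearchScheme) -> dict:
    return {
        "name": scheme.name,
        "k": scheme.k,
        "p": scheme.p,
        "searches": [
            {"pi": list(s.order), "L": list(s.lower), "U": list(s.upper)}
            for s in scheme.searches
        ],
    }


def scheme_from_dict(d: dict) -> SearchScheme:
    try:
        searches = tuple(
            make_search(s["pi"], s["L"], s["U"]) for s in d["searches"]
        )
        return SearchScheme(str(d["name"]), int(d["k"]), int(d["p"]), searches)
    except KeyError as exc:
        raise SchemeError(f"scheme JSON is missing key {exc}")


def dumps_scheme(scheme: SearchScheme) -> str:
    """Canonical JSON text for a scheme (sorted keys, indent 2, newline)."""
    return json.dumps(scheme_to_dict(scheme), sort_keys=True, indent=2) + "\n"


def write_scheme(scheme: SearchScheme, path: str | Path) -> None:
    Path(path).write_text(dumps_scheme(scheme))


def load_scheme(path: str | Path) -> SearchScheme:
    """Read and validate a scheme JSON file."""
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemeError(f"{path}: not valid JSON ({exc})")
    return scheme_from_dict(d)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file, sequences upper-cased."""
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def write_hits_tsv(hits: Iterable[Occurrence], path) -> None:
    """Hits as TSV with 0-based half-open coordinates; accepts a path or
    an open text handle."""
    own = not hasattr(path, "write")
    fh = open(path, "w") if own else path
    try:
        fh.write("\t".join(HITS_COLUMNS) + "\n")
        for o in sorted(hits):
            fh.write(
                f"{o.query_id}\t{o.start}\t{o.end}\t{o.distance}\t{o.search_index}\n"
            )
    finally:
        if own:
            fh.close()
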