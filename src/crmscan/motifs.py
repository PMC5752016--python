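"""IUPAC motif handling: validation, expansion, orientation variants, query parsing.

A query is either a single (possibly degenerate) motif or a comma-separated
pair of motifs; pairs are the "CRM" unit of the whole analysis. Degenerate
queries are expanded into their concrete component sequences before matching,
and each concrete sequence may additionally be searched in its reversed,
complemented and reverse-complemented reading.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Orientation labels, in the priority order used to deduplicate palindromes.
ORIENTATIONS = ("forward", "reverse", "complement", "reverse-complement")


class InvalidMotifError(ValueError):
    """Raised when a motif contains a character outside the IUPAC alphabet."""


@dataclass(frozen=True)
class Motif:
    """A single IUPAC nucleotide motif."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise InvalidMotifError("empty motif")
        for i, ch in enumerate(self.pattern):
            if ch not in IUPAC_CODES:
                raise InvalidMotifError(
                    f"invalid IUPAC character {ch!r} at position {i} in {self.pattern!r}"
                )

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern

    @property
    def degeneracy(self) -> int:
        """Number of concrete sequences the motif expands to."""
        n = 1
        for ch in self.pattern:
            n *= len(IUPAC_CODES[ch])
        return n


def expand_iupac(motif: Motif | str) -> frozenset[str]:
    """Expand a degenerate motif into the set of its concrete component CREs.

    The cardinality of the result equals the product of the per-position
    degeneracies (e.g. ``AAARCC`` -> ``{AAAGCC, AAAACC}``).
    """
    if not isinstance(motif, Motif):
        motif = Motif(motif)
    choices = [IUPAC_CODES[ch] for ch in motif.pattern]
    return frozenset("".join(bases) for bases in itertools.product(*choices))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def orientation_variants(seq: str, mode: str = "all") -> list[tuple[str, str]]:
    """Orientation readings of a concrete sequence.

    mode="forward_only" returns just the sequence itself; mode="all" returns
    the forward, reversed, complemented and reverse-complemented readings.
    Identical strings (palindromes and self-complements) are deduplicated,
    keeping the first label in :data:`ORIENTATIONS` priority order.
    """
    if mode == "forward_only":
        return [(seq, "forward")]
    if mode != "all":
        raise ValueError(f"unknown orientation mode {mode!r}")
    readings = [
        (seq, "forward"),
        (seq[::-1], "reverse"),
        (complement(seq), "complement"),
        (reverse_complement(seq), "reverse-complement"),
    ]
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for s, label in readings:
        if s not in seen:
            seen.add(s)
            out.append((s, label))
    return out


@dataclass(frozen=True)
class Query:
    """A user query: one motif, or a pair of motifs forming a candidate CRM."""

    members: tuple[Motif, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 2:
            raise ValueError("a query holds one motif or a pair of motifs")

    @property
    def is_pair(self) -> bool:
        return len(self.members) == 2

    @property
    def label(self) -> str:
        return ",".join(m.pattern for m in self.members)

    def __str__(self) -> str:
        return self.label


def parse_query(text: str) -> Query:
    parts = [p.strip().upper() for p in text.split(",") if p.strip()]
    if not parts:
        raise ValueError(f"empty query line: {text!r}")
    if len(parts) > 2:
        raise ValueError(f"queries hold at most two motifs: {text!r}")
    return Query(tuple(Motif(p) for p in parts))


def read_motif_list(path: str | Path) -> list[Query]:
    """Read a query list: one query per line, comma separates pair members,
    ``#`` starts a comment."""
    queries = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            queries.append(parse_query(line))
    return queries
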