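"""Fixed-length promoter sets.

Promoters are equal-length upstream regions whose 3' (right) end abuts the
transcription start site. All coordinates are 0-based from the 5' (distal)
end; the distance of a match to the TSS is measured from the match's
TSS-proximal edge: ``region_length - (start + len(variant))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASE_CODE = np.full(256, 4, dtype=np.uint8)  # N and anything unknown -> 4
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass
class PromoterSet:
    """Mapping gene id -> uppercase promoter sequence, all of one length."""

    entries: dict[str, str]
    region_length: int
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)
    _index_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty promoter set")
        for gid, seq in self.entries.items():
            if len(seq) != self.region_length:
                raise ValueError(
                    f"promoter {gid!r} has length {len(seq)}, "
                    f"expected {self.region_length}"
                )
        self.genes: list[str] = list(self.entries)
        self.gene_pos: dict[str, int] = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    @property
    def codes(self) -> np.ndarray:
        """(n_genes, region_length) uint8 matrix; A,C,G,T -> 0..3, N -> 4."""
        if self._codes is None:
            buf = "".join(self.entries[g] for g in self.genes).encode("ascii")
            arr = _BASE_CODE[np.frombuffer(buf, dtype=np.uint8)]
            self._codes = arr.reshape(len(self.genes), self.region_length)
        return self._codes

    @classmethod
    def from_fasta(cls, path: str | Path, region_length: int | None = None) -> "PromoterSet":
        entries: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            gid = rec.id  # first whitespace-delimited token
            if gid in entries:
                raise ValueError(f"duplicate gene id {gid!r} in {path}")
            entries[gid] = str(rec.seq).upper()
        if not entries:
            raise ValueError(f"no FASTA records in {path}")
        if region_length is None:
            region_length = len(next(iter(entries.values())))
        return cls(entries, region_length)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.entries[g]), id=g, description="") for g in self.genes
        ]
        SeqIO.write(records, str(path), "fasta")
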