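"""K-mer-indexed motif matching over a promoter set.

Every concrete variant of a query (IUPAC expansions x orientation readings)
is located by looking up its leading k bases in a k-mer index and verifying
the remainder directly against the sequence, which is exactly equivalent to
a naive scan. Promoter ``N`` bases never match any motif position: sequences
are encoded base-5 with N as a fifth symbol that no concrete query encodes.
"""

from __future__ import annotations

import warnings
from typing import Iterable, NamedTuple

import numpy as np

from .motifs import Motif, Query, ORIENTATIONS, expand_iupac, orientation_variants
from .promoters import PromoterSet

#: Longest seed used by the index; variants longer than this are verified
#: against the sequence after the seed lookup.
MAX_K = 8

_ORIENT_RANK = {label: i for i, label in enumerate(ORIENTATIONS)}
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


class MatchRecord(NamedTuple):
    gene_id: str
    start: int
    variant: str
    orientation: str


class KmerIndex:
    """Postings of every k-mer occurrence in a promoter set.

    Postings are stored grouped by a base-5 integer encoding of the k-mer;
    :meth:`postings` exposes the conventional kmer -> [(gene_id, offset)] view.
    """

    def __init__(self, promoters: PromoterSet, k: int):
        L = promoters.region_length
        if not 1 <= k <= L:
            raise ValueError(f"k={k} outside [1, {L}]")
        self.k = k
        self.promoters = promoters
        codes = promoters.codes
        G, _ = codes.shape
        W = L - k + 1
        vals = np.zeros((G, W), dtype=np.int64)
        for j in range(k):
            vals *= 5
            vals += codes[:, j : j + W]
        flat = vals.ravel()
        order = np.argsort(flat, kind="stable")  # stable => (gene, offset) order
        sorted_vals = flat[order]
        self._genes = (order // W).astype(np.int64)
        self._offsets = (order % W).astype(np.int64)
        bounds = np.flatnonzero(np.diff(sorted_vals)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [sorted_vals.size]))
        self._slices = {
            int(sorted_vals[s]): (int(s), int(e)) for s, e in zip(starts, ends)
        }

    @staticmethod
    def encode(kmer: str) -> int | None:
        val = 0
        for ch in kmer:
            code = _ENC.get(ch)
            if code is None:
                return None
            val = val * 5 + code
        return val

    def lookup(self, kmer: str) -> tuple[np.ndarray, np.ndarray]:
        """(gene indices, offsets) of every occurrence of a concrete k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        key = self.encode(kmer)
        span = self._slices.get(key) if key is not None else None
        if span is None:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        s, e = span
        return self._genes[s:e], self._offsets[s:e]

    def postings(self, kmer: str) -> list[tuple[str, int]]:
        genes, offs = self.lookup(kmer)
        names = self.promoters.genes
        return [(names[g], int(o)) for g, o in zip(genes, offs)]

    def n_postings(self) -> int:
        return int(self._genes.size)


def build_index(promoters: PromoterSet, k: int) -> KmerIndex:
    """Build (or fetch from the per-set cache) the k-mer index."""
    cache = promoters._index_cache
    if k not in cache:
        cache[k] = KmerIndex(promoters, k)
    return cache[k]


def variant_table(motif: Motif | str, mode: str = "all") -> list[tuple[str, str]]:
    """Distinct concrete search strings for a motif: IUPAC expansions crossed
    with orientation readings, deduplicated with orientation-priority labels,
    in deterministic order."""
    out: list[tuple[str, str]] = []
    best: dict[str, str] = {}
    for expansion in sorted(expand_iupac(motif)):
        for seq, label in orientation_variants(expansion, mode):
            old = best.get(seq)
            if old is None or _ORIENT_RANK[label] < _ORIENT_RANK[old]:
                best[seq] = label
    for seq in sorted(best):
        out.append((seq, best[seq]))
    return out


def _variant_hits(
    variant: str, promoters: PromoterSet
) -> tuple[np.ndarray, np.ndarray]:
    """All (gene index, start) occurrences of one concrete variant."""
    L = promoters.region_length
    ell = len(variant)
    k = min(ell, MAX_K)
    index = build_index(promoters, k)
    genes, offs = index.lookup(variant[:k])
    if ell > k and genes.size:
        keep = offs <= L - ell
        genes, offs = genes[keep], offs[keep]
        if genes.size:
            tail = np.array([_ENC[c] for c in variant[k:]], dtype=np.uint8)
            cols = offs[:, None] + np.arange(k, ell)
            ok = (promoters.codes[genes[:, None], cols] == tail).all(axis=1)
            genes, offs = genes[ok], offs[ok]
    return genes, offs


def find_matches(
    query: Motif | str, promoters: PromoterSet, mode: str = "all"
) -> list[MatchRecord]:
    """All occurrences of a motif's expansions/orientations in a promoter set.

    Overlapping occurrences are all reported; identical (gene, start, variant)
    records are deduplicated. Result ordered by (gene id, start, variant).
    """
    if not isinstance(query, Motif):
        query = Motif(query)
    if len(query) > promoters.region_length:
        warnings.warn(
            f"motif {query.pattern!r} longer than region_length "
            f"{promoters.region_length}; no matches possible"
        )
        return []
    names = promoters.genes
    records: list[MatchRecord] = []
    for variant, label in variant_table(query, mode):
        genes, offs = _variant_hits(variant, promoters)
        for g, o in zip(genes, offs):
            records.append(MatchRecord(names[g], int(o), variant, label))
    records.sort(key=lambda r: (r.gene_id, r.start, r.variant))
    return records


def matched_genes(matches: Iterable[MatchRecord]) -> set[str]:
    """Gene ids with at least one occurrence."""
    return {m.gene_id for m in matches}


def member_gene_indices(
    motif: Motif | str, promoters: PromoterSet, mode: str = "all"
) -> np.ndarray:
    """Sorted unique indices of promoters containing >=1 occurrence of a motif.

    Fast presence path used by the decision engine; agrees with
    ``matched_genes(find_matches(...))``.
    """
    if not isinstance(motif, Motif):
        motif = Motif(motif)
    if len(motif) > promoters.region_length:
        return np.empty(0, dtype=np.int64)
    parts = [
        _variant_hits(variant, promoters)[0] for variant, _ in variant_table(motif, mode)
    ]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def genes_matching_query(
    query: Query, promoters: PromoterSet, mode: str = "all"
) -> set[str]:
    """Genes satisfying a query: union over a motif's component CREs, and for
    a pair the intersection of the two members' gene sets."""
    idx = query_gene_indices(query, promoters, mode)
    return {promoters.genes[i] for i in idx}


def query_gene_indices(
    query: Query, promoters: PromoterSet, mode: str = "all"
) -> np.ndarray:
    sets = [member_gene_indices(m, promoters, mode) for m in query.members]
    out = sets[0]
    for s in sets[1:]:
        out = np.intersect1d(out, s, assume_unique=True)
    return out
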