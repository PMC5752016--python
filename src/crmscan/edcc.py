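"""The candidate-calling decision engine.

A query motif (or pair) is called a *candidate* when its distribution of
expression maxima (DEM) deviates from the all-genes background by at least a
threshold number of standard deviations in some category, where the standard
deviations come from the DEMs of many random CREs, and the verdict is taken
by majority vote over many independently drawn random backgrounds.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .expression import ExpressionCatalog, background_distribution, dem_from_codes
from .matching import member_gene_indices
from .motifs import Motif, Query
from .promoters import PromoterSet

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: Reason string attached to calls failing the occurrence filter.
INSUFFICIENT = "insufficient occurrences"


def random_cre(rng: np.random.Generator, len_min: int = 5, len_max: int = 8) -> str:
    """A random concrete CRE: length uniform in [len_min, len_max], bases
    i.i.d. uniform over A/C/G/T."""
    if len_min > len_max:
        raise ValueError("len_min > len_max")
    length = int(rng.integers(len_min, len_max + 1))
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def random_query(rng: np.random.Generator, arity: int = 1, len_min: int = 5, len_max: int = 8) -> Query:
    return Query(tuple(Motif(random_cre(rng, len_min, len_max)) for _ in range(arity)))


@dataclass
class BackgroundModel:
    """Per-category mean/sd of the DEMs of ``n_random`` qualifying random CREs."""

    mean: np.ndarray
    sd: np.ndarray
    dems: np.ndarray  # (n_random, n_categories)
    n_rejected: int
    arity: int
    len_min: int
    len_max: int

    @property
    def n_random(self) -> int:
        return self.dems.shape[0]


class _Context:
    """Shared per-(promoters, catalog) precomputation with presence caching."""

    def __init__(self, promoters: PromoterSet, catalog: ExpressionCatalog, mode: str):
        self.promoters = promoters
        self.catalog = catalog
        self.mode = mode
        self.codes = catalog.category_codes(promoters.genes)
        self.background = background_distribution(catalog).values
        self.n_categories = catalog.n_categories
        key = ("_member_presence", mode)
        self._cache = promoters._index_cache.setdefault(key, {})

    def member_indices(self, motif: Motif) -> np.ndarray:
        arr = self._cache.get(motif.pattern)
        if arr is None:
            arr = member_gene_indices(motif, self.promoters, self.mode)
            self._cache[motif.pattern] = arr
        return arr

    def query_indices(self, query: Query) -> np.ndarray:
        out = self.member_indices(query.members[0])
        for m in query.members[1:]:
            out = np.intersect1d(out, self.member_indices(m), assume_unique=True)
        return out

    def query_dem(self, query: Query) -> tuple[int, np.ndarray | None]:
        idx = self.query_indices(query)
        return int(idx.size), dem_from_codes(self.codes[idx], self.n_categories)


def get_context(promoters: PromoterSet, catalog: ExpressionCatalog, mode: str = "all") -> _Context:
    key = ("_edcc_context", id(catalog), mode)
    ctx = promoters._index_cache.get(key)
    if ctx is None:
        ctx = _Context(promoters, catalog, mode)
        promoters._index_cache[key] = ctx
    return ctx


def build_background_model(
    promoters: PromoterSet,
    catalog: ExpressionCatalog,
    rng: np.random.Generator,
    n_random: int = 100,
    min_matches: int = 20,
    len_min: int = 5,
    len_max: int = 8,
    arity: int = 1,
    mode: str = "all",
    max_draw_factor: int = 200,
) -> BackgroundModel:
    """Draw random CREs (or pairs, for arity 2) until ``n_random`` of them
    occur in at least ``min_matches`` promoters and have a defined DEM;
    rejected draws are replaced. Returns per-category mean and sd of the
    qualifying DEMs (sample sd, ddof=1).
    """
    ctx = get_context(promoters, catalog, mode)
    dems = np.empty((n_random, ctx.n_categories))
    accepted = 0
    rejected = 0
    max_draws = max_draw_factor * n_random
    for _ in range(max_draws):
        q = random_query(rng, arity, len_min, len_max)
        n, d = ctx.query_dem(q)
        if n >= min_matches and d is not None:
            dems[accepted] = d
            accepted += 1
            if accepted == n_random:
                break
        else:
            rejected += 1
    else:
        raise RuntimeError(
            f"could not collect {n_random} qualifying random CREs "
            f"within {max_draws} draws (min_matches={min_matches})"
        )
    return BackgroundModel(
        mean=dems.mean(axis=0),
        sd=dems.std(axis=0, ddof=1),
        dems=dems,
        n_rejected=rejected,
        arity=arity,
        len_min=len_min,
        len_max=len_max,
    )


def build_backgrounds(
    promoters: PromoterSet,
    catalog: ExpressionCatalog,
    rng: np.random.Generator,
    n_backgrounds: int = 100,
    **kwargs,
) -> list[BackgroundModel]:
    """The per-run ensemble of independently drawn background models."""
    return [
        build_background_model(promoters, catalog, rng, **kwargs)
        for _ in range(n_backgrounds)
    ]


@dataclass
class CandidateCall:
    """Verdict for one query against a background ensemble."""

    query: Query
    n_matching_promoters: int
    dem: np.ndarray | None
    deviations: np.ndarray | None  # (n_backgrounds, n_categories), in sd units
    votes: int
    n_backgrounds: int
    candidate: bool
    flagged_categories: tuple[str, ...]
    threshold_sd: float
    min_matches: int
    reason: str | None = None


def _deviations(dem: np.ndarray, background: np.ndarray, models: Sequence[BackgroundModel]) -> np.ndarray:
    """|DEM - background| / sd for every background model and category.

    Zero-sd categories: deviation 0 where the DEM equals the background there,
    +inf otherwise (a zero-variance category that moved always flags).
    """
    diff = np.abs(dem - background)
    sds = np.stack([m.sd for m in models])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / sds
    zero = sds == 0
    if zero.any():
        z = np.where(zero & (diff == 0), 0.0, z)
        z = np.where(zero & (diff > 0), np.inf, z)
    return z


def decide(
    query: Query,
    n_matching: int,
    dem: np.ndarray | None,
    deviations: np.ndarray | None,
    catalog: ExpressionCatalog,
    threshold_sd: float,
    min_matches: int,
    n_backgrounds: int,
) -> CandidateCall:
    """Apply threshold + occurrence filter + majority vote to an evaluation."""
    if dem is None or deviations is None:
        return CandidateCall(
            query, n_matching, dem, None, 0, n_backgrounds, False,
            (), threshold_sd, min_matches,
            reason="no cataloged matches" if dem is None else None,
        )
    flags = deviations >= threshold_sd  # (B, C)
    votes = int(flags.any(axis=1).sum())
    majority = votes > n_backgrounds / 2
    flagged = tuple(
        catalog.categories[c]
        for c in np.flatnonzero(flags.sum(axis=0) > n_backgrounds / 2)
    )
    enough = n_matching >= min_matches
    return CandidateCall(
        query, n_matching, dem, deviations, votes, n_backgrounds,
        bool(majority and enough), flagged, threshold_sd, min_matches,
        reason=None if enough else INSUFFICIENT,
    )


def evaluate_query(
    query: Query | str,
    promoters: PromoterSet,
    catalog: ExpressionCatalog,
    backgrounds: Sequence[BackgroundModel] | None = None,
    threshold_sd: float = 1.0,
    min_matches: int = 20,
    n_backgrounds: int = 100,
    n_random: int = 100,
    rng: np.random.Generator | None = None,
    mode: str = "all",
) -> CandidateCall:
    """Evaluate one query: DEM vs. catalog background, per-background
    deviations in sd units, majority vote over the ensemble.

    If ``backgrounds`` is not supplied it is built here (requires ``rng``)
    with arity matched to the query (pair queries get random-pair backgrounds).
    """
    if isinstance(query, str):
        from .motifs import parse_query

        query = parse_query(query)
    ctx = get_context(promoters, catalog, mode)
    if backgrounds is None:
        if rng is None:
            raise ValueError("either backgrounds or rng must be given")
        backgrounds = build_backgrounds(
            promoters, catalog, rng, n_backgrounds=n_backgrounds,
            n_random=n_random, min_matches=min_matches,
            arity=len(query.members), mode=mode,
        )
    n_matching, d = ctx.query_dem(query)
    devs = None if d is None else _deviations(d, ctx.background, backgrounds)
    return decide(
        query, n_matching, d, devs, catalog,
        threshold_sd, min_matches, len(backgrounds),
    )


def quartile_dispersion_coefficient(counts: Sequence[float]) -> float | None:
    """(Q3 - Q1)/(Q3 + Q1) of a sample, linear-interpolation quartiles.

    ``None`` for fewer than two values or a degenerate all-zero sample.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        return None
    q1, q3 = np.percentile(counts, [25, 75])
    if q1 + q3 == 0:
        return None
    return float((q3 - q1) / (q3 + q1))


@dataclass
class QuerySetReport:
    calls: list[list[CandidateCall]]  # per repeat, per query
    candidate_sets: list[set[str]]  # query labels per repeat
    counts: list[int]
    overlap: float | None  # |intersection| / |union| across repeats
    qdc: float | None


def run_query_set(
    queries: Sequence[Query],
    promoters: PromoterSet,
    catalog: ExpressionCatalog,
    rng: np.random.Generator,
    n_repeats: int = 5,
    threshold_sd: float = 1.0,
    min_matches: int = 20,
    n_backgrounds: int = 100,
    n_random: int = 100,
    mode: str = "all",
) -> QuerySetReport:
    """Repeat the whole run (fresh background ensembles) and report the
    candidate overlap fraction and the quartile dispersion coefficient of the
    candidate counts across repeats."""
    if n_repeats < 1:
        raise ValueError("n_repeats >= 1 required")
    ctx = get_context(promoters, catalog, mode)
    evals = [(q, *ctx.query_dem(q)) for q in queries]
    arities = sorted({len(q.members) for q in queries})
    all_calls: list[list[CandidateCall]] = []
    candidate_sets: list[set[str]] = []
    for _ in range(n_repeats):
        ensembles = {
            a: build_backgrounds(
                promoters, catalog, rng, n_backgrounds=n_backgrounds,
                n_random=n_random, min_matches=min_matches, arity=a, mode=mode,
            )
            for a in arities
        }
        calls = []
        for q, n_matching, d in evals:
            models = ensembles[len(q.members)]
            devs = None if d is None else _deviations(d, ctx.background, models)
            calls.append(
                decide(q, n_matching, d, devs, catalog, threshold_sd, min_matches, len(models))
            )
        all_calls.append(calls)
        candidate_sets.append({c.query.label for c in calls if c.candidate})
    union = set().union(*candidate_sets)
    inter = set.intersection(*candidate_sets)
    overlap = len(inter) / len(union) if union else None
    counts = [len(s) for s in candidate_sets]
    return QuerySetReport(
        all_calls, candidate_sets, counts, overlap,
        quartile_dispersion_coefficient(counts) if n_repeats > 1 else None,
    )


def enumerate_pairs(motifs: Sequence[Motif | str]) -> list[Query]:
    """All unordered pairs of a deduplicated motif list, including homotypic
    self-pairs, in lexicographic order: m(m+1)/2 queries."""
    patterns = sorted({m.pattern if isinstance(m, Motif) else str(m).upper() for m in motifs})
    return [
        Query((Motif(a), Motif(b)))
        for a, b in itertools.combinations_with_replacement(patterns, 2)
    ]


def count_pairs(motifs: Sequence[Motif | str]) -> int:
    """Number of unordered (homotypic-inclusive) pairs, by enumeration."""
    patterns = sorted({m.pattern if isinstance(m, Motif) else str(m).upper() for m in motifs})
    return sum(1 for _ in itertools.combinations_with_replacement(patterns, 2))


# ---------------------------------------------------------------------------
# Mutational scan of a CRE pair


@dataclass
class MutantPair:
    members: tuple[str, str]
    n_mutations: int
    call: CandidateCall


@dataclass
class MutationScanResult:
    original: CandidateCall
    mutants: list[MutantPair]
    survivors: list[MutantPair]


def _mutant_space(total_len: int, max_mutations: int) -> int:
    return sum(math.comb(total_len, j) * 3**j for j in range(max_mutations + 1))


def mutation_scan(
    pair: Query,
    promoters: PromoterSet,
    catalog: ExpressionCatalog,
    rng: np.random.Generator,
    n_mutants: int = 1000,
    max_mutations: int = 16,
    backgrounds: Sequence[BackgroundModel] | None = None,
    threshold_sd: float = 1.0,
    min_matches: int = 20,
    n_backgrounds: int = 100,
    n_random: int = 100,
    mode: str = "all",
) -> MutationScanResult:
    """Sample unique mutants of a concrete CRE pair (0..max_mutations base
    substitutions, uniform over positions and alternative bases, duplicates
    rejected) and re-evaluate each under fixed settings.

    A *survivor* is a mutant that is still a candidate with every originally
    flagged category still flagged.
    """
    a, b = (m.pattern for m in pair.members)
    if any(ch not in BASES for ch in a + b):
        raise ValueError("mutation_scan requires concrete pair members")
    total_len = len(a) + len(b)
    space = _mutant_space(total_len, max_mutations)
    if n_mutants > space:
        warnings.warn(
            f"requested {n_mutants} mutants but only {space} exist; capping"
        )
        n_mutants = space
    if backgrounds is None:
        backgrounds = build_backgrounds(
            promoters, catalog, rng, n_backgrounds=n_backgrounds,
            n_random=n_random, min_matches=min_matches, arity=2, mode=mode,
        )
    ctx = get_context(promoters, catalog, mode)

    def call_pair(sa: str, sb: str) -> CandidateCall:
        q = Query((Motif(sa), Motif(sb)))
        n, d = ctx.query_dem(q)
        devs = None if d is None else _deviations(d, ctx.background, backgrounds)
        return decide(q, n, d, devs, catalog, threshold_sd, min_matches, len(backgrounds))

    original_call = call_pair(a, b)
    ref_flags = set(original_call.flagged_categories)
    orig = a + b
    seen: set[tuple[str, str]] = set()
    mutants: list[MutantPair] = []
    attempts = 0
    while len(mutants) < n_mutants and attempts < 100 * n_mutants:
        attempts += 1
        m = int(rng.integers(0, max_mutations + 1))
        chars = list(orig)
        if m:
            positions = rng.choice(total_len, size=m, replace=False)
            for p in positions:
                alts = [x for x in BASES if x != orig[p]]
                chars[p] = alts[int(rng.integers(0, 3))]
        sa, sb = "".join(chars[: len(a)]), "".join(chars[len(a):])
        if (sa, sb) in seen:
            continue
        seen.add((sa, sb))
        n_mut = sum(1 for x, y in zip(sa + sb, orig) if x != y)
        mutants.append(MutantPair((sa, sb), n_mut, call_pair(sa, sb)))
    survivors = [
        mp
        for mp in mutants
        if mp.call.candidate and ref_flags <= set(mp.call.flagged_categories)
    ]
    return MutationScanResult(original_call, mutants, survivors)


def survivor_pwm(
    original_member: str, survivor_members: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position base frequencies over survivors and an importance profile.

    importance[i] = fraction of survivors whose base at position i equals the
    original base (1 - fraction mutated): positions that tolerate no change
    score 1. Returns (freq matrix position x ACGT, importance vector).
    """
    if not survivor_members:
        raise ValueError("at least one survivor required")
    L = len(original_member)
    freqs = np.zeros((L, 4))
    base_pos = {b: i for i, b in enumerate(BASES)}
    for s in survivor_members:
        if len(s) != L:
            raise ValueError("survivor length mismatch")
        for i, ch in enumerate(s):
            freqs[i, base_pos[ch]] += 1
    freqs /= len(survivor_members)
    importance = np.array(
        [freqs[i, base_pos[original_member[i]]] for i in range(L)]
    )
    return freqs, importance
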