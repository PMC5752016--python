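"""Positional statistics for candidate CRE pairs.

Three features per pair, measured over the promoters containing both members:

* distance test — two-sided two-sample Kolmogorov-Smirnov test of the
  observed member-to-member spacings against a simulated null in which the
  expected number of occurrences of each member is dropped uniformly into
  the promoter and the smallest absolute position difference is kept;
* order test — exact binomial test (null probability 0.5) of which member's
  TSS-nearest occurrence lies closer to the TSS;
* Bowley quartile skewness of the module positions, on promoter coordinates
  (TSS at the right end), so TSS-proximal clustering gives negative skew.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .matching import MatchRecord
from .promoters import PromoterSet


class PairPlacement(NamedTuple):
    gene_id: str
    distance: int  # closest spacing between TSS-proximal edges of the members
    crm_position: int  # smallest distance of any constituent CRE to the TSS
    order: str | None  # "A" / "B": which member is TSS-proximal; None on ties


@dataclass
class PositionalStats:
    order_p: float | None
    distance_p: float | None
    bowley: float | None
    n_promoters: int


def _tss_distances(matches: Sequence[MatchRecord], region_length: int) -> dict[str, list[int]]:
    """Per gene: distances of each occurrence's TSS-proximal edge to the TSS."""
    out: dict[str, list[int]] = {}
    for m in matches:
        d = region_length - (m.start + len(m.variant))
        out.setdefault(m.gene_id, []).append(d)
    return out


def observed_placements(
    matches_a: Sequence[MatchRecord],
    matches_b: Sequence[MatchRecord],
    region_length: int,
) -> list[PairPlacement]:
    """Per-promoter placement of a pair over its co-occurring promoters.

    distance: min over occurrence pairs of |d_A - d_B| (TSS-proximal edges);
    crm_position: min over both members' occurrences of the TSS distance;
    order: from the TSS-nearest occurrence of each member, undefined on exact
    ties (such promoters are dropped from the order test only).
    """
    by_gene_a = _tss_distances(matches_a, region_length)
    by_gene_b = _tss_distances(matches_b, region_length)
    placements = []
    for gene in sorted(set(by_gene_a) & set(by_gene_b)):
        da = np.array(by_gene_a[gene])
        db = np.array(by_gene_b[gene])
        spacing = int(np.abs(da[:, None] - db[None, :]).min())
        na, nb = int(da.min()), int(db.min())
        if na < nb:
            order = "A"
        elif nb < na:
            order = "B"
        else:
            order = None
        placements.append(PairPlacement(gene, spacing, min(na, nb), order))
    return placements


def null_distance_distribution(
    rate_a: float,
    rate_b: float,
    region_length: int = 1000,
    iters: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulated null spacings between two CREs placed uniformly at random.

    Per iteration, each member is dropped as many times as it is expected to
    occur in one promoter (rates rounded, floored at one — a co-occurrence
    needs at least one of each), at integer positions uniform in
    [0, region_length); the smallest absolute pairwise position difference is
    recorded. Returns all ``iters`` minima.
    """
    if rate_a <= 0 or rate_b <= 0:
        raise ValueError("occurrence rates must be positive")
    if rng is None:
        rng = np.random.default_rng()
    n_a = max(1, round(rate_a))
    n_b = max(1, round(rate_b))
    pos_a = rng.integers(0, region_length, size=(iters, n_a))
    pos_b = rng.integers(0, region_length, size=(iters, n_b))
    diffs = np.abs(pos_a[:, :, None] - pos_b[:, None, :])
    return diffs.reshape(iters, -1).min(axis=1)


def distance_test(
    observed: Sequence[float], null_sample: Sequence[float]
) -> float | None:
    """Two-sided two-sample KS p-value of observed spacings vs. the null.

    ``None`` (not computed) for fewer than 3 observations; a degenerate
    all-equal null is an error.
    """
    observed = np.asarray(observed, dtype=float)
    null_sample = np.asarray(null_sample, dtype=float)
    if observed.size < 3:
        return None
    if null_sample.size == 0 or np.all(null_sample == null_sample[0]):
        raise ValueError("degenerate null distance sample")
    return float(stats.ks_2samp(observed, null_sample, alternative="two-sided").pvalue)


def order_test(n: int, x: int) -> float | None:
    """Exact two-sided binomial order test with null probability 0.5.

    ``x`` is the count of the more frequent order among ``n`` promoters with a
    defined order; the two-sided p-value doubles the upper tail
    p = min(1, 2 * sum_{i=x..n} C(n,i) * 0.5^n). ``None`` when n = 0.
    """
    if n < 0 or not 0 <= x <= n:
        raise ValueError(f"invalid order counts n={n}, x={x}")
    if x < n - x:
        raise ValueError("x must be the count of the more frequent order")
    if n == 0:
        return None
    return float(min(1.0, 2.0 * stats.binom.sf(x - 1, n, 0.5)))


def order_counts(placements: Sequence[PairPlacement]) -> tuple[int, int]:
    """(n, X): promoters with a defined order, and the majority-order count."""
    orders = [p.order for p in placements if p.order is not None]
    n = len(orders)
    n_a = sum(1 for o in orders if o == "A")
    return n, max(n_a, n - n_a)


def bowley_skewness(positions: Sequence[float]) -> float | None:
    """Bowley's quartile coefficient of skewness S = (Q3 + Q1 - 2 Q2)/(Q3 - Q1).

    Quartiles by linear interpolation between order statistics. S lies in
    [-1, 1] (clipped against floating-point overshoot at the boundary);
    negative values indicate a left-skewed distribution. ``None`` (not
    computed) for fewer than 4 values or when Q3 == Q1.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size < 4:
        return None
    q1, q2, q3 = np.percentile(positions, [25, 50, 75])
    if q3 == q1:
        return None
    return float(np.clip((q3 + q1 - 2 * q2) / (q3 - q1), -1.0, 1.0))


def pair_positional_stats(
    matches_a: Sequence[MatchRecord],
    matches_b: Sequence[MatchRecord],
    promoters: PromoterSet,
    rng: np.random.Generator,
    iters: int = 10_000,
) -> PositionalStats:
    """Bundle the three positional features for one pair.

    Occurrence rates for the null are estimated as total occurrences divided
    by the number of promoters in the set. Bowley skewness is computed on
    promoter coordinates (region_length - TSS distance), so modules clustered
    near the TSS skew negative.
    """
    L = promoters.region_length
    placements = observed_placements(matches_a, matches_b, L)
    n_co = len(placements)
    if n_co == 0 or not matches_a or not matches_b:
        return PositionalStats(None, None, None, n_co)
    n, x = order_counts(placements)
    order_p = order_test(n, x) if n > 0 else None
    distances = [p.distance for p in placements]
    distance_p = None
    if len(distances) >= 3:
        rate_a = len(matches_a) / len(promoters)
        rate_b = len(matches_b) / len(promoters)
        null = null_distance_distribution(rate_a, rate_b, L, iters, rng)
        distance_p = distance_test(distances, null)
    coords = [L - p.crm_position for p in placements]
    return PositionalStats(order_p, distance_p, bowley_skewness(coords), n_co)
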