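"""Synthetic promoter sets with planted CRE/CRM signals.

The generator produces the statistical structure the analysis assumes: fixed
length promoters, a one-category-per-gene expression catalog, and planted
motifs or motif pairs with controlled position models, order bias, and
category enrichment. Ground-truth manifests record every planted coordinate
so downstream statistics can be checked against construction parameters.

Plants overwrite sequence windows (never insert), keeping region_length and
hence all positional arithmetic exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionCatalog, ZT_CATEGORIES
from .motifs import Motif, Query
from .promoters import PromoterSet

_BASES = np.array(list("ACGT"))


def generate_promoters(
    n: int,
    region_length: int = 1000,
    base_probs: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    prefix: str = "g",
) -> PromoterSet:
    """i.i.d. random promoter sequences, seed-reproducible."""
    if n < 1:
        raise ValueError("n >= 1 required")
    if rng is None:
        rng = np.random.default_rng()
    if base_probs is None:
        draws = rng.integers(0, 4, size=(n, region_length))
    else:
        p = np.asarray(base_probs, dtype=float)
        p = p / p.sum()
        draws = rng.choice(4, size=(n, region_length), p=p)
    width = max(4, len(str(n)))
    entries = {
        f"{prefix}{i:0{width}d}": "".join(_BASES[row]) for i, row in enumerate(draws)
    }
    return PromoterSet(entries, region_length)


@dataclass
class PlantSpec:
    """What to plant and how.

    position_model:
      * ``uniform`` — TSS distance of the (proximal) member uniform over the
        feasible range; for pairs the spacing is drawn as |U - V| for two
        iid uniform positions, i.e. exactly the uniform-placement null;
      * ``tss_proximal`` — TSS distance ~ Exponential(tss_scale), truncated;
        pair spacing as above;
      * ``fixed_spacing`` — pairs only; spacing = spacing ± jitter.

    order_pi is the probability that the *first* member is the TSS-proximal
    one (pairs only). rho is the probability a planted gene is assigned the
    target expression category.
    """

    members: tuple[str, ...]
    n_target_promoters: int
    position_model: str = "uniform"
    tss_scale: float = 120.0
    spacing: int | None = None
    jitter: int = 0
    order_pi: float = 0.95
    target_category: str | None = None
    rho: float = 0.9

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 2:
            raise ValueError("plant one motif or a pair")
        for m in self.members:
            if any(ch not in "ACGT" for ch in m):
                raise ValueError("planted motifs must be concrete A/C/G/T")
        if len(self.members) == 2 and not 0.5 <= self.order_pi <= 1.0:
            raise ValueError("order_pi must lie in [0.5, 1]")
        if self.position_model not in ("uniform", "tss_proximal", "fixed_spacing"):
            raise ValueError(f"unknown position model {self.position_model!r}")
        if self.position_model == "fixed_spacing" and self.spacing is None:
            raise ValueError("fixed_spacing requires spacing")

    @property
    def query(self) -> Query:
        return Query(tuple(Motif(m) for m in self.members))


def _draw_tss_distance(rng: np.random.Generator, model: str, scale: float, bound: int) -> int:
    """TSS distance of a proximal edge, in [0, bound]."""
    if model == "uniform" or model == "fixed_spacing":
        return int(rng.integers(0, bound + 1))
    for _ in range(1000):
        d = int(rng.exponential(scale))
        if d <= bound:
            return d
    return int(rng.integers(0, bound + 1))


def plant(
    promoters: PromoterSet, spec: PlantSpec, rng: np.random.Generator
) -> tuple[PromoterSet, pd.DataFrame]:
    """Overwrite windows of randomly chosen promoters with the planted
    motif(s); returns the modified set plus the exact placement manifest."""
    L = promoters.region_length
    genes = list(promoters.genes)
    if spec.n_target_promoters > len(genes):
        raise ValueError("more target promoters requested than available")
    targets = [genes[i] for i in rng.choice(len(genes), spec.n_target_promoters, replace=False)]
    rows = []
    for gene in targets:
        if len(spec.members) == 1:
            m = spec.members[0]
            d = _draw_tss_distance(rng, spec.position_model, spec.tss_scale, L - len(m))
            start = L - d - len(m)
            rows.append((gene, 0, m, start, d, "single"))
        else:
            a, b = spec.members
            max_len = max(len(a), len(b))
            # spacing between TSS-proximal edges; resampled only when the
            # members would overlap or fall off the distal end
            for _ in range(10_000):
                if spec.position_model == "fixed_spacing":
                    s = spec.spacing + (int(rng.integers(-spec.jitter, spec.jitter + 1)) if spec.jitter else 0)
                else:
                    u, v = rng.integers(0, L, size=2)
                    s = int(abs(u - v))
                if s >= max_len and s + max_len <= L:
                    break
            else:
                raise RuntimeError("could not draw a feasible spacing")
            proximal_first = rng.random() < spec.order_pi
            prox, dist = (a, b) if proximal_first else (b, a)
            d_prox = _draw_tss_distance(
                rng, spec.position_model, spec.tss_scale, L - s - len(dist)
            )
            d_dist = d_prox + s
            placements = [(0, a), (1, b)] if proximal_first else [(1, b), (0, a)]
            for (member_idx, m), (dd, role) in zip(
                placements, ((d_prox, "proximal"), (d_dist, "distal"))
            ):
                start = L - dd - len(m)
                rows.append((gene, member_idx, m, start, dd, role))
    rebuilt = dict(promoters.entries)
    for gene, _, m, start, _, _ in rows:
        s = rebuilt[gene]
        rebuilt[gene] = s[:start] + m + s[start + len(m):]
    manifest = pd.DataFrame(
        rows, columns=["gene_id", "member", "sequence", "start", "tss_distance", "role"]
    )
    return PromoterSet(rebuilt, L), manifest


def generate_catalog(
    genes: Sequence[str],
    rng: np.random.Generator,
    categories: Sequence[str] = ZT_CATEGORIES,
    weights: Sequence[float] | None = None,
    planted_genes: Sequence[str] = (),
    target_category: str | None = None,
    rho: float = 0.9,
) -> ExpressionCatalog:
    """Assign every gene one category: unplanted genes follow the background
    weights; planted genes get the target category with probability rho, else
    one of the remaining categories uniformly."""
    categories = tuple(categories)
    k = len(categories)
    if weights is None:
        w = np.full(k, 1.0 / k)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    planted = set(planted_genes)
    if planted and target_category is None:
        raise ValueError("target_category required when planting enrichment")
    if planted and not (1.0 / k) <= rho <= 1.0:
        raise ValueError(f"rho must lie in [1/{k}, 1]")
    assignment: dict[str, str] = {}
    others = [c for c in categories if c != target_category]
    for g in genes:
        if g in planted:
            if rng.random() < rho:
                assignment[g] = target_category
            else:
                assignment[g] = others[int(rng.integers(0, len(others)))]
        else:
            assignment[g] = categories[int(rng.choice(k, p=w))]
    return ExpressionCatalog(categories, assignment)


def _degenerate_heptamer(rng: np.random.Generator) -> str:
    """A heptamer with two N positions: ~16 concrete expansions, so its
    promoter occupancy is near-saturating — the profile of curated,
    degenerate CRE collections."""
    chars = [ "ACGT"[i] for i in rng.integers(0, 4, size=7) ]
    ns = rng.choice(7, size=2, replace=False)
    for i in ns:
        chars[i] = "N"
    return "".join(chars)


@dataclass
class Fixture:
    """A named synthetic study: promoters + catalog + query list + truth."""

    name: str
    promoters: PromoterSet | None
    catalog: ExpressionCatalog | None
    queries: list[Query]
    manifest: pd.DataFrame | None
    truth: dict
    training_set: object | None = None  # TrainingSet for the network fixture
    sweep_queries: list[Query] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.promoters is not None:
            self.promoters.to_fasta(outdir / "promoters.fasta")
        if self.catalog is not None:
            self.catalog.to_tsv(outdir / "catalog.tsv")
        if self.queries:
            (outdir / "queries.txt").write_text(
                "".join(q.label + "\n" for q in self.queries)
            )
        if self.sweep_queries:
            (outdir / "sweep_queries.txt").write_text(
                "".join(q.label + "\n" for q in self.sweep_queries)
            )
        if self.manifest is not None:
            self.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        if self.training_set is not None:
            from .cng import INPUT_NAMES

            ts = self.training_set
            pd.DataFrame(
                ts.positives, columns=list(INPUT_NAMES), index=ts.positive_keys
            ).rename_axis("pair").to_csv(outdir / "positives.tsv", sep="\t")
            pd.DataFrame(
                ts.randoms, columns=list(INPUT_NAMES), index=ts.random_keys
            ).rename_axis("pair").to_csv(outdir / "randoms.tsv", sep="\t")


#: Planted module of the pair fixtures: a G-box-like 9-mer and a concrete 8-mer.
PAIR_MEMBERS = ("CCACGTGGC", "AGATATTT")
#: Planted motif of the single-CRE fixture: the evening element.
EVENING_ELEMENT = "AAAATATCT"

N_PROMOTERS = 200
REGION_LENGTH = 1000


def _unique_random_queries(rng, n, make) -> list[Query]:
    out: list[Query] = []
    seen: set[str] = set()
    while len(out) < n:
        q = make(rng)
        if q.label not in seen:
            seen.add(q.label)
            out.append(q)
    return out


def standard_fixtures(seed: int) -> dict[str, Fixture]:
    """The deterministic fixture bundle used throughout the test suite.

    * ``null`` — no plants; calibration queries are degenerate heptamers,
      plus a mixed-length concrete query set for threshold sweeps;
    * ``single-cre`` — the evening element planted in 50 of 200 promoters
      with 90% of planted genes in one category;
    * ``pair-order`` — a pair planted TSS-proximally with order bias 0.95 and
      null-distributed spacing (significant order, negative skew, no distance
      preference, by construction);
    * ``pair-spacing`` — the same pair at a fixed 50 bp spacing;
    * ``two-cluster`` — a network training set with two well-separated positive
      clusters over a uniform random cloud, one per module archetype:
      order-preferring TSS-proximal pairs (small order p, negative skew) and
      spacing-preferring pairs (small distance p).
    """
    from .cng import TrainingSet  # local import to avoid a cycle

    root = np.random.default_rng(seed)
    rngs = {name: np.random.default_rng(s) for name, s in zip(
        ("null", "single-cre", "pair-order", "pair-spacing", "two-cluster"),
        root.integers(0, 2**31 - 1, size=5),
    )}
    fixtures: dict[str, Fixture] = {}

    # -- null ---------------------------------------------------------------
    rng = rngs["null"]
    promoters = generate_promoters(N_PROMOTERS, REGION_LENGTH, rng=rng)
    catalog = generate_catalog(promoters.genes, rng)
    calib = _unique_random_queries(
        rng, 60, lambda r: Query((Motif(_degenerate_heptamer(r)),))
    )
    sweep = _unique_random_queries(
        rng, 40, lambda r: Query((Motif("".join("ACGT"[i] for i in r.integers(0, 4, size=5 + int(r.integers(0, 4))))),))
    )
    fixtures["null"] = Fixture("null", promoters, catalog, calib, None, {}, sweep_queries=sweep)

    # -- single-cre ---------------------------------------------------------
    rng = rngs["single-cre"]
    promoters = generate_promoters(N_PROMOTERS, REGION_LENGTH, rng=rng)
    spec = PlantSpec(
        (EVENING_ELEMENT,), n_target_promoters=50, position_model="uniform",
        target_category="ZT8-ZT12", rho=0.9,
    )
    promoters, manifest = plant(promoters, spec, rng)
    catalog = generate_catalog(
        promoters.genes, rng, planted_genes=manifest["gene_id"].unique(),
        target_category=spec.target_category, rho=spec.rho,
    )
    from .edcc import random_query

    queries = [spec.query] + _unique_random_queries(rng, 99, lambda r: random_query(r))
    fixtures["single-cre"] = Fixture(
        "single-cre", promoters, catalog, queries, manifest,
        {"planted": spec.query.label, "target_category": spec.target_category, "spec": spec},
    )

    # -- pair-order ---------------------------------------------------------
    rng = rngs["pair-order"]
    promoters = generate_promoters(N_PROMOTERS, REGION_LENGTH, rng=rng)
    spec = PlantSpec(
        PAIR_MEMBERS, n_target_promoters=60, position_model="tss_proximal",
        tss_scale=120.0, order_pi=0.95, target_category="ZT4-ZT8", rho=0.9,
    )
    promoters, manifest = plant(promoters, spec, rng)
    catalog = generate_catalog(
        promoters.genes, rng, planted_genes=manifest["gene_id"].unique(),
        target_category=spec.target_category, rho=spec.rho,
    )
    fixtures["pair-order"] = Fixture(
        "pair-order", promoters, catalog, [spec.query], manifest,
        {"planted": spec.query.label, "target_category": spec.target_category, "spec": spec},
    )

    # -- pair-spacing -------------------------------------------------------
    rng = rngs["pair-spacing"]
    promoters = generate_promoters(N_PROMOTERS, REGION_LENGTH, rng=rng)
    spec = PlantSpec(
        PAIR_MEMBERS, n_target_promoters=60, position_model="fixed_spacing",
        spacing=50, jitter=0, order_pi=0.5, target_category="ZT12-ZT16", rho=0.9,
    )
    promoters, manifest = plant(promoters, spec, rng)
    catalog = generate_catalog(
        promoters.genes, rng, planted_genes=manifest["gene_id"].unique(),
        target_category=spec.target_category, rho=spec.rho,
    )
    fixtures["pair-spacing"] = Fixture(
        "pair-spacing", promoters, catalog, [spec.query], manifest,
        {"planted": spec.query.label, "spacing": 50, "spec": spec},
    )

    # -- two-cluster --------------------------------------------------------
    rng = rngs["two-cluster"]
    c1 = np.column_stack([
        np.clip(rng.normal(-0.8, 0.03, 25), -1, 1),
        np.clip(rng.normal(0.30, 0.05, 25), 0, 1),
        np.clip(rng.normal(0.005, 0.002, 25), 1e-6, 1),
    ])
    c2 = np.column_stack([
        np.clip(rng.normal(0.75, 0.03, 25), -1, 1),
        np.clip(rng.normal(0.005, 0.002, 25), 1e-6, 1),
        np.clip(rng.normal(0.70, 0.05, 25), 0, 1),
    ])
    positives = np.vstack([c1, c2])
    keys = [f"c1-{i:02d}" for i in range(25)] + [f"c2-{i:02d}" for i in range(25)]
    n_rand = 600
    randoms = np.column_stack([
        rng.uniform(-1, 1, n_rand), rng.uniform(0, 1, n_rand), rng.uniform(0, 1, n_rand)
    ])
    ts = TrainingSet(positives, keys, randoms, [f"r{i:03d}" for i in range(n_rand)])
    fixtures["two-cluster"] = Fixture(
        "two-cluster", None, None, [], None,
        {"cluster_keys": (keys[:25], keys[25:])}, training_set=ts,
    )
    return fixtures
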