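"""Expression catalogs and distributions of expression maxima (DEMs).

Each gene belongs to exactly one expression category (for the circadian case
study: the six 4-hour Zeitgeber-time bins, assigned by the condition of
maximum expression). The percentage distribution of a gene set over the
ordered categories is the DEM; computed over all cataloged genes it is the
background distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Category labels of the circadian case study (4-hour peak-time bins).
ZT_CATEGORIES = ("ZT0-ZT4", "ZT4-ZT8", "ZT8-ZT12", "ZT12-ZT16", "ZT16-ZT20", "ZT20-ZT0")


@dataclass
class ExpressionCatalog:
    """Ordered category labels plus a gene -> category assignment."""

    categories: tuple[str, ...]
    assignment: dict[str, str]
    _codes: dict[str, int] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        cat_pos = {c: i for i, c in enumerate(self.categories)}
        if len(cat_pos) != len(self.categories):
            raise ValueError("duplicate category labels")
        for g, c in self.assignment.items():
            if c not in cat_pos:
                raise ValueError(f"gene {g!r} assigned to unknown category {c!r}")
        self._codes = {g: cat_pos[c] for g, c in self.assignment.items()}

    def __len__(self) -> int:
        return len(self.assignment)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def category_codes(self, genes: Sequence[str]) -> np.ndarray:
        """Integer category per gene, -1 for genes absent from the catalog."""
        return np.array([self._codes.get(g, -1) for g in genes], dtype=np.int64)

    @classmethod
    def from_tsv(cls, path: str | Path, categories: Sequence[str] | None = None) -> "ExpressionCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene_id", "category"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns gene_id, category")
        if categories is None:
            categories = tuple(dict.fromkeys(df["category"]))
        return cls(tuple(categories), dict(zip(df["gene_id"], df["category"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"gene_id": list(self.assignment), "category": list(self.assignment.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Distribution:
    """Per-category percentages over an ordered category list (sum 100)."""

    categories: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.categories),):
            raise ValueError("one value per category required")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.categories))


def categorize_by_max(
    expr: pd.DataFrame,
    condition_to_category: Mapping[str, str],
    categories: Sequence[str],
) -> ExpressionCatalog:
    """Assign each gene to the category containing its maximum-expression
    condition.

    ``expr`` is a gene x condition matrix (index = gene ids). Ties are broken
    by the earliest category in the ordered list (logged); genes with
    all-missing values are excluded with a warning.
    """
    categories = tuple(categories)
    missing = set(expr.columns) - set(condition_to_category)
    if missing:
        raise ValueError(f"conditions without category mapping: {sorted(missing)}")
    cat_pos = {c: i for i, c in enumerate(categories)}
    col_cat = np.array([cat_pos[condition_to_category[c]] for c in expr.columns])
    values = expr.to_numpy(dtype=float)
    assignment: dict[str, str] = {}
    n_ties = n_dropped = 0
    for gene, row in zip(expr.index, values):
        if np.all(np.isnan(row)):
            n_dropped += 1
            continue
        best = np.nanmax(row)
        cats = col_cat[np.flatnonzero(row == best)]
        if cats.size > 1 and len(set(cats.tolist())) > 1:
            n_ties += 1
        assignment[str(gene)] = categories[int(cats.min())]
    if n_dropped:
        logger.warning("categorize_by_max: %d genes with all-missing values excluded", n_dropped)
    if n_ties:
        logger.info("categorize_by_max: %d ties broken by earliest category", n_ties)
    return ExpressionCatalog(categories, assignment)


def _percentages(counts: np.ndarray) -> np.ndarray:
    return 100.0 * counts / counts.sum()


def background_distribution(catalog: ExpressionCatalog) -> Distribution:
    """Percentage of all cataloged genes per category."""
    if not catalog.assignment:
        raise ValueError("empty catalog")
    codes = catalog.category_codes(list(catalog.assignment))
    counts = np.bincount(codes, minlength=catalog.n_categories).astype(float)
    return Distribution(catalog.categories, _percentages(counts))


def dem(gene_set: Iterable[str], catalog: ExpressionCatalog) -> Distribution | None:
    """Distribution of expression maxima of a gene set.

    Genes absent from the catalog are dropped (count logged); an empty
    intersection yields ``None`` (undefined DEM), never a zero distribution.
    """
    genes = list(gene_set)
    codes = catalog.category_codes(genes)
    dropped = int((codes < 0).sum())
    if dropped:
        logger.debug("dem: %d of %d genes not in catalog", dropped, len(genes))
    codes = codes[codes >= 0]
    if codes.size == 0:
        return None
    counts = np.bincount(codes, minlength=catalog.n_categories).astype(float)
    return Distribution(catalog.categories, _percentages(counts))


def dem_from_codes(codes: np.ndarray, n_categories: int) -> np.ndarray | None:
    """DEM values from precomputed category codes (-1 = not cataloged).

    Fast path used by the decision engine; mirrors :func:`dem`.
    """
    codes = codes[codes >= 0]
    if codes.size == 0:
        return None
    counts = np.bincount(codes, minlength=n_categories).astype(float)
    return _percentages(counts)
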