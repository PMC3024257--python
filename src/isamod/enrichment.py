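"""Hypergeometric over-representation of annotation categories with
Benjamini-Hochberg control, over gene lists and module gene sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class EnrichmentError(ValueError):
    pass


@dataclass
class Category:
    """A named gene set with optional namespace/level metadata."""

    name: str
    genes: frozenset
    namespace: str | None = None
    level: int | None = None

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise EnrichmentError(f"category {self.name!r} has an empty gene set")


class AnnotationMap:
    """Mapping from category id to :class:`Category`."""

    def __init__(self, categories: Mapping[str, Category] | None = None):
        self._categories: dict[str, Category] = dict(categories or {})

    def add(self, cat_id: str, category: Category) -> None:
        if cat_id in self._categories:
            raise EnrichmentError(f"duplicate category id {cat_id!r}")
        self._categories[cat_id] = category

    def __getitem__(self, cat_id: str) -> Category:
        return self._categories[cat_id]

    def __contains__(self, cat_id: str) -> bool:
        return cat_id in self._categories

    def __len__(self) -> int:
        return len(self._categories)

    def __iter__(self):
        return iter(self._categories)

    def items(self):
        return self._categories.items()

    def filter_level(self, level: int) -> "AnnotationMap":
        return AnnotationMap(
            {cid: c for cid, c in self.items() if c.level == level}
        )


@dataclass
class EnrichmentRow:
    category_id: str
    raw_p: float
    adjusted_p: float
    odds_ratio: float
    expected_count: float
    count: int
    category_size: int
    direction: str = ""


def expected_count(category_size: int, selected: int, universe: int) -> float:
    """Hypergeometric mean overlap: ``category_size * selected / universe``."""
    if universe <= 0:
        raise EnrichmentError("universe must be positive")
    if category_size > universe or selected > universe:
        raise EnrichmentError("category/selected cannot exceed universe")
    return category_size * selected / universe


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    # sample cross-product ratio; Haldane 0.5 correction only when a cell is 0
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def hypergeom_test(
    category: Iterable,
    selected: Iterable,
    universe: Iterable,
    per_gene_direction: Mapping | None = None,
) -> EnrichmentRow:
    """One-sided (greater) hypergeometric over-representation test of
    ``category`` within ``selected`` from ``universe``.

    ``per_gene_direction`` optionally maps gene -> sign (+/-) and yields the
    ``ind`` / ``sup`` / ``ind/sup`` direction label of the overlap genes.
    """
    universe = frozenset(universe)
    category = frozenset(category)
    selected = frozenset(selected)
    if not category <= universe:
        raise EnrichmentError("category must be a subset of the universe")
    if not selected <= universe:
        raise EnrichmentError("selected must be a subset of the universe")
    overlap = category & selected
    count, K, n_sel, N = len(overlap), len(category), len(selected), len(universe)
    raw_p = float(stats.hypergeom.sf(count - 1, N, K, n_sel))
    a = count
    b = K - count
    c = n_sel - count
    d = N - K - n_sel + count
    direction = ""
    if per_gene_direction is not None and overlap:
        signs = {np.sign(per_gene_direction[g]) for g in overlap if g in per_gene_direction}
        if signs == {1}:
            direction = "ind"
        elif signs == {-1}:
            direction = "sup"
        else:
            direction = "ind/sup"
    return EnrichmentRow(
        category_id="",
        raw_p=raw_p,
        adjusted_p=raw_p,
        odds_ratio=_odds_ratio(a, b, c, d),
        expected_count=expected_count(K, n_sel, N),
        count=count,
        category_size=K,
        direction=direction,
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def enrich_modules(
    modules: Sequence,
    ann: AnnotationMap,
    universe: Iterable,
    level_filter: int | None = None,
    per_gene_direction: Mapping | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every category against every module gene
    set, with BH correction over the pooled (module x category) family.

    Categories are restricted to the universe before testing; ``level_filter``
    keeps only categories whose metadata ``level`` matches.
    """
    universe = frozenset(universe)
    if not universe:
        raise EnrichmentError("universe must be non-empty")
    if level_filter is not None:
        ann = ann.filter_level(level_filter)
    rows = []
    for module in modules:
        genes = frozenset(module.gene_set) & universe
        if not genes:
            continue
        for cat_id, cat in ann.items():
            cat_genes = cat.genes & universe
            if not cat_genes:
                continue
            row = hypergeom_test(cat_genes, genes, universe, per_gene_direction)
            rows.append(
                {
                    "module_id": module.id,
                    "category_id": cat_id,
                    "term": cat.name,
                    "raw_p": row.raw_p,
                    "odds_ratio": row.odds_ratio,
                    "expected_count": row.expected_count,
                    "count": row.count,
                    "category_size": row.category_size,
                    "direction": row.direction,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "module_id",
            "category_id",
            "term",
            "raw_p",
            "odds_ratio",
            "expected_count",
            "count",
            "category_size",
            "direction",
        ],
    )
    if len(table):
        table["adjusted_p"] = bh_adjust(table["raw_p"].to_numpy())
        table = table.sort_values(["adjusted_p", "raw_p"], kind="stable").reset_index(
            drop=True
        )
    else:
        table["adjusted_p"] = pd.Series(dtype=float)
    return table


def enrich_gene_list(
    selected: Iterable,
    ann: AnnotationMap,
    universe: Iterable,
    level_filter: int | None = None,
    per_gene_direction: Mapping | None = None,
) -> pd.DataFrame:
    """Enrichment of a single gene list; BH over the tested categories."""
    universe = frozenset(universe)
    selected = frozenset(selected) & universe
    if level_filter is not None:
        ann = ann.filter_level(level_filter)
    rows = []
    for cat_id, cat in ann.items():
        cat_genes = cat.genes & universe
        if not cat_genes:
            continue
        row = hypergeom_test(cat_genes, selected, universe, per_gene_direction)
        rows.append(
            {
                "category_id": cat_id,
                "term": cat.name,
                "raw_p": row.raw_p,
                "odds_ratio": row.odds_ratio,
                "expected_count": row.expected_count,
                "count": row.count,
                "category_size": row.category_size,
                "direction": row.direction,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["adjusted_p"] = bh_adjust(table["raw_p"].to_numpy())
        table = table.sort_values(["adjusted_p", "raw_p"], kind="stable").reset_index(
            drop=True
        )
    return table
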