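"""Gene-set overrepresentation analysis.

Three-way partition of two DEG sets (A-only / overlap / B-only), term-size
filtering of a GMT-backed gene-set collection to the 15-400-gene window,
and the upper-tail hypergeometric test with BH adjustment within each
(query, namespace) family. The enrichment ratio (k/n)/(K/N) — observed over
expected query fraction in a term — is carried on every row because the
downstream redundancy reduction ranks terms by it.

The background universe is the caller's choice; the pipeline uses all genes
with a defined DE test result, which is what was actually measurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .diffexpr import DegSet

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "partition_degs",
    "filter_terms",
    "hypergeom_enrich",
]

NAMESPACES = ("BP", "CC", "MF")
TERM_SIZE_MIN = 15
TERM_SIZE_MAX = 400


@dataclass(frozen=True)
class GeneSet:
    """One named term: id, display name, namespace (BP/CC/MF), member genes."""

    term_id: str
    name: str
    namespace: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has no member genes")

    def __len__(self):
        return len(self.genes)


class GeneSetCollection:
    """An ordered collection of unique GeneSets, GMT-serializable."""

    def __init__(self, terms: Iterable[GeneSet]):
        self._terms: dict[str, GeneSet] = {}
        for t in terms:
            if t.term_id in self._terms:
                raise ValueError(f"duplicate term id {t.term_id!r}")
            self._terms[t.term_id] = t

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._terms.values())

    def __len__(self):
        return len(self._terms)

    def __contains__(self, term_id):
        return term_id in self._terms

    def __getitem__(self, term_id) -> GeneSet:
        return self._terms[term_id]

    def term_ids(self) -> list[str]:
        return list(self._terms)

    def namespaces(self) -> list[str]:
        return sorted({t.namespace for t in self})

    def subset(self, term_ids) -> "GeneSetCollection":
        return GeneSetCollection(self._terms[t] for t in term_ids)

    def restrict(self, universe: set) -> "GeneSetCollection":
        """Intersect every term with a universe, dropping emptied terms."""
        universe = set(universe)
        kept = []
        for t in self:
            g = t.genes & universe
            if g:
                kept.append(GeneSet(t.term_id, t.name, t.namespace, frozenset(g)))
        return GeneSetCollection(kept)


def partition_degs(set_a: DegSet, set_b: DegSet) -> dict[str, set]:
    """Split two DEG sets into {A_only, overlap, B_only} (disjoint, union-preserving)."""
    a, b = set(set_a.genes), set(set_b.genes)
    return {"A_only": a - b, "overlap": a & b, "B_only": b - a}


def filter_terms(
    collection: GeneSetCollection,
    min_size: int = TERM_SIZE_MIN,
    max_size: int = TERM_SIZE_MAX,
    universe: set | None = None,
) -> GeneSetCollection:
    """Keep terms whose in-universe membership is within [min_size, max_size].

    Members are intersected with the universe before the size check, so the
    bounds apply to what is actually measurable, not the full annotation.
    """
    if min_size > max_size:
        raise ValueError(f"min_size {min_size} > max_size {max_size}")
    kept = []
    for t in collection:
        members = t.genes & universe if universe is not None else t.genes
        if min_size <= len(members) <= max_size:
            kept.append(GeneSet(t.term_id, t.name, t.namespace, frozenset(members)))
    return GeneSetCollection(kept)


def hypergeom_enrich(
    query: set,
    collection: GeneSetCollection,
    universe: set,
    query_id: str = "query",
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of every term in a query.

    For a term with K in-universe members, a query of n genes, and overlap
    k in a universe of N genes, p = P(X >= k), X ~ Hypergeometric(N, K, n).
    BH adjustment is applied within each (query_id, namespace) family.
    Query genes outside the universe are dropped with a warning. Returns one
    row per term with a significance flag at p_adj <= padj_max.
    """
    universe = set(universe)
    query = set(query)
    stray = query - universe
    if stray:
        warnings.warn(f"{len(stray)} query genes outside the universe were dropped")
        query &= universe
    if not query:
        raise ValueError("query is empty (after universe restriction)")
    N = len(universe)
    n = len(query)

    rows = []
    for t in collection:
        members = t.genes & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        ratio = (k / n) / (K / N)
        rows.append((t.term_id, t.name, t.namespace, query_id, k, n, K, N, p, ratio))
    df = pd.DataFrame(
        rows,
        columns=["term_id", "name", "namespace", "query_id", "k", "n", "K", "N", "p", "ratio"],
    )
    df["p_adj"] = float("nan")
    for ns, idx in df.groupby("namespace").groups.items():
        df.loc[idx, "p_adj"] = multipletests(df.loc[idx, "p"], method="fdr_bh")[1]
    df["significant"] = df["p_adj"] <= padj_max
    return df
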