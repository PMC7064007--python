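"""Over-representation statistics for modules and gene lists.

Classic one-sided tests on flat annotation sets: per-term hypergeometric
upper-tail p-values for GO enrichment, a one-sided Fisher exact test for the
custom cell-wall gene list, keyword grouping of significant terms, and the
BP/CC cell-wall term counts used to score bait subnetworks.  No
ontology-graph decorrelation is applied and no multiple-testing correction
is applied by default (a raw 0.05 threshold defines significance); an
optional Benjamini-Hochberg adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .data import AnnotationTable, KeywordMap

__all__ = [
    "EnrichmentResult",
    "term_enrichment",
    "custom_list_enrichment",
    "group_terms_by_keyword",
    "count_cw_terms",
    "CW_KEYWORDS_DEFAULT",
]

CW_KEYWORDS_DEFAULT = ("SCW", "cellulose", "xylan", "lignin", "pectin",
                       "cell_wall_CC")


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's (or list's) over-representation in a gene set."""

    term_id: str
    namespace: str
    set_count: int
    set_size: int
    universe_count: int
    universe_size: int
    p_value: float
    significant: bool

    def as_row(self) -> dict:
        return self.__dict__.copy()


def _hypergeom_upper_tail(k: int, M: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(M, n, N)."""
    return float(hypergeom.sf(k - 1, M, n, N))


def term_enrichment(
    gene_set: set[str],
    annotation: AnnotationTable,
    universe: set[str],
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Per-term hypergeometric enrichment of ``gene_set`` within ``universe``.

    Only terms annotating at least one universe gene are tested.  Results are
    sorted by p-value, then term ID.  With ``adjust=True`` significance is
    called on Benjamini-Hochberg adjusted p-values instead of raw ones.
    """
    if not universe:
        raise ValueError("empty universe")
    extra = gene_set - universe
    if extra:
        raise ValueError(f"gene set outside the universe: {sorted(extra)[:5]}")
    if not gene_set:
        return []
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in annotation.terms_for(gene):
            term_genes.setdefault(term, set()).add(gene)
    M, N = len(universe), len(gene_set)
    results = []
    for term in sorted(term_genes):
        in_universe = term_genes[term]
        k = len(gene_set & in_universe)
        p = _hypergeom_upper_tail(k, M, len(in_universe), N)
        results.append(
            EnrichmentResult(
                term_id=term,
                namespace=annotation.term_namespace.get(term, "BP"),
                set_count=k,
                set_size=N,
                universe_count=len(in_universe),
                universe_size=M,
                p_value=p,
                significant=p < alpha,
            )
        )
    if adjust and results:
        rejected, adjusted, *_ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        results = [
            EnrichmentResult(
                r.term_id, r.namespace, r.set_count, r.set_size,
                r.universe_count, r.universe_size, float(q), bool(rej),
            )
            for r, q, rej in zip(results, adjusted, rejected)
        ]
    return sorted(results, key=lambda r: (r.p_value, r.term_id))


def custom_list_enrichment(
    module_genes: set[str],
    cw_list: set[str],
    universe: set[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """One-sided Fisher exact test of cell-wall-list over-representation.

    The 2x2 table crosses module membership with custom-list membership over
    the universe; the alternative is enrichment (odds ratio > 1).
    """
    if not universe:
        raise ValueError("empty universe")
    module_genes = module_genes & universe
    cw_in_universe = cw_list & universe
    a = len(module_genes & cw_in_universe)
    b = len(module_genes) - a
    c = len(cw_in_universe) - a
    d = len(universe) - a - b - c
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(
        term_id="custom_cw_list",
        namespace="BP",
        set_count=a,
        set_size=len(module_genes),
        universe_count=len(cw_in_universe),
        universe_size=len(universe),
        p_value=float(p),
        significant=p < alpha,
    )


def group_terms_by_keyword(
    enrichment: list[EnrichmentResult], keyword_map: KeywordMap
) -> dict[str, list[EnrichmentResult]]:
    """Significant enriched terms grouped under each keyword.

    A term belonging to several keywords appears in every matching group.
    """
    significant = [r for r in enrichment if r.significant]
    out: dict[str, list[EnrichmentResult]] = {}
    for keyword in keyword_map.keywords:
        members = keyword_map.groups[keyword]
        out[keyword] = [r for r in significant if r.term_id in members]
    return out


def count_cw_terms(
    enrichment: list[EnrichmentResult],
    keyword_map: KeywordMap,
    cw_keywords: tuple[str, ...] = CW_KEYWORDS_DEFAULT,
) -> tuple[int, int]:
    """Distinct significant cell-wall terms, split by namespace (BP, CC).

    A term under several cell-wall keywords is counted once.
    """
    cw_terms = keyword_map.terms_under(*cw_keywords)
    seen = {r.term_id: r for r in enrichment if r.significant and r.term_id in cw_terms}
    n_bp = sum(1 for r in seen.values() if r.namespace == "BP")
    n_cc = sum(1 for r in seen.values() if r.namespace == "CC")
    return n_bp, n_cc


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term_id", "namespace", "set_count", "set_size",
            "universe_count", "universe_size", "p_value", "significant"]
    return pd.DataFrame([r.as_row() for r in results], columns=cols)
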