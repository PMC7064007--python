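"""Bait-gene neighborhood extraction and cell-wall evidence classification.

Each MYB/NAC bait transcription factor seeds a two-layer "top subnetwork":
its k most correlated genes (layer 1, default k = 15, ranked by raw signed
correlation), plus the top-k lists of every layer-1 gene (layer 2).  The
deduplicated union including the bait holds at most 1 + k + k^2 genes (241
at k = 15).  The union list is scored by the number of distinct significant
cell-wall GO terms it is enriched in and classified as none (< 3),
light (3-5), medium (6-11) or high (>= 12).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AnnotationTable, KeywordMap
from .enrichment import CW_KEYWORDS_DEFAULT, count_cw_terms, term_enrichment
from .network import ModuleSet, NetworkModel, UNASSIGNED

__all__ = [
    "Subnetwork",
    "top_neighbors",
    "two_layer_subnetwork",
    "classify_cw_enrichment",
    "screen_baits",
    "CATEGORIES",
]

CATEGORIES = ("none", "light", "medium", "high")


@dataclass
class Subnetwork:
    """A bait gene with its two-layer top-correlated neighborhood."""

    bait: str
    k: int
    layer1: list[str]
    layer2: set[str]
    union_list: set[str] = field(default_factory=set)
    cw_term_count: int = 0
    category: str = "none"

    @property
    def size(self) -> int:
        return len(self.union_list)


def top_neighbors(
    gene: str,
    correlation: np.ndarray,
    gene_ids: list[str],
    k: int = 15,
) -> list[str]:
    """The k genes most correlated with ``gene`` (self excluded).

    Ranking is by raw signed correlation descending (the signed-network
    convention), ties broken by ascending gene ID.  If fewer than k
    candidates exist, all are returned with a warning.
    """
    try:
        gi = gene_ids.index(gene)
    except ValueError:
        raise KeyError(f"gene {gene!r} absent from the network") from None
    order = sorted(
        (g for g in range(len(gene_ids)) if g != gi),
        key=lambda g: (-correlation[gi, g], gene_ids[g]),
    )
    if len(order) < k:
        warnings.warn(
            f"only {len(order)} candidate neighbors for {gene!r} (< k={k})",
            stacklevel=2,
        )
    return [gene_ids[g] for g in order[:k]]


def two_layer_subnetwork(
    bait: str,
    correlation: np.ndarray,
    gene_ids: list[str],
    k: int = 15,
) -> Subnetwork:
    """Extract the bait's two-layer top-k neighborhood.

    union = {bait} | layer1 | union of each layer-1 gene's own top-k list;
    at most 1 + k + k^2 genes.
    """
    layer1 = top_neighbors(bait, correlation, gene_ids, k)
    layer2: set[str] = set()
    for g in layer1:
        layer2.update(top_neighbors(g, correlation, gene_ids, k))
    union = {bait} | set(layer1) | layer2
    return Subnetwork(bait=bait, k=k, layer1=layer1, layer2=layer2, union_list=union)


def classify_cw_enrichment(cw_term_count: int) -> str:
    """Map a cell-wall GO term count onto the enrichment category.

    Half-open reading of the printed ranges: < 3 none, [3, 6) light,
    [6, 12) medium, >= 12 high.
    """
    if cw_term_count < 0:
        raise ValueError("cell-wall term count cannot be negative")
    if cw_term_count < 3:
        return "none"
    if cw_term_count < 6:
        return "light"
    if cw_term_count < 12:
        return "medium"
    return "high"


def screen_baits(
    bait_table: pd.DataFrame,
    model: NetworkModel,
    module_set: ModuleSet,
    annotation: AnnotationTable,
    keyword_map: KeywordMap,
    filtered_genes: set[str] | None = None,
    k: int = 15,
    alpha: float = 0.05,
    cw_keywords: tuple[str, ...] = CW_KEYWORDS_DEFAULT,
) -> pd.DataFrame:
    """Screen every bait transcription factor for cell-wall evidence.

    ``bait_table`` is indexed by gene ID with columns ``tf_family`` and
    ``clade``.  Baits absent from ``filtered_genes`` (the genes surviving the
    read filter; defaults to the network's gene universe) are reported as
    ``excluded_low_expression``; baits present but not retained by the
    strong-correlation filter as ``excluded_weak_correlation``.  For
    everything else the two-layer subnetwork is extracted, its union list is
    tested for GO enrichment against the network universe, and the count of
    significant cell-wall terms is classified.

    The output is one row per bait, invariant to bait-table row order.
    """
    universe = set(model.gene_ids)
    if filtered_genes is None:
        filtered_genes = universe
    retained_all = {g for genes in module_set.retained.values() for g in genes}
    missing = set(bait_table.index) - set(annotation.table.index)
    if missing:
        raise KeyError(f"baits absent from the annotation: {sorted(missing)[:5]}")

    rows = []
    for bait in sorted(bait_table.index):
        family = bait_table.loc[bait, "tf_family"]
        clade = bait_table.loc[bait, "clade"] if "clade" in bait_table.columns else ""
        row = {
            "gene_id": bait,
            "tf_family": family,
            "clade": clade,
            "module": "",
            "status": "",
            "subnetwork_size": 0,
            "cw_term_count": 0,
            "category": "none",
        }
        if bait not in filtered_genes or bait not in universe:
            row["status"] = "excluded_low_expression"
        elif bait not in retained_all:
            row["status"] = "excluded_weak_correlation"
            row["module"] = module_set.labels.get(bait, UNASSIGNED)
        else:
            sub = two_layer_subnetwork(bait, model.correlation, model.gene_ids, k)
            results = term_enrichment(
                sub.union_list & universe, annotation, universe, alpha=alpha
            )
            n_bp, n_cc = count_cw_terms(results, keyword_map, cw_keywords)
            sub.cw_term_count = n_bp + n_cc
            sub.category = classify_cw_enrichment(sub.cw_term_count)
            row.update(
                module=module_set.labels.get(bait, UNASSIGNED),
                status="screened",
                subnetwork_size=sub.size,
                cw_term_count=sub.cw_term_count,
                category=sub.category,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
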