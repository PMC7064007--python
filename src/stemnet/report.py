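"""Evidence integration across pipeline stages and clade summaries."""

from __future__ import annotations

import math

import pandas as pd

from .data import AnnotationTable, ValidationError
from .network import ModuleSet, UNASSIGNED
from .subnetworks import CATEGORIES

__all__ = ["clade_composition", "build_evidence_table"]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def clade_composition(membership: pd.DataFrame, lineage_of_interest: str = "monocot"
                      ) -> pd.DataFrame:
    """Per-clade totals and nearest-integer lineage percentages.

    ``membership`` needs one row per gene with columns ``clade`` and
    ``lineage``.  Percentages use round-half-away-from-zero.
    """
    if "clade" not in membership.columns or "lineage" not in membership.columns:
        raise ValidationError("membership table needs 'clade' and 'lineage' columns")
    missing = membership.index[membership["lineage"].isna()
                               | (membership["lineage"].astype(str) == "")]
    if len(missing):
        raise ValidationError(f"genes missing a lineage label: {list(missing[:5])}")
    rows = []
    for clade, group in membership.groupby("clade", sort=True):
        n_total = len(group)
        n_lineage = int((group["lineage"] == lineage_of_interest).sum())
        rows.append(
            {
                "clade": clade,
                "n_total": n_total,
                f"n_{lineage_of_interest}": n_lineage,
                f"pct_{lineage_of_interest}": _round_half_away(
                    100.0 * n_lineage / n_total
                ),
            }
        )
    return pd.DataFrame(rows).set_index("clade")


def build_evidence_table(
    module_set: ModuleSet,
    connectivity: pd.DataFrame,
    bait_screen: pd.DataFrame,
    annotation: AnnotationTable,
    hub_lists: dict[str, dict[str, list[str]]] | None = None,
    cw_modules: set[str] | None = None,
) -> pd.DataFrame:
    """One evidence row per bait transcription factor.

    Combines module membership, hub status (only meaningful for genes in
    modules with a populated retained set), subnetwork size, cell-wall term
    count and category.  Rows are sorted by category (high -> none), then
    cell-wall term count descending, then gene ID — a total order.
    ``cw_modules`` flags modules passing the dual criterion (custom-list
    enrichment and at least one cell-wall GO term).
    """
    universe_mismatch = set(bait_screen.index) - set(annotation.table.index)
    if universe_mismatch:
        raise ValidationError(
            f"baits outside the annotation universe: {sorted(universe_mismatch)[:5]}"
        )
    cw_modules = cw_modules or set()
    hub_lists = hub_lists or {}
    rank = {cat: i for i, cat in enumerate(reversed(CATEGORIES))}
    rows = []
    for bait, info in bait_screen.iterrows():
        module = info.get("module", "") or UNASSIGNED
        hubs = hub_lists.get(module, {})
        in_retained = bait in set(
            g for genes in module_set.retained.values() for g in genes
        )
        rows.append(
            {
                "gene_id": bait,
                "tf_family": info.get("tf_family", "none"),
                "clade": info.get("clade", ""),
                "module": module,
                "module_cw_related": module in cw_modules,
                "is_hub_top10": in_retained and bait in hubs.get("top_n", []),
                "is_hub_top10pct": in_retained and bait in hubs.get("top_fraction", []),
                "subnetwork_size": int(info.get("subnetwork_size", 0)),
                "cw_term_count": int(info.get("cw_term_count", 0)),
                "category": info.get("category", "none"),
                "status": info.get("status", ""),
            }
        )
    columns = ["gene_id", "tf_family", "clade", "module", "module_cw_related",
               "is_hub_top10", "is_hub_top10pct", "subnetwork_size",
               "cw_term_count", "category", "status"]
    if not rows:
        return pd.DataFrame(columns=columns).set_index("gene_id")
    df = pd.DataFrame(rows)
    df["_cat"] = df["category"].map(rank)
    df = df.sort_values(
        ["_cat", "cw_term_count", "gene_id"], ascending=[True, False, True]
    ).drop(columns="_cat")
    return df.set_index("gene_id")
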