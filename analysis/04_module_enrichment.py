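#!/usr/bin/env python
"""Score modules for cell-wall evidence.

Per-module GO over-representation (one-sided hypergeometric, alpha 0.05),
keyword grouping of the significant terms, BP/CC cell-wall term counts, and
a one-sided Fisher exact test against the custom cell-wall gene list.
Modules enriched in both the custom list and at least one cell-wall GO term
are the "CW-related" set carried forward.
"""

from pathlib import Path

import pandas as pd

from stemnet import io
from stemnet.enrichment import (
    count_cw_terms,
    custom_list_enrichment,
    enrichment_to_frame,
    term_enrichment,
)

DATA = Path("results/data")
NET = Path("results/network")
OUT = Path("results/enrichment")
ALPHA = 0.05


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ann = io.read_annotations(DATA / "annotations.go.tsv",
                              DATA / "annotations.cw.txt",
                              DATA / "annotations.baits.tsv")
    keywords = io.read_keywords(DATA / "keywords.tsv")
    labels = io.read_module_assignment(NET / "modules.tsv")
    universe = set(labels.index)
    cw_list = ann.cw_genes()

    rows, frames = [], []
    for module in sorted(set(labels) - {"unassigned"}):
        genes = set(labels.index[labels == module])
        results = term_enrichment(genes, ann, universe, alpha=ALPHA)
        frame = enrichment_to_frame([r for r in results if r.significant])
        frame.insert(0, "module", module)
        frames.append(frame)
        n_bp, n_cc = count_cw_terms(results, keywords)
        fisher = custom_list_enrichment(genes, cw_list, universe, alpha=ALPHA)
        rows.append(
            {"module": module, "n_genes": len(genes),
             "cw_list_p": fisher.p_value,
             "cw_list_significant": fisher.significant,
             "cw_go_bp": n_bp, "cw_go_cc": n_cc,
             "cw_related": fisher.significant and (n_bp + n_cc) >= 1}
        )
    table = pd.DataFrame(rows).set_index("module")
    table.to_csv(OUT / "module_summary.tsv", sep="\t")
    pd.concat(frames).to_csv(OUT / "significant_terms.tsv", sep="\t", index=False)

    print(table.to_string(float_format=lambda v: f"{v:.3g}"))
    cw_modules = list(table.index[table["cw_related"]])
    print(f"\nCW-related modules (custom list AND >=1 CW GO term): {cw_modules}")


if __name__ == "__main__":
    main()
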