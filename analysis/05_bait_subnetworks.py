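#!/usr/bin/env python
"""Screen every MYB/NAC bait transcription factor.

For each bait surviving the expression filter and the strong-correlation
retention, extracts the two-layer top-15 correlated-gene subnetwork (at
most 1 + 15 + 15^2 = 241 genes), tests its union list for GO enrichment and
classifies the count of significant cell-wall terms: high (>= 12),
medium (6-11), light (3-5), none (< 3).
"""

from pathlib import Path

from stemnet import io
from stemnet.data import ExpressionMatrix
from stemnet.network import (
    NetworkModel,
    apply_strong_correlation_filter,
    detect_modules,
    pearson_correlation,
    topological_overlap,
)
from stemnet.preprocess import filter_low_expression
from stemnet.subnetworks import screen_baits

DATA = Path("results/data")
PRE = Path("results/preprocess")
OUT = Path("results/subnetworks")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = io.read_counts(DATA / "counts.tsv")
    filtered = filter_low_expression(counts, 3, 20)
    expr = io.read_expression(PRE / "expression.tsv")
    ann = io.read_annotations(DATA / "annotations.go.tsv",
                              DATA / "annotations.cw.txt",
                              DATA / "annotations.baits.tsv")
    keywords = io.read_keywords(DATA / "keywords.tsv")

    corr, used = pearson_correlation(expr)
    expr = ExpressionMatrix(expr.values.loc[used])
    model = NetworkModel(used, corr)
    module_set = detect_modules(topological_overlap(model.adjacency()),
                                expr, used)
    module_set = apply_strong_correlation_filter(model, module_set)

    screen = screen_baits(
        ann.bait_genes(), model, module_set, ann, keywords,
        filtered_genes=set(filtered.gene_ids), k=15,
    )
    io.save_artifact(screen, OUT / "bait_screen.tsv", "table")

    n_total = len(screen)
    n_excluded = int((screen["status"] != "screened").sum())
    print(f"{n_total} baits screened; {n_excluded} excluded "
          "(low expression or weak correlation)")
    screened = screen[screen["status"] == "screened"]
    print("subnetwork sizes: "
          f"min {screened['subnetwork_size'].min()}, "
          f"mean {screened['subnetwork_size'].mean():.1f}, "
          f"max {screened['subnetwork_size'].max()} (bound 241)")
    print("categories:", screened["category"].value_counts().to_dict())


if __name__ == "__main__":
    main()
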