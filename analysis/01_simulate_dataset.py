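#!/usr/bin/env python
"""Generate the synthetic internode expression study.

Emulates the field design the analysis assumes: 191 internode samples over
three years, two water regimes and five ordered developmental stages, with
2,000 genes of which five planted modules (500 genes) follow stage-specific
expression profiles.  Cell-wall GO annotation and the custom cell-wall gene
list concentrate in the two modules peaking at mid/late development, and
bait MYB/NAC transcription factors are planted inside and outside modules.

Writes counts, sample table, annotations, keyword map, biochemistry and the
ground-truth module labels under results/data/.
"""

from pathlib import Path

from stemnet import io
from stemnet.simulate import default_config, generate_dataset

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(default_config(seed=SEED))
    io.write_counts(data["counts"], OUT / "counts.tsv")
    io.write_samples(data["design"], OUT / "samples.tsv")
    io.write_annotations(data["annotations"], OUT / "annotations")
    io.write_keywords(data["keywords"], OUT / "keywords.tsv")
    io.write_biochem(data["biochem"], OUT / "biochem.tsv")
    data["planted"].to_csv(OUT / "planted_modules.tsv", sep="\t")

    n_baits = int(data["annotations"].table["is_bait"].sum())
    print(f"samples: {len(data['design'].sample_ids)}")
    print(f"genes: {data['counts'].shape[0]} "
          f"({(data['planted'] != 'background').sum()} in planted modules)")
    print(f"bait TFs: {n_baits}; custom CW list: {len(data['annotations'].cw_genes())} genes")
    print(f"artifacts in {OUT}/")


if __name__ == "__main__":
    main()
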