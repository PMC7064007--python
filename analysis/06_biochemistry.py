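#!/usr/bin/env python
"""Cell-wall component accumulation along internode development.

Derives hemicellulose (NDF - ADF), cellulose (ADF - ADL) and lignin (ADL)
per sample, then compares stage means per trait with pairwise Welch t-tests
under Holm correction and a compact letter display (stages sharing a letter
do not differ at alpha 0.05).
"""

from pathlib import Path

import pandas as pd

from stemnet import io
from stemnet.biochem import TRAITS, compare_stages, derive_wall_fractions

DATA = Path("results/data")
OUT = Path("results/biochem")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bio = io.read_biochem(DATA / "biochem.tsv")
    samples = io.read_samples(DATA / "samples.tsv",
                              stage_order=("D1", "D2", "D3", "D4", "D5"))
    derived = derive_wall_fractions(bio)
    io.save_artifact(derived, OUT / "wall_fractions.tsv", "table")

    summaries = pd.concat([compare_stages(derived, samples, t) for t in TRAITS])
    summaries.to_csv(OUT / "stage_comparison.tsv", sep="\t")
    for trait in TRAITS:
        sub = summaries[summaries["trait"] == trait]
        line = ", ".join(
            f"{s}: {r['mean']:.1f}±{r['standard_error']:.2f} {r['letter_group']}"
            for s, r in sub.iterrows()
        )
        print(f"{trait:14s} {line}")


if __name__ == "__main__":
    main()
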