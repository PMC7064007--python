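"""Derived cell-wall fractions and stage-wise accumulation comparisons.

From the Van Soest fiber fractions (percent of dry matter):
hemicellulose = NDF - ADF, cellulose = ADF - ADL, lignin = ADL; the three
derived components therefore sum exactly to NDF.  Stage means are compared
with pairwise Welch t-tests under Holm correction and summarized with a
compact letter display (stages sharing a letter do not differ significantly).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .data import BiochemTable, SampleTable, ValidationError

__all__ = ["derive_wall_fractions", "compare_stages", "compact_letter_display"]

TRAITS = ("hemicellulose", "cellulose", "lignin")


def derive_wall_fractions(biochem: BiochemTable) -> pd.DataFrame:
    """Per-sample hemicellulose, cellulose and lignin contents (%DM)."""
    t = biochem.table
    bad = t.index[(t["NDF"] < t["ADF"]) | (t["ADF"] < t["ADL"])]
    if len(bad):
        raise ValidationError(f"fiber ordering violated for samples: {list(bad[:5])}")
    out = pd.DataFrame(
        {
            "hemicellulose": t["NDF"] - t["ADF"],
            "cellulose": t["ADF"] - t["ADL"],
            "lignin": t["ADL"],
        },
        index=t.index,
    )
    return out


def compact_letter_display(
    ordered_groups: list[str], differs: set[tuple[str, str]]
) -> dict[str, str]:
    """Greedy insert-and-absorb letter assignment.

    ``ordered_groups`` are sorted by mean; ``differs`` holds unordered pairs
    that are significantly different.  Groups sharing any letter are not
    significantly different.
    """
    from itertools import combinations

    def different(a: str, b: str) -> bool:
        return (a, b) in differs or (b, a) in differs

    # letters correspond to maximal groups with no internal significant
    # difference (maximal cliques of the "not different" graph; group counts
    # are small, so exhaustive enumeration is fine)
    n = len(ordered_groups)
    candidates: list[set[str]] = []
    for size in range(n, 0, -1):
        for combo in combinations(ordered_groups, size):
            if any(different(a, b) for a, b in combinations(combo, 2)):
                continue
            s = set(combo)
            if not any(s < t for t in candidates):
                candidates.append(s)
    rank = {g: i for i, g in enumerate(ordered_groups)}
    letter_sets = sorted(candidates, key=lambda s: min(rank[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in ordered_groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            out[g] += letter
    return out


def compare_stages(
    derived: pd.DataFrame,
    samples: SampleTable,
    trait: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stage means, standard errors and compact letter groups for one trait.

    All pairwise Welch t-tests between stages, Holm-corrected; stages with a
    single replicate have an undefined standard error and are flagged.
    """
    if trait not in derived.columns:
        raise KeyError(f"unknown trait {trait!r}; available: {list(derived.columns)}")
    stage = samples.table.loc[derived.index, "stage"].astype(str)
    groups = {s: derived.loc[stage == s, trait].to_numpy() for s in stage.unique()}
    present = [s for s in samples.stage_order if s in groups]
    if len(present) < 2:
        raise ValueError("stage comparison requires at least 2 stages")

    rows = []
    for s in present:
        x = groups[s]
        n = len(x)
        se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {"stage": s, "mean": float(x.mean()), "standard_error": se,
             "n": n, "flagged_single_replicate": n < 2}
        )
    summary = pd.DataFrame(rows).set_index("stage")

    pairs = [
        (a, b) for i, a in enumerate(present) for b in present[i + 1:]
        if len(groups[a]) > 1 and len(groups[b]) > 1
    ]
    differs: set[tuple[str, str]] = set()
    if pairs:
        pvals = [
            ttest_ind(groups[a], groups[b], equal_var=False).pvalue
            for a, b in pairs
        ]
        rejected, *_ = multipletests(pvals, alpha=alpha, method="holm")
        differs = {pair for pair, rej in zip(pairs, rejected) if rej}

    ordered = list(summary.sort_values("mean", ascending=False).index)
    letters = compact_letter_display(ordered, differs)
    summary["letter_group"] = [letters[s] for s in summary.index]
    summary.insert(0, "trait", trait)
    return summary
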