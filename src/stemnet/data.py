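"""Shared in-memory containers for the internode co-expression pipeline.

Every container wraps a :class:`pandas.DataFrame` (or plain dicts for the
annotation maps) and validates its invariants at construction time, so that
downstream stages can assume well-formed inputs.  Gene and sample order is
never semantic: containers keep the order they were built with, but every
deterministic output sorts by identifier first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CountMatrix",
    "ExpressionMatrix",
    "SampleTable",
    "AnnotationTable",
    "KeywordMap",
    "BiochemTable",
    "REGIME_LEVELS",
    "TF_FAMILIES",
]

REGIME_LEVELS = ("WW", "WD")
TF_FAMILIES = ("MYB", "NAC", "none")


class ValidationError(ValueError):
    """An on-disk artifact or in-memory container violates its invariants."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class CountMatrix:
    """Non-negative integer read counts, genes in rows, samples in columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene IDs")
        _check_unique(self.counts.columns, "sample IDs")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("counts contain missing values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        if not np.allclose(values, np.round(values.astype(float))):
            raise ValidationError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression, genes in rows, samples in columns."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "sample IDs")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        self.values = self.values.astype(float)
        self.values.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and np.allclose(
            self.values.to_numpy(), other.values.to_numpy()
        ) and list(self.values.index) == list(other.values.index) \
            and list(self.values.columns) == list(other.values.columns)


@dataclass
class SampleTable:
    """Per-sample design factors of the field experiment.

    ``stage`` carries a total ordering (developmental stages D1 < D2 < ...);
    the order is taken from ``stage_order`` if given, else from first
    appearance in the table.
    """

    table: pd.DataFrame
    stage_order: tuple[str, ...] | None = None

    REQUIRED = ("year", "block", "regime", "internode_rank", "stage", "replicate")

    def __post_init__(self) -> None:
        if self.table.index.name != "sample_id":
            if "sample_id" in self.table.columns:
                self.table = self.table.set_index("sample_id")
            else:
                self.table = self.table.rename_axis("sample_id")
        _check_unique(self.table.index, "sample IDs")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        bad = set(self.table["regime"].astype(str)) - set(REGIME_LEVELS)
        if bad:
            raise ValidationError(f"unknown water regimes: {sorted(bad)}")
        if self.stage_order is None:
            seen = list(dict.fromkeys(self.table["stage"].astype(str)))
            self.stage_order = tuple(sorted(seen))
        if len(set(self.stage_order)) != len(self.stage_order):
            raise ValidationError("stage ordering contains duplicates")
        extra = set(self.table["stage"].astype(str)) - set(self.stage_order)
        if extra:
            raise ValidationError(f"stages outside declared ordering: {sorted(extra)}")
        self.table = self.table.copy()
        self.table["stage"] = pd.Categorical(
            self.table["stage"].astype(str), categories=self.stage_order, ordered=True
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def stage_index(self) -> pd.Series:
        """Integer position of each sample's stage along the stage ordering."""
        return self.table["stage"].cat.codes.rename("stage_index")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SampleTable)
            and self.stage_order == other.stage_order
            and self.table.astype(str).equals(other.table.astype(str))
        )


@dataclass
class AnnotationTable:
    """Per-gene functional annotation: GO term sets, custom cell-wall flag,
    transcription-factor family/clade and bait status.

    GO terms are kept flat (no ontology-graph ancestor propagation); each term
    carries a namespace tag, BP (biological process) or CC (cellular
    component), because enrichment counts are reported separately for the two.
    """

    table: pd.DataFrame  # index gene_id; cw_custom, tf_family, clade, is_bait
    go_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    term_namespace: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.name != "gene_id":
            if "gene_id" in self.table.columns:
                self.table = self.table.set_index("gene_id")
            else:
                self.table = self.table.rename_axis("gene_id")
        _check_unique(self.table.index, "gene IDs")
        self.table = self.table.copy()
        for col, default in (
            ("cw_custom", False),
            ("tf_family", "none"),
            ("clade", ""),
            ("is_bait", False),
        ):
            if col not in self.table.columns:
                self.table[col] = default
        self.table["cw_custom"] = self.table["cw_custom"].astype(bool)
        self.table["is_bait"] = self.table["is_bait"].astype(bool)
        self.table["tf_family"] = self.table["tf_family"].astype(str)
        self.table["clade"] = self.table["clade"].fillna("").astype(str)
        bad_family = set(self.table["tf_family"]) - set(TF_FAMILIES)
        if bad_family:
            raise ValidationError(f"unknown TF families: {sorted(bad_family)}")
        bad_bait = self.table.index[
            self.table["is_bait"] & (self.table["tf_family"] == "none")
        ]
        if len(bad_bait):
            raise ValidationError(
                f"bait genes without a TF family: {list(bad_bait[:5])}"
            )
        self.go_terms = {g: frozenset(t) for g, t in self.go_terms.items()}
        bad_ns = {ns for ns in self.term_namespace.values() if ns not in ("BP", "CC")}
        if bad_ns:
            raise ValidationError(f"unknown GO namespaces: {sorted(bad_ns)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def terms_for(self, gene_id: str) -> frozenset[str]:
        return self.go_terms.get(gene_id, frozenset())

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, terms in self.go_terms.items() if term in terms}

    def cw_genes(self) -> set[str]:
        return set(self.table.index[self.table["cw_custom"]])

    def bait_genes(self) -> pd.DataFrame:
        return self.table[self.table["is_bait"]][["tf_family", "clade"]]


@dataclass
class KeywordMap:
    """Grouping of GO terms under human-readable keywords (e.g. "SCW")."""

    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.groups = {str(k): frozenset(map(str, v)) for k, v in self.groups.items()}
        for kw, terms in self.groups.items():
            for t in terms:
                if not t or any(c.isspace() for c in t):
                    raise ValidationError(f"malformed term {t!r} under keyword {kw!r}")

    @property
    def keywords(self) -> list[str]:
        return sorted(self.groups)

    def terms_under(self, *keywords: str) -> frozenset[str]:
        out: set[str] = set()
        for kw in keywords:
            out |= self.groups.get(kw, frozenset())
        return frozenset(out)


@dataclass
class BiochemTable:
    """Van Soest fiber fractions per sample, in percent of dry matter:
    NDF (total fiber) >= ADF (lignocellulose) >= ADL (lignin)."""

    table: pd.DataFrame  # index sample_id; NDF, ADF, ADL

    def __post_init__(self) -> None:
        if self.table.index.name != "sample_id":
            if "sample_id" in self.table.columns:
                self.table = self.table.set_index("sample_id")
            else:
                self.table = self.table.rename_axis("sample_id")
        _check_unique(self.table.index, "sample IDs")
        missing = [c for c in ("NDF", "ADF", "ADL") if c not in self.table.columns]
        if missing:
            raise ValidationError(f"biochemistry table missing columns: {missing}")
        t = self.table.astype(float)
        for lo, hi in (("ADL", "ADF"), ("ADF", "NDF")):
            bad = t.index[t[lo] > t[hi] + 1e-9]
            if len(bad):
                raise ValidationError(
                    f"{lo} exceeds {hi} for samples: {list(bad[:5])}"
                )
        if (t["ADL"] < 0).any() or (t["NDF"] > 100).any():
            raise ValidationError("fiber fractions must lie in [0, 100] %DM")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)
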