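"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular artifacts are plain TSV (UTF-8, '.' decimal, header row).  Counts
may alternatively be MatrixMarket (``.mtx``) with two sidecar files
``<stem>.genes.txt`` and ``<stem>.samples.txt`` holding row and column IDs,
one per line.  Deterministic outputs are sorted by identifier; edge lists are
written as ``gene_a  gene_b  correlation  adjacency`` with ``gene_a <
gene_b`` lexicographically and no self-pairs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import (
    AnnotationTable,
    BiochemTable,
    CountMatrix,
    ExpressionMatrix,
    KeywordMap,
    SampleTable,
    ValidationError,
)

ARTIFACT_KINDS = ("table", "edge_list", "module_assignment", "report")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending cell."""


# ---------------------------------------------------------------- counts ----

def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count matrix from TSV or MatrixMarket."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        genes = _read_gene_list(path.parent / (path.stem + ".genes.txt"))
        samples = _read_gene_list(path.parent / (path.stem + ".samples.txt"))
        df = pd.DataFrame(
            np.asarray(scipy.sparse.coo_matrix(mat).todense()),
            index=genes,
            columns=samples,
        )
        return CountMatrix(df)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        if len(bad):
            raise ParseError(
                f"non-numeric count at gene {bad[0]!r}, sample {col!r} "
                f"in {path.name}: {df.loc[bad[0], col]!r}"
            )
        numeric[col] = converted
    return CountMatrix(numeric)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        order = np.argsort(cm.counts.index)
        sorted_df = cm.counts.iloc[order]
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(sorted_df.to_numpy()))
        _write_lines(path.parent / (path.stem + ".genes.txt"), sorted_df.index)
        _write_lines(path.parent / (path.stem + ".samples.txt"), sorted_df.columns)
        return
    cm.counts.sort_index().to_csv(path, sep="\t")


def _read_gene_list(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar ID file: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def _write_lines(path: Path, items) -> None:
    path.write_text("\n".join(map(str, items)) + "\n")


# ---------------------------------------------------------------- tables ----

def read_samples(path: str | Path, stage_order: tuple[str, ...] | None = None
                 ) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{Path(path).name}: missing 'sample_id' column")
    for col in ("internode_rank", "replicate"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    return SampleTable(df, stage_order=stage_order)


def write_samples(st: SampleTable, path: str | Path) -> None:
    out = st.table.copy()
    out["stage"] = out["stage"].astype(str)
    out.sort_index().to_csv(path, sep="\t")


def read_annotations(
    go_path: str | Path,
    cw_list_path: str | Path | None = None,
    bait_path: str | Path | None = None,
) -> AnnotationTable:
    """Assemble an annotation table from a gene<->GO pair file, an optional
    custom cell-wall gene list (one ID per line) and an optional bait TF
    table (columns gene_id, tf_family, clade)."""
    pairs = pd.read_csv(
        go_path, sep="\t", dtype=str,
        names=["gene_id", "term", "namespace"], header=None, comment="#",
    )
    if pairs.iloc[0, 0] == "gene_id":  # tolerate a header row
        pairs = pairs.iloc[1:]
    pairs["namespace"] = pairs["namespace"].fillna("BP")
    go_terms: dict[str, set[str]] = {}
    term_ns: dict[str, str] = {}
    for gene, term, ns in pairs.itertuples(index=False):
        go_terms.setdefault(gene, set()).add(term)
        term_ns[term] = ns
    genes = sorted(go_terms)
    table = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    cw: set[str] = set()
    if cw_list_path is not None:
        cw = set(_read_gene_list(Path(cw_list_path)))
    baits = None
    if bait_path is not None:
        baits = pd.read_csv(bait_path, sep="\t", dtype=str)
    all_genes = set(genes) | cw | (set(baits["gene_id"]) if baits is not None else set())
    table = table.reindex(sorted(all_genes))
    table.index.name = "gene_id"
    table["cw_custom"] = [g in cw for g in table.index]
    table["tf_family"] = "none"
    table["clade"] = ""
    table["is_bait"] = False
    if baits is not None:
        for row in baits.itertuples(index=False):
            table.loc[row.gene_id, "tf_family"] = row.tf_family
            table.loc[row.gene_id, "clade"] = getattr(row, "clade", "") or ""
            table.loc[row.gene_id, "is_bait"] = True
    return AnnotationTable(table, go_terms={g: frozenset(t) for g, t in go_terms.items()},
                           term_namespace=term_ns)


def write_annotations(ann: AnnotationTable, prefix: str | Path) -> None:
    prefix = Path(prefix)
    rows = [
        (g, t, ann.term_namespace.get(t, "BP"))
        for g in sorted(ann.go_terms)
        for t in sorted(ann.go_terms[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term", "namespace"]).to_csv(
        prefix.parent / (prefix.name + ".go.tsv"), sep="\t", index=False, header=False
    )
    _write_lines(prefix.parent / (prefix.name + ".cw.txt"), sorted(ann.cw_genes()))
    baits = ann.bait_genes().sort_index().reset_index()
    baits.to_csv(prefix.parent / (prefix.name + ".baits.tsv"), sep="\t", index=False)


def read_keywords(path: str | Path) -> KeywordMap:
    """Keyword map TSV: two columns, keyword and GO term (one pair per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str, names=["keyword", "term"],
                     header=None, comment="#")
    if len(df) and df.iloc[0, 0] == "keyword":
        df = df.iloc[1:]
    groups: dict[str, set[str]] = {}
    for kw, term in df.itertuples(index=False):
        groups.setdefault(kw, set()).add(term)
    return KeywordMap({k: frozenset(v) for k, v in groups.items()})


def write_keywords(km: KeywordMap, path: str | Path) -> None:
    rows = [(kw, t) for kw in km.keywords for t in sorted(km.groups[kw])]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_biochem(path: str | Path) -> BiochemTable:
    return BiochemTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_biochem(bt: BiochemTable, path: str | Path) -> None:
    bt.table.sort_index().to_csv(path, sep="\t")


def read_expression(path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0))


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.sort_index().to_csv(path, sep="\t")


# --------------------------------------------------------------- dataset ----

def load_dataset(
    counts_path: str | Path,
    samples_path: str | Path,
    annotations_path: str | Path,
    cw_list_path: str | Path | None = None,
    keyword_path: str | Path | None = None,
    bait_path: str | Path | None = None,
    stage_order: tuple[str, ...] | None = None,
):
    """Load and cross-reference the full input set.

    Samples present in the count matrix but absent from the sample table are
    an error; genes on the custom cell-wall list that are absent from the
    count matrix are retained with a warning.
    """
    counts = read_counts(counts_path)
    samples = read_samples(samples_path, stage_order=stage_order)
    missing = set(counts.sample_ids) - set(samples.sample_ids)
    if missing:
        raise ValidationError(
            f"samples in counts but not in sample table: {sorted(missing)[:5]}"
        )
    ann = read_annotations(annotations_path, cw_list_path, bait_path)
    orphan_cw = ann.cw_genes() - set(counts.gene_ids)
    if orphan_cw:
        warnings.warn(
            f"{len(orphan_cw)} cell-wall list genes absent from the count matrix",
            stacklevel=2,
        )
    keywords = read_keywords(keyword_path) if keyword_path else KeywordMap({})
    return counts, samples, ann, keywords


# -------------------------------------------------------------- artifacts ---

def write_edge_list(
    gene_ids, correlation: np.ndarray, adjacency: np.ndarray,
    path: str | Path, min_adjacency: float = 0.0,
) -> int:
    """Write the upper triangle of a symmetric network as a 4-column TSV.

    Returns the number of edge rows written.  Pairs with adjacency strictly
    below ``min_adjacency`` are omitted.
    """
    gene_ids = list(gene_ids)
    order = np.argsort(gene_ids)
    rows = []
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            i, j = order[ai], order[bi]
            if adjacency[i, j] >= min_adjacency:
                rows.append(
                    (gene_ids[i], gene_ids[j],
                     f"{correlation[i, j]:.6g}", f"{adjacency[i, j]:.6g}")
                )
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "correlation", "adjacency"])
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def write_module_assignment(labels: pd.Series, path: str | Path) -> None:
    out = labels.rename("module").rename_axis("gene_id").astype(str)
    out.sort_index().to_csv(path, sep="\t")


def read_module_assignment(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df["module"]


def save_artifact(obj, path: str | Path, kind: str) -> None:
    """Dispatching writer for the generic artifact kinds."""
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; expected {ARTIFACT_KINDS}")
    if kind == "module_assignment":
        write_module_assignment(obj, path)
    elif kind == "edge_list":
        write_edge_list(*obj, path=path)
    elif isinstance(obj, CountMatrix):
        write_counts(obj, path)
    elif isinstance(obj, ExpressionMatrix):
        write_expression(obj, path)
    elif isinstance(obj, SampleTable):
        write_samples(obj, path)
    elif isinstance(obj, BiochemTable):
        write_biochem(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.sort_index().to_csv(path, sep="\t")
    else:
        raise TypeError(f"cannot save object of type {type(obj).__name__}")
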