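"""Signed weighted co-expression network construction and module analysis.

The workflow mirrors the standard weighted-correlation approach: Pearson
correlation of log-expression, soft-threshold adjacency (default variant
``signed_hybrid``: r^beta for positive r, zero otherwise — with beta = 12 an
adjacency cutoff of 0.1 corresponds to a correlation of about 0.82),
topological overlap, average-linkage hierarchical clustering with a static
tree cut, eigengene-based module merging, a strong-correlation retention
filter, and intramodular-connectivity hub ranking.

Module labels are color names drawn deterministically from a fixed palette
ordered by descending module size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .data import ExpressionMatrix

__all__ = [
    "NetworkModel",
    "ModuleSet",
    "pearson_correlation",
    "adjacency",
    "soft_threshold_scan",
    "topological_overlap",
    "module_eigengenes",
    "detect_modules",
    "apply_strong_correlation_filter",
    "cluster_module_profiles",
    "intramodular_connectivity",
    "rank_hub_genes",
    "hub_variant_overlap",
    "UNASSIGNED",
    "MODULE_PALETTE",
]

UNASSIGNED = "unassigned"
ADJACENCY_VARIANTS = ("unsigned", "signed", "signed_hybrid")

# fixed ordered palette; assigned by descending module size
MODULE_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
    "yellowgreen", "lightsteelblue", "orangered", "plum", "ivory",
)


@dataclass
class NetworkModel:
    """Correlation matrix plus the soft-thresholding configuration."""

    gene_ids: list[str]
    correlation: np.ndarray
    beta: int = 12
    variant: str = "signed_hybrid"
    adjacency_threshold: float = 0.1
    correlation_threshold: float = 0.82

    def __post_init__(self) -> None:
        c = np.asarray(self.correlation, dtype=float)
        if c.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("correlation shape inconsistent with gene IDs")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if self.beta < 1:
            raise ValueError("soft-threshold power beta must be >= 1")
        if not (0 < self.adjacency_threshold < 1):
            raise ValueError("adjacency_threshold must lie in (0, 1)")
        if self.variant not in ADJACENCY_VARIANTS:
            raise ValueError(f"unknown adjacency variant {self.variant!r}")
        self.correlation = c

    def adjacency(self, zero_diagonal: bool = True) -> np.ndarray:
        return adjacency(
            self.correlation, beta=self.beta, variant=self.variant,
            zero_diagonal=zero_diagonal,
        )


@dataclass
class ModuleSet:
    """Gene-to-module color assignment plus derived per-module artifacts."""

    labels: pd.Series  # gene_id -> color label or UNASSIGNED
    eigengenes: pd.DataFrame | None = None  # samples x modules, unit norm
    retained: dict[str, list[str]] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.labels) - {UNASSIGNED})

    def members(self, module: str) -> list[str]:
        return sorted(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        return counts.sort_values(ascending=False)


# ------------------------------------------------------------ correlation ---

def pearson_correlation(expr: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Gene-gene Pearson correlation of log-expression.

    Zero-variance genes cannot be correlated and are dropped with a warning;
    returns the matrix together with the list of genes actually used.
    """
    if expr.shape[1] < 3:
        raise ValueError("correlation requires at least 3 samples")
    values = expr.values.to_numpy()
    variances = values.var(axis=1)
    keep = variances > 0
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} zero-variance genes before correlation",
            stacklevel=2,
        )
    used = [g for g, k in zip(expr.gene_ids, keep) if k]
    corr = np.atleast_2d(np.corrcoef(values[keep]))
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr, used


def adjacency(
    correlation: np.ndarray,
    beta: int = 12,
    variant: str = "signed_hybrid",
    zero_diagonal: bool = True,
) -> np.ndarray:
    """Soft-threshold adjacency.

    unsigned: |r|^beta; signed: ((1+r)/2)^beta; signed_hybrid: r^beta for
    r > 0, else 0.  The diagonal is zeroed for connectivity computations.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = np.asarray(correlation, dtype=float)
    if variant == "unsigned":
        a = np.abs(r) ** beta
    elif variant == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    elif variant == "signed_hybrid":
        a = np.where(r > 0, r, 0.0) ** beta
    else:
        raise ValueError(f"unknown adjacency variant {variant!r}")
    if zero_diagonal and a.ndim == 2:
        a = a.copy()
        np.fill_diagonal(a, 0.0)
    return a


def soft_threshold_scan(
    correlation: np.ndarray,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    variant: str = "signed_hybrid",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free topology fit index and mean connectivity per candidate power.

    The fit index is the signed R^2 of log10(frequency) on log10(mean
    connectivity) over equal-width connectivity bins; the sign is
    -sign(slope), so a decaying degree distribution scores positively.
    Powers whose connectivities are all equal report a missing fit.
    """
    if correlation.shape[0] < 50:
        warnings.warn("scale-free fit is unreliable below ~50 genes", stacklevel=2)
    rows = []
    for beta in powers:
        a = adjacency(correlation, beta=beta, variant=variant)
        k = a.sum(axis=1)
        rows.append(
            {"power": beta, "fit_r2": _scale_free_fit(k, n_bins),
             "mean_connectivity": float(k.mean())}
        )
    return pd.DataFrame(rows).set_index("power")


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    if np.allclose(k, k[0]):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    centers, freqs = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            centers.append(k[mask].mean())
            freqs.append(mask.mean())
    centers, freqs = np.asarray(centers), np.asarray(freqs)
    ok = centers > 0
    if ok.sum() < 3:
        return float("nan")
    fit = linregress(np.log10(centers[ok]), np.log10(freqs[ok]))
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j,
    TOM_ii = 1.  Requires a symmetric adjacency with zero diagonal and
    entries in [0, 1].
    """
    a = np.asarray(adj, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (min_k + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------- modules ---

def module_eigengenes(expr: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Columns are unit-norm per-sample profiles, sign-oriented to correlate
    positively with the module's mean expression profile.
    """
    modules = sorted(set(labels) - {UNASSIGNED})
    out = {}
    for module in modules:
        members = labels.index[labels == module]
        sub = expr.values.loc[members].to_numpy()
        sd = sub.std(axis=1)
        usable = sd > 0
        if not usable.any():
            raise ValueError(f"module {module!r} has constant expression")
        z = (sub[usable] - sub[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.corrcoef(eig, mean_profile)[0, 1] < 0:
            eig = -eig
        out[module] = eig / np.linalg.norm(eig)
    return pd.DataFrame(out, index=expr.sample_ids)


def detect_modules(
    tom: np.ndarray,
    expr: ExpressionMatrix,
    gene_ids: list[str] | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    merge_correlation: float = 0.75,
) -> ModuleSet:
    """Average-linkage clustering on 1 - TOM with a static tree cut.

    Clusters smaller than ``min_module_size`` become unassigned; modules whose
    eigengenes correlate above ``merge_correlation`` are merged iteratively
    (closest pair first).  Surviving modules are named from the fixed color
    palette in order of descending size (ties by smallest member gene ID).
    """
    gene_ids = list(gene_ids if gene_ids is not None else expr.gene_ids)
    n = tom.shape[0]
    if n < 2:
        raise ValueError("module detection requires at least 2 genes")
    if n != len(gene_ids):
        raise ValueError("TOM size inconsistent with gene IDs")
    diss = 1.0 - np.asarray(tom, dtype=float)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    link = sch.linkage(squareform(diss, checks=False), method="average")
    raw = sch.fcluster(link, t=cut_height, criterion="distance")

    labels = pd.Series(
        [f"M{c}" for c in raw], index=pd.Index(gene_ids, name="gene_id")
    )
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = UNASSIGNED

    labels = _merge_by_eigengene(expr, labels, merge_correlation)

    # deterministic color naming: descending size, ties by smallest member ID
    keys = sorted(
        set(labels) - {UNASSIGNED},
        key=lambda m: (-int((labels == m).sum()), min(labels.index[labels == m])),
    )
    if len(keys) > len(MODULE_PALETTE):
        palette = list(MODULE_PALETTE) + [
            f"module{i}" for i in range(len(keys) - len(MODULE_PALETTE))
        ]
    else:
        palette = list(MODULE_PALETTE)
    rename = {old: palette[i] for i, old in enumerate(keys)}
    labels = labels.map(lambda m: rename.get(m, UNASSIGNED))

    eigengenes = (
        module_eigengenes(expr.__class__(expr.values.loc[gene_ids]), labels)
        if set(labels) - {UNASSIGNED}
        else None
    )
    return ModuleSet(labels=labels, eigengenes=eigengenes)


def _merge_by_eigengene(
    expr: ExpressionMatrix, labels: pd.Series, merge_correlation: float
) -> pd.Series:
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {UNASSIGNED})
        if len(modules) < 2:
            return labels
        eig = module_eigengenes(
            expr.__class__(expr.values.loc[labels.index]), labels
        )
        corr = eig.corr().to_numpy()
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= merge_correlation:
            return labels
        keep, absorb = sorted((modules[i], modules[j]))
        labels[labels == absorb] = keep


def apply_strong_correlation_filter(
    model: NetworkModel,
    module_set: ModuleSet,
    min_retained: int = 3,
) -> ModuleSet:
    """Populate the retained ("strong correlation") gene sets.

    A gene is retained in its module iff its maximal within-module adjacency
    to another member reaches the model's adjacency threshold (0.1 at
    beta = 12 corresponds to a correlation of about 0.82).  Modules with
    fewer than ``min_retained`` retained genes are dropped from the retained
    map entirely.
    """
    adj = model.adjacency()
    index = {g: i for i, g in enumerate(model.gene_ids)}
    retained: dict[str, list[str]] = {}
    for module in module_set.modules:
        members = [g for g in module_set.members(module) if g in index]
        idx = np.array([index[g] for g in members])
        if len(idx) < 2:
            continue
        sub = adj[np.ix_(idx, idx)]
        strongest = sub.max(axis=1)
        kept = [g for g, s in zip(members, strongest)
                if s >= model.adjacency_threshold]
        if len(kept) >= min_retained:
            retained[module] = kept
    module_set.retained = retained
    return module_set


def cluster_module_profiles(
    profiles: pd.DataFrame, n_clusters: int = 7
) -> tuple[pd.Series, pd.DataFrame]:
    """Meta-cluster module expression profiles.

    ``profiles`` has one column per module (per-sample mean normalized
    expression or eigengene).  Modules are grouped by average-linkage
    clustering on 1 - Pearson correlation, cut into ``n_clusters`` groups.
    Returns the module -> cluster assignment and the module x module
    correlation matrix (the heatmap input).
    """
    n_modules = profiles.shape[1]
    if n_clusters > n_modules:
        raise ValueError(
            f"cannot cut {n_modules} modules into {n_clusters} clusters"
        )
    corr = profiles.corr()
    diss = 1.0 - corr.to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = sch.linkage(squareform(diss, checks=False), method="average")
    groups = sch.fcluster(link, t=n_clusters, criterion="maxclust")
    assignment = pd.Series(
        [f"C{g}" for g in groups], index=profiles.columns, name="profile_cluster"
    )
    return assignment, corr


# ------------------------------------------------------------ connectivity --

def intramodular_connectivity(
    adj: np.ndarray, module_set: ModuleSet, gene_ids: list[str]
) -> pd.DataFrame:
    """Whole-network and within-module connectivity per gene.

    kTotal = sum of adjacencies; kWithin = sum over same-module genes;
    kOut = kTotal - kWithin; kDiff = kWithin - kOut.  Unassigned genes have
    kWithin = 0 by convention.
    """
    labels = module_set.labels.reindex(gene_ids).fillna(UNASSIGNED).to_numpy()
    a = np.asarray(adj, dtype=float)
    k_total = a.sum(axis=1)
    k_within = np.zeros_like(k_total)
    for module in set(labels) - {UNASSIGNED}:
        mask = labels == module
        idx = np.flatnonzero(mask)
        k_within[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    out = pd.DataFrame(
        {
            "module": labels,
            "kTotal": k_total,
            "kWithin": k_within,
            "kOut": k_total - k_within,
            "kDiff": 2 * k_within - k_total,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return out


def rank_hub_genes(
    connectivity: pd.DataFrame,
    module_set: ModuleSet,
    top_n: int = 10,
    top_fraction: float = 0.10,
    use_retained: bool = False,
) -> dict[str, dict[str, list[str]]]:
    """Per-module hub lists by descending kWithin (ties by gene ID).

    Returns, per module, the ``top_n`` list and the top
    ``ceil(top_fraction * module size)`` list, computed on all members or on
    the strong-correlation retained subset.
    """
    out: dict[str, dict[str, list[str]]] = {}
    for module in module_set.modules:
        if use_retained:
            members = module_set.retained.get(module, [])
        else:
            members = module_set.members(module)
        if not members:
            out[module] = {"top_n": [], "top_fraction": []}
            continue
        sub = connectivity.loc[members, "kWithin"]
        ranked = sorted(members, key=lambda g: (-sub[g], g))
        n_frac = math.ceil(top_fraction * len(members))
        out[module] = {
            "top_n": ranked[:top_n],
            "top_fraction": ranked[:n_frac],
        }
    return out


def hub_variant_overlap(
    connectivity: pd.DataFrame,
    module_set: ModuleSet,
    top_n: int = 10,
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """Compare hub lists computed on all members vs the retained subset."""
    full = rank_hub_genes(connectivity, module_set, top_n, top_fraction, False)
    filt = rank_hub_genes(connectivity, module_set, top_n, top_fraction, True)
    rows = []
    for module in module_set.modules:
        a, b = set(full[module]["top_n"]), set(filt[module]["top_n"])
        rows.append(
            {
                "module": module,
                "top_n_overlap": len(a & b),
                "top_n_identical": a == b and len(a) > 0,
                "n_members": len(module_set.members(module)),
                "n_retained": len(module_set.retained.get(module, [])),
            }
        )
    return pd.DataFrame(rows).set_index("module")
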