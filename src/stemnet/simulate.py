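"""Synthetic internode-transcriptome generator with planted structure.

The generator emulates the statistical shape of a multi-year field sampling
of developing internodes: an unbalanced 3-year design of 191 internode
samples (two water regimes, several internode ranks, ordered developmental
stages D1..D5, replicated blocks), negative-binomial read counts whose
planted co-expression modules follow unimodal stage profiles, GO and
custom cell-wall annotations concentrated in specific modules, bait MYB/NAC
transcription factors, and Van Soest fiber fractions (NDF >= ADF >= ADL)
accumulating along development.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import AnnotationTable, BiochemTable, CountMatrix, KeywordMap, SampleTable

__all__ = [
    "ConfigError",
    "ModuleSpec",
    "FactorialDesign",
    "BiochemParams",
    "SimConfig",
    "default_config",
    "generate_design",
    "generate_annotations",
    "generate_counts",
    "generate_biochem",
    "generate_dataset",
    "planted_labels",
    "planted_hubs",
]

STAGES = ("D1", "D2", "D3", "D4", "D5")


class ConfigError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``within_correlation`` is the target pairwise Pearson correlation of the
    module genes' log-expression; count noise erodes it slightly, so the
    realized log-CPM correlation approximates the target to about +-0.1 at
    the default sample size.
    """

    module_id: str
    n_genes: int
    peak_stage: str
    amplitude: float = 2.5
    within_correlation: float = 0.90
    cw_annotation_rate: float = 0.0
    n_bait_tfs: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError(f"module {self.module_id}: n_genes must be >= 1")
        if not (0 <= self.within_correlation < 1):
            raise ConfigError(
                f"module {self.module_id}: within_correlation must lie in [0, 1)"
            )
        if not (0 <= self.cw_annotation_rate <= 1):
            raise ConfigError(
                f"module {self.module_id}: cw_annotation_rate must lie in [0, 1]"
            )
        if self.amplitude < 0:
            raise ConfigError(f"module {self.module_id}: amplitude must be >= 0")
        if self.n_bait_tfs > self.n_genes:
            raise ConfigError(f"module {self.module_id}: more baits than genes")


@dataclass(frozen=True)
class FactorialDesign:
    """Full-factorial alternative to the default unbalanced field layout."""

    years: tuple[str, ...] = ("2013",)
    regimes: tuple[str, ...] = ("WW", "WD")
    internode_ranks: tuple[int, ...] = (12,)
    stages: tuple[str, ...] = STAGES
    replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("years", "regimes", "internode_ranks", "stages"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise ConfigError(f"empty factor level list: {name}")
            if len(set(levels)) != len(levels):
                raise ConfigError(f"duplicated levels in factor {name}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


@dataclass(frozen=True)
class BiochemParams:
    """Logistic accumulation parameters per wall component, in %DM.

    Each component follows ``base + span / (1 + exp(-(t - inflection)/scale))``
    over the stage index t; the fractions are composed additively
    (ADL = lignin, ADF = lignin + cellulose, NDF = ADF + hemicellulose) so the
    Van Soest ordering holds by construction.  Lignin deposition lags the
    polysaccharides, so its inflection must not precede theirs.
    """

    hemicellulose: tuple[float, float, float, float] = (10.0, 15.0, 1.0, 0.5)
    cellulose: tuple[float, float, float, float] = (8.0, 22.0, 1.2, 0.5)
    lignin: tuple[float, float, float, float] = (2.0, 6.0, 2.2, 0.5)
    noise_sd: float = 0.8

    def __post_init__(self) -> None:
        poly_inflection = max(self.hemicellulose[2], self.cellulose[2])
        if self.lignin[2] < poly_inflection:
            raise ConfigError(
                "lignin inflection must not precede the polysaccharide inflections"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name in ("hemicellulose", "cellulose", "lignin"):
            base, span, _, scale = getattr(self, name)
            if base < 0 or span < 0 or scale <= 0:
                raise ConfigError(f"invalid logistic parameters for {name}")


@dataclass(frozen=True)
class SimConfig:
    """Complete recipe for one synthetic dataset."""

    n_genes_total: int = 2000
    module_specs: tuple[ModuleSpec, ...] = ()
    design: FactorialDesign | str = "field_191"
    library_size_range: tuple[float, float] = (0.5e6, 2.0e6)
    dispersion: float = 0.05
    baseline_log2cpm_mean: float = 4.0
    baseline_log2cpm_sd: float = 1.5
    bump_width: float = 0.6
    background_noise_sd: float = 0.7
    hub_noise_factor: float = 0.4
    n_background_baits: int = 2
    n_lowexpr_baits: int = 1
    go_vocab_size: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ConfigError("negative-binomial dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must satisfy 0 < lo <= hi")
        if self.n_module_genes > self.n_genes_total:
            raise ConfigError("planted module genes exceed n_genes_total")
        ids = [m.module_id for m in self.module_specs]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate module IDs")
        if self.n_lowexpr_baits > self.n_background_baits:
            raise ConfigError("n_lowexpr_baits exceeds n_background_baits")
        if self.n_background_baits > self.n_background_genes:
            raise ConfigError("more background baits than background genes")

    @property
    def n_module_genes(self) -> int:
        return sum(m.n_genes for m in self.module_specs)

    @property
    def n_background_genes(self) -> int:
        return self.n_genes_total - self.n_module_genes

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def default_config(seed: int = 0) -> SimConfig:
    """The default study conditions: 2,000 genes, 191 samples, five planted
    modules peaking at distinct stages, cell-wall annotation concentrated in
    the two late modules (the secondary-wall analogues)."""
    modules = (
        ModuleSpec("elong_early", 150, "D1", cw_annotation_rate=0.05, n_bait_tfs=2),
        ModuleSpec("elong_late", 100, "D2", cw_annotation_rate=0.05, n_bait_tfs=2),
        ModuleSpec("scw_main", 120, "D3", cw_annotation_rate=0.80, n_bait_tfs=4),
        ModuleSpec("lignin", 60, "D4", cw_annotation_rate=0.60, n_bait_tfs=3),
        ModuleSpec("maturation", 70, "D5", cw_annotation_rate=0.0, n_bait_tfs=1),
    )
    return SimConfig(module_specs=modules, seed=seed)


# ---------------------------------------------------------------- design ----

def _field_design_191() -> pd.DataFrame:
    """The unbalanced 3-year internode sampling layout (191 samples)."""
    rows: list[tuple[str, int, str, str, int]] = []
    # year 2013: internodes 12 and 16, five stages, four blocks; the top
    # internode (16) was not yet available at D1; one sample is missing.
    for rank in (12, 16):
        for stage in STAGES:
            if rank == 16 and stage == "D1":
                continue
            for regime in ("WW", "WD"):
                for block in range(1, 5):
                    rows.append(("2013", rank, stage, regime, block))
    rows.remove(("2013", 16, "D5", "WD", 4))  # the one missing field sample
    # year 2014: six internode levels over three stages, three blocks.
    combos_2014 = (
        [(13, s) for s in ("D1", "D3", "D5")]
        + [(15, s) for s in ("D1", "D3", "D5")]
        + [(14, "D1"), (16, "D1")]
        + [(17, "D3"), (17, "D5"), (19, "D3"), (19, "D5")]
    )
    for rank, stage in combos_2014:
        for regime in ("WW", "WD"):
            for block in range(1, 4):
                rows.append(("2014", rank, stage, regime, block))
    # year 2015: four apical internodes at an intermediate stage, four
    # flag-leaf-relative internodes at the final stage, three blocks.
    combos_2015 = [(r, "D2") for r in (11, 12, 13, 14)] + [
        (r, "D5") for r in (17, 19, 21, 23)
    ]
    for rank, stage in combos_2015:
        for regime in ("WW", "WD"):
            for block in range(1, 4):
                rows.append(("2015", rank, stage, regime, block))
    df = pd.DataFrame(rows, columns=["year", "internode_rank", "stage", "regime", "block"])
    df["replicate"] = df["block"]
    df["block"] = "B" + df["block"].astype(str)
    df["sample_id"] = (
        "Y" + df["year"] + "_I" + df["internode_rank"].astype(str).str.zfill(2)
        + "_" + df["stage"] + "_" + df["regime"] + "_" + df["block"]
    )
    return df


def generate_design(config: SimConfig) -> SampleTable:
    """Build the sample table.  The default configuration yields the 191-row
    unbalanced field layout; a :class:`FactorialDesign` yields the full cross."""
    if isinstance(config.design, str):
        if config.design != "field_191":
            raise ConfigError(f"unknown named design {config.design!r}")
        df = _field_design_191()
        return SampleTable(df, stage_order=STAGES)
    d = config.design
    rows = []
    for year in d.years:
        for regime in d.regimes:
            for rank in d.internode_ranks:
                for stage in d.stages:
                    for rep in range(1, d.replicates + 1):
                        rows.append(
                            {
                                "sample_id": f"Y{year}_I{rank:02d}_{stage}_{regime}_B{rep}",
                                "year": year,
                                "block": f"B{rep}",
                                "regime": regime,
                                "internode_rank": rank,
                                "stage": stage,
                                "replicate": rep,
                            }
                        )
    return SampleTable(pd.DataFrame(rows), stage_order=tuple(d.stages))


# ----------------------------------------------------------------- genes ----

def _gene_ids(config: SimConfig) -> list[str]:
    width = max(4, len(str(config.n_genes_total - 1)))
    return [f"G{i:0{width}d}" for i in range(config.n_genes_total)]


def planted_labels(config: SimConfig) -> pd.Series:
    """Ground-truth module label per gene ('background' for unplanted genes)."""
    ids = _gene_ids(config)
    labels = []
    for spec in config.module_specs:
        labels.extend([spec.module_id] * spec.n_genes)
    labels.extend(["background"] * config.n_background_genes)
    return pd.Series(labels, index=pd.Index(ids, name="gene_id"), name="planted")


def planted_hubs(config: SimConfig) -> dict[str, str]:
    """The designed hub gene (tightest latent coupling) of each planted module."""
    labels = planted_labels(config)
    return {
        spec.module_id: labels.index[labels == spec.module_id][0]
        for spec in config.module_specs
    }


# CW vocabulary: keyword -> (namespace, term count).  The "SCW" keyword has
# four member ontologies, mirroring the keyword grouping used downstream.
_CW_KEYWORDS = {
    "SCW": ("BP", 4),
    "cellulose": ("BP", 3),
    "xylan": ("BP", 3),
    "lignin": ("BP", 3),
    "pectin": ("BP", 2),
    "cell_wall_CC": ("CC", 2),
}


def _cw_vocabulary() -> tuple[KeywordMap, dict[str, str]]:
    groups: dict[str, frozenset[str]] = {}
    namespaces: dict[str, str] = {}
    counter = 1
    for kw, (ns, n) in _CW_KEYWORDS.items():
        terms = []
        for _ in range(n):
            term = f"GO:CW{counter:04d}"
            terms.append(term)
            namespaces[term] = ns
            counter += 1
        groups[kw] = frozenset(terms)
    return KeywordMap(groups), namespaces


def generate_annotations(
    config: SimConfig, seed: int | None = None
) -> tuple[AnnotationTable, KeywordMap]:
    """Plant GO / cell-wall annotations and bait transcription factors.

    Genes of modules with a high ``cw_annotation_rate`` are preferentially
    tagged with cell-wall GO terms and flagged on the custom list; bait genes
    are tagged MYB or NAC with a clade label.  Background GO terms are spread
    uniformly so enrichment tests have a non-degenerate universe.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    keyword_map, term_ns = _cw_vocabulary()
    cw_terms = sorted(term_ns)
    n_bg_terms = config.go_vocab_size - len(cw_terms)
    if n_bg_terms < 1:
        raise ConfigError(
            f"go_vocab_size must exceed the {len(cw_terms)} cell-wall terms"
        )
    bg_terms = [f"GO:BG{i:04d}" for i in range(1, n_bg_terms + 1)]
    for t in bg_terms:
        term_ns[t] = "BP"

    labels = planted_labels(config)
    ids = list(labels.index)
    go_terms: dict[str, set[str]] = {g: set() for g in ids}
    cw_custom = pd.Series(False, index=labels.index)

    # background annotation: ~2 random terms per gene
    for g in ids:
        k = rng.poisson(2.0)
        if k:
            go_terms[g].update(rng.choice(bg_terms, size=min(k, len(bg_terms)),
                                          replace=False))
    # planted cell-wall annotation
    for spec in config.module_specs:
        members = labels.index[labels == spec.module_id]
        for g in members:
            if rng.random() < spec.cw_annotation_rate:
                cw_custom[g] = True
                k = int(rng.integers(1, 4))
                go_terms[g].update(rng.choice(cw_terms, size=k, replace=False))

    table = pd.DataFrame(index=labels.index.copy())
    table["cw_custom"] = cw_custom
    table["tf_family"] = "none"
    table["clade"] = ""
    table["is_bait"] = False

    clades = ("C", "G", "K", "4", "1B", "12B", "15A")
    bait_counter = 0
    for spec in config.module_specs:
        members = list(labels.index[labels == spec.module_id])
        chosen = rng.choice(members, size=spec.n_bait_tfs, replace=False)
        for g in sorted(chosen):
            family = "NAC" if bait_counter % 2 == 0 else "MYB"
            table.loc[g, ["tf_family", "clade", "is_bait"]] = [
                family, clades[bait_counter % len(clades)], True,
            ]
            bait_counter += 1
    background = list(labels.index[labels == "background"])
    bg_baits = sorted(rng.choice(background, size=config.n_background_baits,
                                 replace=False))
    for g in bg_baits:
        family = "NAC" if bait_counter % 2 == 0 else "MYB"
        table.loc[g, ["tf_family", "clade", "is_bait"]] = [
            family, clades[bait_counter % len(clades)], True,
        ]
        bait_counter += 1

    ann = AnnotationTable(
        table,
        go_terms={g: frozenset(t) for g, t in go_terms.items() if t},
        term_namespace=term_ns,
    )
    return ann, keyword_map


# ---------------------------------------------------------------- counts ----

def _stage_profile(stage_idx: np.ndarray, peak_idx: int, width: float) -> np.ndarray:
    """Unimodal Gaussian bump over the ordered stage index, standardized."""
    bump = np.exp(-((stage_idx - peak_idx) ** 2) / (2.0 * width**2))
    sd = bump.std()
    if sd == 0:
        return np.zeros_like(bump)
    return (bump - bump.mean()) / sd


def generate_counts(
    design: SampleTable,
    annotations: AnnotationTable,
    config: SimConfig,
    seed: int | None = None,
) -> CountMatrix:
    """Sample negative-binomial counts with planted module structure.

    Per module, a latent standardized stage profile is shared by all member
    genes; each gene's log2 mean is ``baseline + amplitude * latent + noise``
    with the noise variance set so the latent share of the log-scale variance
    equals ``within_correlation``.  Counts are negative-binomial around the
    CPM-scaled mean with per-sample library sizes drawn log-uniformly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = planted_labels(config)
    genes = list(labels.index)
    samples = design.sample_ids
    n_genes, n_samples = len(genes), len(samples)
    stage_idx = design.stage_index().to_numpy().astype(float)
    stage_names = list(design.stage_order)

    log2cpm = np.empty((n_genes, n_samples))
    baselines = rng.normal(
        config.baseline_log2cpm_mean, config.baseline_log2cpm_sd, size=n_genes
    )

    # low-expression background baits: pinned to a floor so the read filter
    # removes them (exercises the bait-exclusion path downstream)
    bg_baits = sorted(
        set(annotations.table.index[annotations.table["is_bait"]])
        & set(labels.index[labels == "background"])
    )
    low_expr = set(bg_baits[: config.n_lowexpr_baits])

    row = 0
    for spec in config.module_specs:
        peak = stage_names.index(spec.peak_stage)
        latent = _stage_profile(stage_idx, peak, config.bump_width)
        rho = spec.within_correlation
        if spec.amplitude > 0 and rho > 0:
            noise_sd = spec.amplitude * math.sqrt((1 - rho) / rho)
        else:
            noise_sd = config.background_noise_sd
        for j in range(spec.n_genes):
            # the first member gene is the planted hub: tighter coupling to
            # the latent profile gives it the highest intramodular connectivity
            sd = noise_sd * (config.hub_noise_factor if j == 0 else 1.0)
            eps = rng.normal(0, sd, size=n_samples)
            log2cpm[row] = baselines[row] + spec.amplitude * latent + eps
            row += 1
    for _ in range(config.n_background_genes):
        eps = rng.normal(0, config.background_noise_sd, size=n_samples)
        log2cpm[row] = baselines[row] + eps
        row += 1

    lo, hi = config.library_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    # per-gene log2 levels act as relative abundances: renormalize per sample
    # so expected totals match the drawn library sizes (counts therefore carry
    # the compositional coupling real RNA-seq has; TMM removes it downstream)
    weight = np.power(2.0, log2cpm)
    # low-expression baits: pinned to ~0.3 expected reads per million so the
    # read filter removes them regardless of the abundance renormalization
    if low_expr:
        totals = weight.sum(axis=0)
        for g in low_expr:
            weight[genes.index(g)] = totals * 3e-7
    mu = weight / weight.sum(axis=0, keepdims=True) * lib_sizes[None, :]
    mu = np.maximum(mu, 1e-8)
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    return CountMatrix(df)


# --------------------------------------------------------------- biochem ----

def _logistic(t: np.ndarray, params: tuple[float, float, float, float]) -> np.ndarray:
    base, span, inflection, scale = params
    return base + span / (1.0 + np.exp(-(t - inflection) / scale))


def generate_biochem(
    design: SampleTable,
    params: BiochemParams | None = None,
    seed: int = 0,
) -> BiochemTable:
    """Per-sample NDF/ADF/ADL trajectories along the stage ordering.

    Components accumulate logistically with lignin lagging the
    polysaccharides; composing the fractions additively guarantees
    ADL <= ADF <= NDF on every sample, noise included.
    """
    params = params or BiochemParams()
    rng = np.random.default_rng(seed)
    t = design.stage_index().to_numpy().astype(float)
    n = len(t)
    hemi = _logistic(t, params.hemicellulose)
    cell = _logistic(t, params.cellulose)
    lig = _logistic(t, params.lignin)
    if params.noise_sd > 0:
        hemi = np.maximum(hemi + rng.normal(0, params.noise_sd, n), 0.0)
        cell = np.maximum(cell + rng.normal(0, params.noise_sd, n), 0.0)
        lig = np.maximum(lig + rng.normal(0, params.noise_sd * 0.5, n), 0.0)
    adl = lig
    adf = lig + cell
    ndf = adf + hemi
    df = pd.DataFrame(
        {"NDF": ndf, "ADF": adf, "ADL": adl},
        index=pd.Index(design.sample_ids, name="sample_id"),
    )
    return BiochemTable(df)


# ----------------------------------------------------------------- bundle ---

def generate_dataset(config: SimConfig | None = None, seed: int | None = None):
    """Generate the full artifact set for one run of the study conditions."""
    config = config or default_config()
    if seed is not None:
        config = config.with_seed(seed)
    design = generate_design(config)
    annotations, keywords = generate_annotations(config)
    counts = generate_counts(design, annotations, config)
    biochem = generate_biochem(design, seed=config.seed)
    return {
        "config": config,
        "design": design,
        "annotations": annotations,
        "keywords": keywords,
        "counts": counts,
        "biochem": biochem,
        "planted": planted_labels(config),
    }
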