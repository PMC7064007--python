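"""End-to-end orchestration: simulate -> preprocess -> network -> enrichment
-> subnetworks -> biochemistry -> evidence report.

``run_pipeline`` executes the full chain from a config mapping (or YAML
file), writes every stage's artifacts as TSV under the output directory,
and records a manifest (config snapshot, seed, per-stage row counts).
All randomness flows from the single configured seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, io
from .biochem import TRAITS, compare_stages, derive_wall_fractions
from .data import ValidationError
from .enrichment import (
    count_cw_terms,
    custom_list_enrichment,
    enrichment_to_frame,
    term_enrichment,
)
from .network import (
    NetworkModel,
    apply_strong_correlation_filter,
    cluster_module_profiles,
    detect_modules,
    hub_variant_overlap,
    intramodular_connectivity,
    pearson_correlation,
    rank_hub_genes,
    soft_threshold_scan,
    topological_overlap,
)
from .preprocess import estimate_batch_effects, filter_low_expression, normalize_counts
from .report import build_evidence_table
from .simulate import SimConfig, default_config, generate_dataset
from .subnetworks import screen_baits

log = logging.getLogger("stemnet")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {"enabled": True},
    "inputs": {},
    "preprocess": {"min_reads": 3, "min_samples": 20,
                   "batch_factors": ["year", "block"]},
    "network": {
        "power": 12,
        "variant": "signed_hybrid",
        "adjacency_threshold": 0.1,
        "correlation_threshold": 0.82,
        "min_module_size": 30,
        "cut_height": 0.99,
        "merge_correlation": 0.75,
        "min_retained": 3,
        "n_profile_clusters": 7,
        "run_power_scan": False,
    },
    "enrichment": {"alpha": 0.05},
    "subnetworks": {"k": 15},
    "biochem": {"enabled": True},
}


def _merge_config(base: dict, override: dict) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge_config(out[key], value)
        else:
            out[key] = value
    return out


def load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_config(DEFAULT_CONFIG, user)


def run_pipeline(
    config: dict | str | Path | None = None,
    outdir: str | Path = "results/run",
    seed: int | None = None,
) -> dict[str, Any]:
    """Run the full analysis; returns the in-memory artifacts.

    ``config`` may be a mapping, a YAML path, or None for the defaults.
    ``seed`` overrides the configured seed.
    """
    t0 = time.time()
    if config is None:
        config = DEFAULT_CONFIG
    elif isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = _merge_config(DEFAULT_CONFIG, config)
    if seed is not None:
        config["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_stage: dict[str, int] = {}

    # ----- inputs -------------------------------------------------------
    if config["simulate"].get("enabled", True):
        log.info("simulating dataset (seed=%s)", config["seed"])
        sim_kwargs = {
            k: v for k, v in config["simulate"].items() if k != "enabled"
        }
        sim_config = (
            SimConfig(**{**default_config().__dict__, **sim_kwargs,
                         "seed": config["seed"]})
            if sim_kwargs
            else default_config(seed=config["seed"])
        )
        data = generate_dataset(sim_config)
        counts, samples = data["counts"], data["design"]
        annotations, keywords = data["annotations"], data["keywords"]
        biochem = data["biochem"]
        io.write_counts(counts, outdir / "counts.tsv")
        io.write_samples(samples, outdir / "samples.tsv")
        io.write_annotations(annotations, outdir / "annotations")
        io.write_keywords(keywords, outdir / "keywords.tsv")
        io.write_biochem(biochem, outdir / "biochem.tsv")
        data["planted"].to_csv(outdir / "planted_modules.tsv", sep="\t")
    else:
        paths = config["inputs"]
        if "counts" not in paths:
            raise ValidationError(
                "config error: simulate disabled and no inputs.counts path"
            )
        log.info("loading dataset from %s", paths["counts"])
        counts, samples, annotations, keywords = io.load_dataset(
            paths["counts"], paths["samples"], paths["annotations"],
            paths.get("cw_list"), paths.get("keywords"), paths.get("baits"),
        )
        biochem = io.read_biochem(paths["biochem"]) if paths.get("biochem") else None

    counts_stage["samples"] = counts.shape[1]
    counts_stage["genes_raw"] = counts.shape[0]

    # ----- preprocess ---------------------------------------------------
    pp = config["preprocess"]
    log.info("filtering (> %d reads in >= %d samples) and normalizing",
             pp["min_reads"], pp["min_samples"])
    filtered = filter_low_expression(counts, pp["min_reads"], pp["min_samples"])
    counts_stage["genes_filtered"] = filtered.shape[0]
    expr = normalize_counts(filtered)
    batch_estimates, expr = estimate_batch_effects(
        expr, samples, tuple(pp["batch_factors"])
    )
    for est in batch_estimates:
        log.info("batch factor %s: global magnitude %.4f",
                 est.factor, est.global_magnitude)
    io.write_expression(expr, outdir / "expression.tsv")

    # ----- network ------------------------------------------------------
    net = config["network"]
    log.info("building signed network (power=%d, variant=%s)",
             net["power"], net["variant"])
    corr, used_genes = pearson_correlation(expr)
    expr = expr.__class__(expr.values.loc[used_genes])
    model = NetworkModel(
        gene_ids=used_genes,
        correlation=corr,
        beta=net["power"],
        variant=net["variant"],
        adjacency_threshold=net["adjacency_threshold"],
        correlation_threshold=net["correlation_threshold"],
    )
    if net.get("run_power_scan"):
        scan = soft_threshold_scan(corr, variant=net["variant"])
        scan.to_csv(outdir / "soft_threshold_scan.tsv", sep="\t")
    adj = model.adjacency()
    tom = topological_overlap(adj)
    module_set = detect_modules(
        tom, expr, used_genes,
        min_module_size=net["min_module_size"],
        cut_height=net["cut_height"],
        merge_correlation=net["merge_correlation"],
    )
    module_set = apply_strong_correlation_filter(
        model, module_set, min_retained=net["min_retained"]
    )
    counts_stage["modules_detected"] = len(module_set.modules)
    counts_stage["modules_retained"] = len(module_set.retained)
    log.info("%d modules detected, %d kept after the strong-correlation filter",
             counts_stage["modules_detected"], counts_stage["modules_retained"])
    io.write_module_assignment(module_set.labels, outdir / "modules.tsv")
    retained_rows = [
        (m, g) for m in sorted(module_set.retained) for g in module_set.retained[m]
    ]
    pd.DataFrame(retained_rows, columns=["module", "gene_id"]).to_csv(
        outdir / "retained_genes.tsv", sep="\t", index=False
    )
    if module_set.eigengenes is not None:
        module_set.eigengenes.rename_axis("sample_id").to_csv(
            outdir / "eigengenes.tsv", sep="\t"
        )
        n_clusters = min(net["n_profile_clusters"], len(module_set.modules))
        if n_clusters >= 1 and len(module_set.modules) >= n_clusters:
            clusters, profile_corr = cluster_module_profiles(
                module_set.eigengenes, n_clusters
            )
            clusters.rename_axis("module").to_csv(
                outdir / "module_profile_clusters.tsv", sep="\t"
            )
            profile_corr.rename_axis("module").to_csv(
                outdir / "module_profile_correlation.tsv", sep="\t"
            )

    connectivity = intramodular_connectivity(adj, module_set, used_genes)
    io.save_artifact(connectivity, outdir / "connectivity.tsv", "table")
    hub_lists = rank_hub_genes(connectivity, module_set)
    hub_overlap = hub_variant_overlap(connectivity, module_set)
    io.save_artifact(hub_overlap, outdir / "hub_overlap.tsv", "table")

    # ----- enrichment ---------------------------------------------------
    alpha = config["enrichment"]["alpha"]
    universe = set(used_genes)
    cw_list = annotations.cw_genes()
    module_rows = []
    cw_modules: set[str] = set()
    module_enrichments = {}
    for module in module_set.modules:
        genes = set(module_set.members(module)) & universe
        results = term_enrichment(genes, annotations, universe, alpha=alpha)
        module_enrichments[module] = results
        n_bp, n_cc = count_cw_terms(results, keywords)
        fisher = custom_list_enrichment(genes, cw_list, universe, alpha=alpha)
        if fisher.significant and (n_bp + n_cc) >= 1:
            cw_modules.add(module)
        module_rows.append(
            {
                "module": module,
                "n_genes": len(genes),
                "cw_list_p": fisher.p_value,
                "cw_list_significant": fisher.significant,
                "cw_go_bp": n_bp,
                "cw_go_cc": n_cc,
            }
        )
    module_table = pd.DataFrame(module_rows).set_index("module") if module_rows \
        else pd.DataFrame()
    io.save_artifact(module_table, outdir / "module_enrichment.tsv", "table")
    counts_stage["cw_modules"] = len(cw_modules)
    all_results = [
        r.as_row() | {"module": m}
        for m, results in module_enrichments.items()
        for r in results
        if r.significant
    ]
    pd.DataFrame(all_results).to_csv(
        outdir / "module_go_enrichment.tsv", sep="\t", index=False
    )

    # ----- bait subnetworks --------------------------------------------
    bait_table = annotations.bait_genes()
    screen = screen_baits(
        bait_table, model, module_set, annotations, keywords,
        filtered_genes=set(filtered.gene_ids),
        k=config["subnetworks"]["k"], alpha=alpha,
    )
    io.save_artifact(screen, outdir / "bait_screen.tsv", "table")
    counts_stage["baits_screened"] = int((screen["status"] == "screened").sum())
    counts_stage["baits_excluded"] = int((screen["status"] != "screened").sum())

    # ----- biochemistry -------------------------------------------------
    stage_summaries = None
    if config["biochem"].get("enabled", True) and biochem is not None:
        derived = derive_wall_fractions(biochem)
        io.save_artifact(derived, outdir / "wall_fractions.tsv", "table")
        stage_summaries = pd.concat(
            [compare_stages(derived, samples, trait) for trait in TRAITS]
        )
        stage_summaries.to_csv(outdir / "stage_comparison.tsv", sep="\t")

    # ----- evidence report ---------------------------------------------
    evidence = build_evidence_table(
        module_set, connectivity, screen, annotations,
        hub_lists=hub_lists, cw_modules=cw_modules,
    )
    io.save_artifact(evidence, outdir / "evidence.tsv", "table")

    manifest = {
        "package_version": __version__,
        "seed": config["seed"],
        "config": config,
        "stage_counts": counts_stage,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    log.info("pipeline finished in %.1f s", manifest["elapsed_seconds"])

    return {
        "config": config,
        "counts": counts,
        "filtered": filtered,
        "samples": samples,
        "annotations": annotations,
        "keywords": keywords,
        "expression": expr,
        "model": model,
        "tom": tom,
        "module_set": module_set,
        "connectivity": connectivity,
        "hub_lists": hub_lists,
        "hub_overlap": hub_overlap,
        "module_enrichment": module_table,
        "cw_modules": cw_modules,
        "bait_screen": screen,
        "biochem": biochem,
        "stage_summaries": stage_summaries,
        "evidence": evidence,
        "batch_estimates": batch_estimates,
        "manifest": manifest,
    }
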