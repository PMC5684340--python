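"""End-to-end orchestration of the analysis on a simulated experiment.

``run_all`` chains the stages — candidate calling, regulatory filtering,
differential enrichment, per-condition SE calling, differential SEs,
expression integration and the lncRNA overlap test — and writes plain-text
TSV/BED outputs plus a provenance manifest. Outputs are deterministic given
the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .enhancers import (
    call_candidate_enhancers,
    differential_enhancer_table,
    filter_regulatory,
)
from .expression import (
    assign_enhancers_to_genes,
    call_de_genes,
    contribution_summary,
    map_nearest_genes_rose,
    normalize_expression,
)
from .intervals import IntervalSet, write_bed
from .lncrna import run_overlap_test
from .simulate import SimulatedExperiment, SimulationConfig, simulate_experiment
from .superenhancers import (
    call_super_enhancers,
    differential_super_enhancers,
    se_summary_stats,
)

__all__ = ["run_all", "build_simulation_config"]


def build_simulation_config(cfg: PipelineConfig) -> SimulationConfig:
    sim_kwargs = dict(cfg.simulation)
    genome = sim_kwargs.pop("genome", None)
    if isinstance(genome, dict):
        from .intervals import GenomeLayout

        sim_kwargs["genome"] = GenomeLayout(genome)
    sim_kwargs.setdefault("seed", cfg.seed)
    return SimulationConfig(**sim_kwargs)


def _manifest(outdir: Path, cfg: PipelineConfig, outputs: list[str]) -> None:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "tool": "enhancerkit",
        "version": __version__,
        "python": sys.version.split()[0],
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "config": json.loads(payload),
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_all(
    cfg: PipelineConfig,
    outdir,
    experiment: SimulatedExperiment | None = None,
) -> dict:
    """Run every stage on a (simulated) experiment; returns key results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if experiment is None:
        experiment = simulate_experiment(build_simulation_config(cfg))
    exp = experiment
    outputs: list[str] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")
        outputs.append(name)

    # enhancer calling ------------------------------------------------
    ac_peaks = exp.peak_sets("H3K27ac")
    me1_peaks = exp.peak_sets("H3K4me1")
    k4me3 = exp.peak_sets("H3K4me3")
    k4me3_set = k4me3[0] if k4me3 else IntervalSet()
    candidates, support = call_candidate_enhancers(
        ac_peaks, me1_peaks, cfg.min_support)
    catalog = filter_regulatory(
        candidates, exp.genes, k4me3_set, cfg.promoter_flank, support)
    enh_bed = catalog.enhancers.df.copy()
    enh_bed["support"] = catalog.ac_support
    write_bed(IntervalSet(enh_bed), outdir / "enhancers.bed",
              extra_cols=["support"])
    outputs.append("enhancers.bed")

    from .intervals import genomic_distribution

    dist = genomic_distribution(catalog.enhancers, exp.genes,
                                cfg.promoter_flank)
    _write(dist.rename_axis("category").reset_index(),
           "genomic_distribution.tsv")

    # differential enrichment ----------------------------------------
    chip = exp.tracks_for("H3K27ac")
    inputs = exp.tracks_for("input")
    table = differential_enhancer_table(
        catalog, chip, inputs,
        logfc_threshold=cfg.logfc_threshold, q_threshold=cfg.q_threshold,
        background_band=cfg.background_band, de_novo_hi=cfg.de_novo_hi,
        de_novo_lo=cfg.de_novo_lo, de_novo_scale=cfg.de_novo_scale,
    )
    _write(table, "differential_enhancers.tsv")

    # super-enhancers -------------------------------------------------
    rankings = {}
    for cond, short in (("control", "ctrl"), ("treated", "trt")):
        rankings[cond] = call_super_enhancers(
            catalog.enhancers,
            exp.tracks_for("H3K27ac", cond),
            exp.tracks_for("input", cond),
            cfg.stitch_gap,
        )
        _write(rankings[cond].table, f"se_ranking_{short}.tsv")
    diff_se = differential_super_enhancers(
        rankings["control"], rankings["treated"],
        exp.tracks_for("H3K27ac", "control"), exp.tracks_for("input", "control"),
        exp.tracks_for("H3K27ac", "treated"), exp.tracks_for("input", "treated"),
        epsilon=cfg.se_epsilon, gained_fc=cfg.se_gained_fc,
        lost_fc=cfg.se_lost_fc,
    )
    _write(diff_se, "differential_superenhancers.tsv")
    _write(se_summary_stats(diff_se), "se_summary_stats.tsv")

    # expression integration ------------------------------------------
    expr = normalize_expression(exp.expression)
    expr = call_de_genes(expr, cfg.de_min_coverage, cfg.de_min_fc)
    _write(expr, "expression.tsv")
    diff_enh = table[table["class"].isin(
        ["up", "down", "de_novo_gained", "de_novo_lost"])]
    de_genes = [g for g in exp.genes
                if g.gene_id in set(expr.loc[expr["de"], "gene_id"])]
    links = assign_enhancers_to_genes(
        diff_enh, de_genes, cfg.window_enhancer_gene)
    _write(links, "enhancer_gene_links.tsv")

    ses = diff_se[["chrom", "start", "end"]]
    te_mask = ~rankings["treated"].table["is_se"].to_numpy(dtype=bool)
    tes = rankings["treated"].table.loc[te_mask, ["chrom", "start", "end"]]
    rose_links = map_nearest_genes_rose(
        ses, tes, exp.genes, expr,
        cfg.window_nearest_gene, cfg.expression_floor,
    )
    _write(rose_links, "rose_gene_links.tsv")
    summary: dict = {}
    se_classes = pd.Series(diff_se["class"].to_numpy())
    if (rose_links["link_type"] == "nearest_50kb_SE").any():
        summary = contribution_summary(rose_links, expr, se_classes)
        _write(pd.DataFrame([{
            **{k: v for k, v in summary.items() if not isinstance(v, dict)},
            **{f"contribution_{k}": v
               for k, v in summary["class_contributions"].items()},
        }]), "contribution_summary.tsv")

    # lncRNA overlap --------------------------------------------------
    result = run_overlap_test(
        catalog.enhancers, exp.lncrnas, exp.genome,
        n_sims=cfg.n_sims, seed=cfg.seed,
    )
    _write(pd.DataFrame([{
        "k_observed": result.k_observed,
        "k_observed_lncrna_side": result.k_observed_lncrna_side,
        "n_enhancers": result.n_enhancers,
        "n_lncrnas": result.n_lncrnas,
        "n_sims": result.n_sims,
        "null_mean": result.null_mean,
        "null_sd": result.null_sd,
        "p_empirical": result.p_empirical,
    }]), "lncrna_overlap.tsv")

    _manifest(outdir, cfg, outputs)
    return {
        "catalog": catalog,
        "differential": table,
        "rankings": rankings,
        "diff_se": diff_se,
        "expression": expr,
        "links": links,
        "rose_links": rose_links,
        "contribution": summary,
        "overlap": result,
    }
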