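"""End-to-end pipeline orchestration with a single YAML config and root seed.

Stages run in dependency order: simulate -> qc -> scan -> causal -> de ->
prioritize.  Every stage reads/writes the TSV dialects of
:mod:`ailqtl.core_io` under one output directory and appends its record
counts to a manifest, so a run is reproducible from the config alone and the
filter cascade (markers in -> informative -> scanned; genes in ->
polymorphic -> scored) is auditable.  All randomness flows from the single
root seed; stage seeds are spawned deterministically from it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, causal_modeling, expression_de, phenotype_qc, prioritization, qtl_scan
from . import core_io, synthetic_data

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "scan", "causal", "de", "prioritize")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 1
    stages: tuple[str, ...] = STAGES
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        outdir = Path(raw.pop("outdir", "ailqtl_out"))
        seed = int(raw.pop("seed", 1))
        stages = tuple(raw.pop("stages", list(STAGES)))
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        return cls(outdir=outdir, seed=seed, stages=stages, options=raw)

    def stage_seed(self, stage: str) -> int:
        # deterministic, independent per stage, bounded below 2**31
        return int(
            np.random.SeedSequence([self.seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31)
        )


def _preflight(config: RunConfig) -> None:
    opts = config.options
    if "simulate" not in config.stages:
        needed = []
        if {"qc", "scan", "causal"} & set(config.stages):
            needed += ["genotypes", "phenotypes"]
        if "de" in config.stages:
            needed += ["expression_values", "expression_samples"]
        for key in needed:
            path = opts.get(key)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"stage inputs missing: config key {key!r}")
    if "prioritize" in config.stages and "simulate" not in config.stages:
        for key in ("genes", "variants"):
            path = opts.get(key)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"prioritization input missing: config key {key!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    _preflight(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    opts = config.options
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "counts": {},
        "thresholds": {},
    }

    sim = opts.get("simulate", {})
    scan_opts = opts.get("scan", {})
    scan_config = qtl_scan.ScanConfig(
        simplem_window=int(scan_opts.get("simplem_window", 820)),
        simplem_c=float(scan_opts.get("simplem_c", 0.995)),
        alpha_significant=float(scan_opts.get("alpha_significant", 0.05)),
        alpha_highly_significant=float(scan_opts.get("alpha_highly_significant", 0.01)),
        lod_drop=float(scan_opts.get("lod_drop", 1.5)),
        max_missing_fraction=float(scan_opts.get("max_missing_fraction", 0.1)),
    )

    genotypes = phenos = expr = genes = variants = None
    truth: dict[str, Any] = {}

    if "simulate" in config.stages:
        genotypes, phenos, expr, genes, variants, truth = _stage_simulate(config, sim, out)
        manifest["counts"]["individuals"] = len(genotypes.individuals)
        manifest["counts"]["markers_in"] = genotypes.n_markers
    else:
        if {"qc", "scan", "causal", "prioritize"} & set(config.stages):
            genotypes = core_io.read_genotypes(opts["genotypes"])
            phenos = core_io.read_phenotypes(opts["phenotypes"])
        if "de" in config.stages:
            expr = core_io.read_expression(opts["expression_values"], opts["expression_samples"])
        if "prioritize" in config.stages:
            genes = core_io.read_gene_models(opts["genes"])
            variants = core_io.read_variant_annotations(opts["variants"])

    if "qc" in config.stages:
        phenos, removed = phenotype_qc.remove_outliers(phenos)
        report = phenotype_qc.correlation_matrix(phenos)
        core_io.write_phenotypes(phenos, out / "phenotypes_clean.tsv")
        removed.to_csv(out / "outliers_removed.tsv", sep="\t", index=False)
        report.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["counts"]["outlier_values_removed"] = len(removed)

    intervals: list[qtl_scan.QtlInterval] = []
    if "scan" in config.stages:
        informative, filter_log = qtl_scan.informative_markers(
            genotypes, scan_config.max_missing_fraction
        )
        manifest["counts"]["markers_informative"] = informative.n_markers
        trait_list = scan_opts.get("traits") or core_io.trait_columns(phenos)
        n_select = int(scan_opts.get("n_select", 0)) or len(informative.individuals)
        selection_traits = scan_opts.get("selection_traits") or trait_list[:1]
        selected_ids = synthetic_data.select_tails(
            phenos, selection_traits, min(n_select, len(phenos))
        )
        selected_ids = [i for i in selected_ids if i in informative.individuals]
        g_selected = informative.subset_individuals(selected_ids)
        meff = qtl_scan.simple_m(g_selected, scan_config.simplem_window, scan_config.simplem_c)
        manifest["thresholds"]["meff"] = meff
        manifest["thresholds"]["lod_significant"] = qtl_scan.bonferroni_lod_threshold(
            scan_config.alpha_significant, max(meff, 1)
        )
        manifest["thresholds"]["lod_highly_significant"] = qtl_scan.bonferroni_lod_threshold(
            scan_config.alpha_highly_significant, max(meff, 1)
        )
        n_scanned = 0
        for trait in trait_list:
            cands = scan_opts.get("covariate_candidates", [])
            covs, _ = (
                qtl_scan.screen_covariates(phenos, trait, cands, scan_config.covariate_alpha)
                if cands
                else ([], {})
            )
            curve = qtl_scan.scan(g_selected, phenos, trait, covs, scan_config)
            n_scanned = max(n_scanned, int(curve["lod"].notna().sum()))
            curve.to_csv(out / f"lod_{trait}.tsv", sep="\t", index=False, float_format="%.6g")
            intervals.extend(
                qtl_scan.two_stage_scan(
                    g_selected, informative, phenos, trait, covs, scan_config
                )
            )
        manifest["counts"]["markers_scanned"] = n_scanned
        qtl_scan.intervals_to_frame(intervals).to_csv(
            out / "qtl.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest["counts"]["qtl"] = len(intervals)

    if "causal" in config.stages and intervals:
        verdicts = []
        by_chrom: dict[str, list[qtl_scan.QtlInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            for i in range(len(ivs)):
                for j in range(i + 1, len(ivs)):
                    a, b = ivs[i], ivs[j]
                    if a.start <= b.stop and b.start <= a.stop and a.trait != b.trait:
                        top = a if a.lod >= b.lod else b
                        verdicts.append(
                            causal_modeling.fit_causal_models(
                                genotypes.codes(top.top_marker).loc[phenos.index],
                                phenos[a.trait],
                                phenos[b.trait],
                                marker=top.top_marker,
                                trait1=a.trait,
                                trait2=b.trait,
                            )
                        )
        if verdicts:
            causal_modeling.verdicts_to_frame(verdicts).to_csv(
                out / "causal.tsv", sep="\t", index=False, float_format="%.6g"
            )
        manifest["counts"]["causal_pairs"] = len(verdicts)

    de_genes: set[str] = set()
    if "de" in config.stages:
        norm = expression_de.normalize(expr)
        de = expression_de.differential_expression(norm)
        de.to_csv(out / "de.tsv", sep="\t", index=False, float_format="%.6g")
        de_genes = expression_de.de_genes_any_tissue(de)
        manifest["counts"]["de_probes"] = int(de["significant"].sum())

    if "prioritize" in config.stages:
        if not intervals:
            logger.warning("no QTL intervals; prioritization produces an empty table")
        scheme = prioritization.ScoringScheme(
            mode=opts.get("prioritize", {}).get("mode", "per_category")
        )
        kegg_genes = set(opts.get("prioritize", {}).get("kegg_genes", truth.get("kegg_genes", [])))
        cards = []
        n_candidates = 0
        for iv in intervals:
            cand = prioritization.candidate_genes(iv, genes)
            n_candidates += len(cand)
            poly = prioritization.polymorphic_filter(cand, variants)
            for _, g in poly.iterrows():
                rows = variants[variants["gene"] == g["gene"]]
                flags, counts = prioritization.flags_from_annotations(rows)
                cards.append(
                    prioritization.score_gene(
                        flags,
                        de_in_any_tissue=g["gene"] in de_genes,
                        kegg_relevant=g["gene"] in kegg_genes,
                        scheme=scheme,
                        counts=counts,
                        gene=g["gene"],
                        qtl=iv.name,
                    )
                )
        cards = prioritization.rank_candidates(cards)
        prioritization.cards_to_frame(cards).to_csv(
            out / "gene_scores.tsv", sep="\t", index=False
        )
        manifest["counts"]["genes_candidate"] = n_candidates
        manifest["counts"]["genes_scored"] = len(cards)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(config: RunConfig, sim: Mapping[str, Any], out: Path):
    """Generate genotypes, phenotypes, expression, gene models and annotations."""
    seed = config.stage_seed("simulate")
    chromosomes = [tuple(c) for c in sim.get("chromosomes", [["1", 100_000_000], ["2", 100_000_000]])]
    design = synthetic_data.evenly_spaced_design(
        n_individuals=int(sim.get("n_individuals", 397)),
        n_generations=int(sim.get("n_generations", 10)),
        chromosomes=[(str(n), int(l)) for n, l in chromosomes],
        markers_per_chromosome=int(sim.get("markers_per_chromosome", 100)),
        seed=seed,
    )
    genotypes = synthetic_data.simulate_ail_genotypes(design)

    qtl_specs = []
    for q in sim.get("qtl", []):
        marker = q.get("marker")
        if marker is None and "chrom" in q:  # nearest marker to requested position
            sub = genotypes.markers[genotypes.markers["chrom"] == str(q["chrom"])]
            k = int(np.argmin(np.abs(sub["pos"].to_numpy() - int(q["pos"]))))
            marker = sub.index[k]
        qtl_specs.append(
            synthetic_data.QtlSpec(
                marker_id=marker,
                target_trait=q["trait"],
                additive_effect=float(q.get("additive", 0.0)),
                dominance_effect=float(q.get("dominance", 0.0)),
                mediation=tuple(q["mediation"]) if q.get("mediation") else None,
                noise_sd=float(q.get("noise_sd", 1.0)),
            )
        )
    cov = sim.get("covariate")
    covariate_spec = (
        synthetic_data.CovariateSpec(
            affected_traits=tuple(cov.get("traits", [])), effect=float(cov.get("effect", 0.0))
        )
        if cov
        else None
    )
    phenos = synthetic_data.simulate_phenotypes(
        genotypes, qtl_specs, covariate_spec, seed=seed + 1
    )

    expr_opts = sim.get("expression", {})
    expr, _ = synthetic_data.simulate_expression(
        synthetic_data.ExpressionDesign(
            n_probes=int(expr_opts.get("n_probes", 500)),
            de_fraction=float(expr_opts.get("de_fraction", 0.1)),
            effect_size_log2=float(expr_opts.get("effect_size_log2", 1.0)),
            noise_sd=float(expr_opts.get("noise_sd", 0.3)),
            seed=seed + 2,
        )
    )
    genes = synthetic_data.simulate_gene_models(
        [(str(n), int(l)) for n, l in chromosomes],
        n_genes_per_chromosome=int(sim.get("genes_per_chromosome", 40)),
        seed=seed + 3,
    )
    variants = synthetic_data.simulate_variant_annotations(genes, seed=seed + 4)
    rng = np.random.default_rng(seed + 5)
    # tie probes to the simulated gene models so DE feeds prioritization
    expr.probe_genes = pd.Series(
        rng.choice(genes["gene"], size=len(expr.probe_genes), replace=True),
        index=expr.probe_genes.index,
    )
    kegg_genes = list(rng.choice(genes["gene"], size=max(1, len(genes) // 5), replace=False))

    core_io.write_genotypes(genotypes, out / "genotypes.tsv")
    core_io.write_phenotypes(phenos, out / "phenotypes.tsv")
    core_io.write_expression(expr, out / "expression.tsv", out / "expression_samples.tsv")
    core_io.write_gene_models(genes, out / "genes.tsv")
    core_io.write_variant_annotations(variants, out / "variants.tsv")
    return genotypes, phenos, expr, genes, variants, {"kegg_genes": kegg_genes}
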