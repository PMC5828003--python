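"""End-to-end pipeline: GWAS summary SNPs → germline-regulated genes →
overlap, randomization and enrichment reports.

Stage order: select → remap (optional) → LD-expand → annotate →
regulatory mapping (five sources) → per-phenotype gene-set union → locus
clustering → overlap reports (gene, locus, and pruned-SNP level with the
randomization null) → pathway enrichment.  Every stage logs its row
counts; a manifest records input hashes, thresholds, the seed and the
per-stage counts so a run is fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotation, enrichment, integration_overlap, ld_ops, regulatory_map
from .io_formats import (
    SnpAssociation,
    read_bed_intervals,
    read_gmt,
    read_haplotype_panel,
    read_snp_table,
    read_table,
    write_table,
)

logger = logging.getLogger("regshare")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the analysis constants: SNP selection at
    p < 1e-3; LD expansion at r² > 0.8 within ±1 Mb; LD pruning at
    r² = 0.5; single-tissue eQTL q <= 0.05; multi-tissue posterior > 0.8;
    1-Mb locus clustering; 10,000 randomization trials; enrichment
    significance at adjusted p <= 0.05.
    """

    # inputs
    gwas_snps: str = ""
    panel_vcf: str = ""
    gene_models: str = ""
    eqtl_single: str = ""
    eqtl_multi: str = ""
    eqtl_probe: str = ""
    enhancers_bed: str = ""
    fantom_associations: str = ""
    impet_pairs: str = ""
    tx2gene: str = ""
    pathways_gmt: str = ""
    chip_snps: str = ""
    mapping_table: str = ""  # optional identifier remap
    background_genes: str = ""  # optional enrichment universe override
    # thresholds
    p_select: float = 1e-3
    r2_expand: float = 0.8
    window_bp: int = 1_000_000
    r2_prune: float = 0.5
    prune_window_variants: int = 50
    prune_step_variants: int = 5
    q_max: float = 0.05
    posterior_min: float = 0.8
    cluster_bp: int = 1_000_000
    alpha: float = 0.05
    n_trials: int = 10_000
    seed: int = 0
    phenotypes: list[str] = field(default_factory=lambda: ["LUAD", "LUSC", "SCLC"])

    REQUIRED_PATHS = (
        "gwas_snps", "panel_vcf", "gene_models", "eqtl_single", "eqtl_multi",
        "eqtl_probe", "enhancers_bed", "fantom_associations", "impet_pairs",
        "tx2gene", "pathways_gmt", "chip_snps",
    )

    def validate(self, check_paths: bool = True) -> None:
        for name in ("p_select", "r2_expand", "r2_prune", "q_max",
                     "posterior_min", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"config: {name}={v} outside (0, 1]")
        for name in ("window_bp", "cluster_bp", "n_trials",
                     "prune_window_variants", "prune_step_variants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")
        if len(self.phenotypes) < 2:
            raise ValueError("config: need at least two phenotype labels")
        if check_paths:
            for name in self.REQUIRED_PATHS:
                p = getattr(self, name)
                if not p:
                    raise ValueError(f"config: missing required path {name!r}")
                if not Path(p).exists():
                    raise ValueError(f"config: {name} path does not exist: {p}")
            for name in ("mapping_table", "background_genes"):
                p = getattr(self, name)
                if p and not Path(p).exists():
                    raise ValueError(f"config: {name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory view of one run's outputs (files live in the run dir)."""

    config: PipelineConfig
    selected: dict[str, list[SnpAssociation]]
    location_summaries: dict[str, annotation.LocationSummary]
    expanded: dict[str, set[str]]
    gene_sets: dict[str, integration_overlap.GeneSet]
    loci: dict[str, integration_overlap.LocusClustering]
    gene_overlap: integration_overlap.OverlapReport
    locus_overlap: integration_overlap.OverlapReport
    snp_overlap: integration_overlap.OverlapReport
    pruned_sets: dict[str, set[str]]
    randomization: integration_overlap.RandomizationResult
    enrichment: dict[str, list[enrichment.EnrichmentResult]]
    manifest: dict[str, Any]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest: dict, name: str, **counts: Any) -> None:
    manifest["stages"].append({"stage": name, **counts})
    logger.info("stage %s: %s", name, counts)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute the full pipeline; write reports under *out_dir*."""
    config.validate(check_paths=True)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "thresholds": {
            k: getattr(config, k)
            for k in ("p_select", "r2_expand", "window_bp", "r2_prune",
                      "prune_window_variants", "prune_step_variants", "q_max",
                      "posterior_min", "cluster_bp", "alpha", "n_trials")
        },
        "seed": config.seed,
        "phenotypes": list(config.phenotypes),
        "inputs": {},
        "stages": [],
    }
    for name in config.REQUIRED_PATHS:
        manifest["inputs"][name] = {
            "path": str(getattr(config, name)),
            "sha256": _sha256(getattr(config, name)),
        }

    def fail(stage: str, err: Exception) -> Exception:
        return RuntimeError(f"pipeline stage {stage!r} failed: {err}")

    # --- load inputs -------------------------------------------------------
    try:
        all_snps = read_snp_table(config.gwas_snps)
        panel = read_haplotype_panel(config.panel_vcf)
        models = annotation.read_gene_models(config.gene_models)
        single_cat = regulatory_map.eqtl_records_from_table(
            read_table(config.eqtl_single, ["rsid", "gene"]))
        multi_cat = regulatory_map.eqtl_records_from_table(
            read_table(config.eqtl_multi, ["rsid", "gene"]))
        probe_cat = regulatory_map.eqtl_records_from_table(
            read_table(config.eqtl_probe, ["rsid", "gene"]))
        enhancers = read_bed_intervals(config.enhancers_bed)
        fantom_assoc = regulatory_map.enhancer_associations_from_table(
            read_table(config.fantom_associations,
                       ["enh_chrom", "enh_start", "enh_end", "target"]))
        impet_pairs = regulatory_map.enhancer_associations_from_table(
            read_table(config.impet_pairs,
                       ["enh_chrom", "enh_start", "enh_end", "target", "rpkm"]))
        tx2gene_df = read_table(config.tx2gene, ["transcript", "gene"])
        tx2gene = {str(r.transcript): str(r.gene) for r in tx2gene_df.itertuples()}
        pathways = read_gmt(config.pathways_gmt)
        chip = [
            line.strip()
            for line in Path(config.chip_snps).read_text().splitlines()
            if line.strip()
        ]
    except Exception as err:  # noqa: BLE001 - stage context wrapper
        raise fail("load_inputs", err) from err
    _stage(manifest, "load_inputs", n_gwas_rows=len(all_snps),
           n_panel_variants=panel.n_variants, n_chip_snps=len(chip))

    # --- select ------------------------------------------------------------
    selected: dict[str, list[SnpAssociation]] = {
        phen: [s for s in all_snps if s.phenotype == phen and s.pvalue < config.p_select]
        for phen in config.phenotypes
    }
    for phen, snps in selected.items():
        if not snps:
            raise fail("select", ValueError(f"no SNPs pass p < {config.p_select} "
                                            f"for phenotype {phen!r}"))
    _stage(manifest, "select",
           **{phen: len(snps) for phen, snps in selected.items()})

    # --- remap (optional) --------------------------------------------------
    if config.mapping_table:
        mapping = read_table(config.mapping_table)
        n_unmapped = {}
        for phen in config.phenotypes:
            selected[phen], unmapped = annotation.remap_identifiers(
                selected[phen], mapping)
            n_unmapped[phen] = len(unmapped)
        _stage(manifest, "remap", **n_unmapped)

    # --- annotate ----------------------------------------------------------
    flat = [s for snps in selected.values() for s in snps]
    summaries = annotation.summarize_locations(flat, models)
    write_table(
        pd.DataFrame([asdict(s) for s in summaries.values()]),
        out_dir / "location_summary.tsv",
    )
    _stage(manifest, "annotate", n_snps=len(flat))

    # --- LD expansion ------------------------------------------------------
    ld_params = ld_ops.LdParams(
        r2_expand=config.r2_expand, r2_prune=config.r2_prune,
        window_bp=config.window_bp,
        prune_window_variants=config.prune_window_variants,
        prune_step_variants=config.prune_step_variants,
    )
    expanded: dict[str, set[str]] = {}
    for phen in config.phenotypes:
        present, absent = ld_ops.partition_tags(selected[phen], panel)
        expanded[phen] = ld_ops.ld_expand(selected[phen], panel, ld_params)
        manifest["stages"].append({
            "stage": "ld_expand", "phenotype": phen,
            "n_tags": len(selected[phen]), "n_tags_in_panel": len(present),
            "n_tags_skipped": len(absent), "n_expanded": len(expanded[phen]),
        })

    # --- regulatory mapping ------------------------------------------------
    panel_pos: dict[str, tuple[str, int]] = {
        rsid: (chrom, pos0)
        for rsid, chrom, pos0 in zip(
            panel.variants["rsid"], panel.variants["chrom"], panel.variants["pos0"]
        )
    }
    gene_sets: dict[str, integration_overlap.GeneSet] = {}
    all_hits: dict[str, list[regulatory_map.RegulatoryHit]] = {}
    for phen in config.phenotypes:
        snp_ids = expanded[phen]
        hits: list[regulatory_map.RegulatoryHit] = []
        hits += regulatory_map.map_eqtls_single(snp_ids, single_cat, config.q_max)
        hits += regulatory_map.map_eqtls_multi(snp_ids, multi_cat, config.posterior_min)
        hits += regulatory_map.map_probe_eqtls(snp_ids, probe_cat)
        # positional carriers for the expanded SNPs that exist in the panel
        carriers = [
            SnpAssociation(rsid, panel_pos[rsid][0], panel_pos[rsid][1] + 1, 0.5, phen)
            for rsid in sorted(snp_ids)
            if rsid in panel_pos
        ]
        enh_hits = regulatory_map.intersect_enhancers(carriers, enhancers)
        hits += regulatory_map.enhancer_targets_fantom(enh_hits, fantom_assoc)
        hits += regulatory_map.enhancer_targets_impet(enh_hits, impet_pairs, tx2gene)
        all_hits[phen] = hits
        gene_sets[phen] = integration_overlap.union_sources(hits, phen)
        manifest["stages"].append({
            "stage": "regulatory_map", "phenotype": phen,
            "n_hits": len(hits), "n_genes": len(gene_sets[phen].genes),
        })
        rows = [
            (g, ",".join(sorted(gene_sets[phen].provenance[g])))
            for g in sorted(gene_sets[phen].genes)
        ]
        write_table(pd.DataFrame(rows, columns=["gene", "sources"]),
                    out_dir / f"genes_{phen}.tsv")

    # --- locus clustering --------------------------------------------------
    spans_by_gene = {m.gene: (m.chrom, m.span[0], m.span[1]) for m in models}
    loci: dict[str, integration_overlap.LocusClustering] = {}
    for phen in config.phenotypes:
        spans = []
        n_missing = 0
        for g in sorted(gene_sets[phen].genes):
            if g in spans_by_gene:
                chrom, s, e = spans_by_gene[g]
                spans.append((g, chrom, s, e))
            else:
                n_missing += 1
        if n_missing:
            logger.warning("cluster: %d gene(s) without a model span for %s",
                           n_missing, phen)
        loci[phen] = integration_overlap.cluster_loci(spans, config.cluster_bp)
        with open(out_dir / f"loci_{phen}.bed", "w") as fh:
            for loc in loci[phen].clusters:
                fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t"
                         f"{','.join(sorted(loc.genes))}\n")
        manifest["stages"].append({
            "stage": "cluster", "phenotype": phen, "n_loci": loci[phen].n_loci,
        })

    # --- overlap reports ---------------------------------------------------
    gene_overlap = integration_overlap.upset_counts(
        {phen: gene_sets[phen].genes for phen in config.phenotypes})
    union_genes = sorted(set().union(*(gene_sets[p].genes for p in config.phenotypes)))
    union_spans = [
        (g, *spans_by_gene[g]) for g in union_genes if g in spans_by_gene
    ]
    union_loci = integration_overlap.cluster_loci(union_spans, config.cluster_bp)
    locus_sets = {
        phen: {
            i for i, loc in enumerate(union_loci.clusters)
            if loc.genes & gene_sets[phen].genes
        }
        for phen in config.phenotypes
    }
    locus_overlap = integration_overlap.upset_counts(locus_sets)
    _stage(manifest, "overlap",
           gene_union=gene_overlap.union_size, n_union_loci=union_loci.n_loci)

    # --- pruned SNP overlap + randomization null ---------------------------
    pruned_sets: dict[str, set[str]] = {}
    for phen in config.phenotypes:
        in_panel = [s.rsid for s in selected[phen] if s.rsid in panel]
        pruned_sets[phen] = ld_ops.ld_prune(in_panel, panel, ld_params)
    snp_overlap = integration_overlap.upset_counts(pruned_sets)
    observed = len(set.intersection(*pruned_sets.values()))
    pool = ld_ops.ld_prune([r for r in chip if r in panel], panel, ld_params)
    rand = integration_overlap.randomization_test(
        [len(pruned_sets[p]) for p in config.phenotypes],
        pool,
        n_trials=config.n_trials,
        seed=config.seed,
        observed_overlap=observed,
    )
    _stage(manifest, "randomization", pool_size=len(pool),
           observed_overlap=observed, empirical_p=rand.empirical_p)

    # --- enrichment --------------------------------------------------------
    if config.background_genes:
        background = {
            line.strip()
            for line in Path(config.background_genes).read_text().splitlines()
            if line.strip()
        }
    else:
        background = set()
        background |= {r.gene for r in single_cat}
        background |= {r.gene for r in multi_cat}
        background |= {r.gene for r in regulatory_map.clean_probe_catalog(probe_cat)}
        background |= {a.target for a in fantom_assoc}
        background |= {tx2gene[p.target] for p in impet_pairs if p.target in tx2gene}
    enrich_results: dict[str, list[enrichment.EnrichmentResult]] = {}
    for phen in config.phenotypes:
        results = enrichment.enrich_pathways(
            gene_sets[phen].genes, pathways, background, config.alpha)
        enrich_results[phen] = results
        write_table(
            pd.DataFrame([
                (r.pathway_id, r.k_overlap, r.n_query, r.K_pathway,
                 r.N_background, r.p_raw, r.p_adjusted, r.significant,
                 ",".join(sorted(r.overlap_genes)))
                for r in results
            ], columns=["pathway_id", "k_overlap", "n_query", "K_pathway",
                        "N_background", "p_raw", "p_adjusted", "significant",
                        "overlap_genes"]),
            out_dir / f"enrichment_{phen}.tsv",
        )
    _stage(manifest, "enrichment", n_background=len(background),
           n_pathways=len(pathways))

    # --- reports -----------------------------------------------------------
    with open(out_dir / "overlap.json", "w") as fh:
        json.dump({
            "genes": gene_overlap.to_json_dict(),
            "loci": {
                "set_labels": locus_overlap.set_labels,
                "union_size": locus_overlap.union_size,
                "exclusive_cells": {
                    "&".join(sorted(k)): v
                    for k, v in locus_overlap.exclusive_cells.items()
                },
            },
            "pruned_snps": gene_overlap_json_cells(snp_overlap),
        }, fh, indent=2, sort_keys=True)
    with open(out_dir / "randomization.json", "w") as fh:
        json.dump({
            "n_trials": rand.n_trials,
            "observed_overlap": rand.observed_overlap,
            "overlap_distribution": {str(k): v for k, v in
                                     rand.overlap_distribution.items()},
            "empirical_p": rand.empirical_p,
            "expected_overlap": rand.expected_overlap,
            "pool_size": len(pool),
            "set_sizes": {p: len(pruned_sets[p]) for p in config.phenotypes},
        }, fh, indent=2, sort_keys=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=config,
        selected=selected,
        location_summaries=summaries,
        expanded=expanded,
        gene_sets=gene_sets,
        loci=loci,
        gene_overlap=gene_overlap,
        locus_overlap=locus_overlap,
        snp_overlap=snp_overlap,
        pruned_sets=pruned_sets,
        randomization=rand,
        enrichment=enrich_results,
        manifest=manifest,
    )


def gene_overlap_json_cells(report: integration_overlap.OverlapReport) -> dict:
    return {
        "set_labels": report.set_labels,
        "union_size": report.union_size,
        "exclusive_cells": {
            "&".join(sorted(k)): v for k, v in report.exclusive_cells.items()
        },
    }
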