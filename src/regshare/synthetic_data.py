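"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes: a block-structured phased
haplotype panel, per-phenotype GWAS summary tables with partially shared
planted signals, eQTL catalogs with q-values and posteriors, transcribed
and predicted enhancer sets with target associations, a transcript→gene
map, pathway collections with one planted enriched pathway, and a chip
background SNP list.  A :class:`PlantedTruth` record makes every stage's
expected outcome checkable.

LD blocks are built by founder-copy-with-flips: every SNP in a block is a
copy of the block's founder column with a per-haplotype flip probability
eps chosen so that the expected pairwise r² between block-mates matches
the target.  For a founder at allele frequency 1/2 the haplotype
correlation between two copies is exactly (1 - 2*eps)^2, hence
eps = (1 - r2_target^(1/4)) / 2; at other frequencies the relation is
approximate.  Across blocks, columns are independent.  All generators are
pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gene_models
from .io_formats import (
    GenomicInterval,
    HaplotypePanel,
    PathwayCollection,
    SnpAssociation,
    write_bed_intervals,
    write_gmt,
    write_haplotype_panel,
    write_snp_table,
    write_table,
)
from .regulatory_map import EnhancerAssociation, EqtlRecord

PHENOTYPES = ("LUAD", "LUSC", "SCLC")

#: physical separation between block starts, comfortably beyond the 1-Mb
#: expansion window so proxies never leak across blocks
BLOCK_GAP_BP = 3_000_000


@dataclass(frozen=True)
class LdBlockSpec:
    """Layout and LD strength of the simulated haplotype panel."""

    n_blocks: int = 60
    snps_per_block: int = 8
    within_block_r2: float = 0.9
    maf_range: tuple[float, float] = (0.1, 0.5)
    bp_spacing: int = 1_000

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.snps_per_block < 1:
            raise ValueError("need at least one block and one SNP per block")
        if not (0.0 <= self.within_block_r2 <= 1.0):
            raise ValueError("within_block_r2 must lie in [0, 1]")
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError(f"infeasible maf_range {self.maf_range}")
        if self.bp_spacing < 1:
            raise ValueError("bp_spacing must be >= 1")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted into a synthetic study."""

    shared_signal_snps: frozenset[str]
    unique_signal_snps: dict[str, frozenset[str]]
    shared_target_genes: frozenset[str]
    unique_target_genes: dict[str, frozenset[str]]
    enriched_pathway_id: str

    def __post_init__(self) -> None:
        all_unique: set[str] = set()
        for snps in self.unique_signal_snps.values():
            if snps & self.shared_signal_snps:
                raise ValueError("shared and unique signal SNPs must be disjoint")
            if snps & all_unique:
                raise ValueError("unique signal SNPs must not repeat across phenotypes")
            all_unique |= snps

    @property
    def phenotypes(self) -> list[str]:
        return list(self.unique_signal_snps)

    def planted_snps(self, phenotype: str) -> frozenset[str]:
        return self.shared_signal_snps | self.unique_signal_snps[phenotype]

    def planted_genes(self, phenotype: str) -> frozenset[str]:
        return self.shared_target_genes | self.unique_target_genes[phenotype]


def simulate_haplotype_panel(
    spec: LdBlockSpec, n_haplotypes: int, seed: int
) -> HaplotypePanel:
    """Block-structured phased panel; deterministic given (spec, seed).

    With ``within_block_r2 = 1`` every column in a block equals the
    founder; with ``within_block_r2 = 0`` the flip probability is 1/2 and
    columns are independent Bernoulli(1/2) regardless of the founder.
    """
    if n_haplotypes < 4 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even and >= 4")
    rng = np.random.default_rng(seed)
    eps = (1.0 - spec.within_block_r2 ** 0.25) / 2.0
    cols = []
    rows = []
    snp_i = 0
    for b in range(spec.n_blocks):
        low, high = spec.maf_range
        p = rng.uniform(low, high)
        founder = (rng.random(n_haplotypes) < p).astype(np.uint8)
        # a monomorphic founder defeats the block structure; redraw a few times
        for _ in range(100):
            if 0 < founder.sum() < n_haplotypes:
                break
            founder = (rng.random(n_haplotypes) < p).astype(np.uint8)
        base = b * BLOCK_GAP_BP
        for s in range(spec.snps_per_block):
            flips = (rng.random(n_haplotypes) < eps).astype(np.uint8)
            col = founder ^ flips
            cols.append(col)
            rows.append(
                (f"rs{snp_i + 1}", "1", base + s * spec.bp_spacing, "A", "G")
            )
            snp_i += 1
    variants = pd.DataFrame(rows, columns=["rsid", "chrom", "pos0", "ref", "alt"])
    return HaplotypePanel(variants, np.column_stack(cols))


def block_center_rsids(spec: LdBlockSpec, blocks: Sequence[int]) -> list[str]:
    """rsid of the middle SNP of each requested block."""
    mid = spec.snps_per_block // 2
    return [f"rs{b * spec.snps_per_block + mid + 1}" for b in blocks]


def simulate_gwas_summaries(
    panel: HaplotypePanel,
    truth: PlantedTruth,
    alpha_signal: float = 1e-4,
    seed: int = 0,
) -> dict[str, list[SnpAssociation]]:
    """Per-phenotype association tables covering every panel SNP.

    Planted signal SNPs draw p ~ Uniform(0, alpha_signal); all other SNPs
    draw p ~ Uniform(0, 1).  P-values are floored at 1e-300 to respect the
    open lower bound.
    """
    if not (0.0 < alpha_signal <= 1.0):
        raise ValueError("alpha_signal must lie in (0, 1]")
    all_planted = set(truth.shared_signal_snps)
    for snps in truth.unique_signal_snps.values():
        all_planted |= snps
    missing = [r for r in sorted(all_planted) if r not in panel]
    if missing:
        raise ValueError(f"planted rsid(s) not in panel: {missing}")
    rng = np.random.default_rng(seed)
    rsids = panel.rsids
    chroms = panel.variants["chrom"].to_list()
    pos1 = (panel.variants["pos0"] + 1).to_list()
    out: dict[str, list[SnpAssociation]] = {}
    for phen in truth.phenotypes:
        planted = truth.planted_snps(phen)
        pvals = rng.random(len(rsids))
        table = []
        for i, rsid in enumerate(rsids):
            p = pvals[i] * alpha_signal if rsid in planted else pvals[i]
            table.append(
                SnpAssociation(rsid, chroms[i], pos1[i], max(p, 1e-300), phen)
            )
        out[phen] = table
    return out


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

GENE_SPAN_BP = 20_000
#: decoy and unique genes sit on their own loci, > 1 Mb from any neighbour
GENE_LOCUS_GAP_BP = 2_000_000
#: shared target genes share one locus, < 1 Mb apart
SHARED_GENE_SPACING_BP = 300_000


def _make_gene(gene: str, chrom: str, start: int) -> GeneModel:
    """A 20-kb gene with UTR/CDS/UTR exon structure."""
    return GeneModel(
        gene=gene,
        chrom=chrom,
        strand="+",
        span=(start, start + GENE_SPAN_BP),
        exons=[
            (start, start + 1_000),
            (start + 8_000, start + 12_000),
            (start + 19_000, start + GENE_SPAN_BP),
        ],
        cds=[(start + 8_000, start + 12_000)],
        utr=[(start, start + 1_000), (start + 19_000, start + GENE_SPAN_BP)],
    )


def make_gene_models(truth: PlantedTruth, n_decoy_genes: int) -> list[GeneModel]:
    """Deterministic gene layout realising the planted locus structure.

    Shared target genes share one sub-1-Mb locus; every unique target gene
    and decoy gene sits on its own locus with > 1 Mb to any neighbour.
    """
    models: list[GeneModel] = []
    base = 200_000_000  # clear of the SNP blocks
    for i, gene in enumerate(sorted(truth.shared_target_genes)):
        models.append(_make_gene(gene, "1", base + i * SHARED_GENE_SPACING_BP))
    cursor = base + 10_000_000
    for phen in truth.phenotypes:
        for gene in sorted(truth.unique_target_genes[phen]):
            models.append(_make_gene(gene, "1", cursor))
            cursor += GENE_LOCUS_GAP_BP
    for d in range(n_decoy_genes):
        models.append(_make_gene(f"DECOY{d + 1}", "2", 1_000_000 + d * GENE_LOCUS_GAP_BP))
    return models


# ---------------------------------------------------------------------------
# Regulatory catalogs
# ---------------------------------------------------------------------------

ENHANCER_HALF_WIDTH_BP = 100


@dataclass
class RegulatoryCatalogs:
    """The five regulatory evidence inputs plus the transcript→gene map."""

    single_tissue: list[EqtlRecord]
    multi_tissue: list[EqtlRecord]
    probe: list[EqtlRecord]
    enhancers: list[GenomicInterval]
    fantom_associations: list[EnhancerAssociation]
    impet_pairs: list[EnhancerAssociation]
    tx2gene: dict[str, str]

    def gene_universe(self) -> set[str]:
        """All genes any catalog can possibly yield (the default
        enrichment background)."""
        genes = {r.gene for r in self.single_tissue}
        genes |= {r.gene for r in self.multi_tissue}
        genes |= {r.gene for r in self.probe if r.gene}
        genes |= {a.target for a in self.fantom_associations}
        genes |= {
            self.tx2gene[p.target]
            for p in self.impet_pairs
            if p.target in self.tx2gene
        }
        return genes

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all catalogs as the TSV/BED dialects io_formats reads.

        Output is byte-deterministic for a given object.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def eqtl_df(records: list[EqtlRecord]) -> pd.DataFrame:
            return pd.DataFrame(
                [
                    (r.rsid, r.gene, r.tissue, r.qvalue, r.posterior, r.probe_id)
                    for r in records
                ],
                columns=["rsid", "gene", "tissue", "qvalue", "posterior", "probe_id"],
            )

        def assoc_df(assocs: list[EnhancerAssociation]) -> pd.DataFrame:
            return pd.DataFrame(
                [
                    (
                        a.enhancer.chrom,
                        a.enhancer.start,
                        a.enhancer.end,
                        a.target,
                        a.score,
                        a.rpkm,
                        a.cell_line,
                    )
                    for a in assocs
                ],
                columns=[
                    "enh_chrom", "enh_start", "enh_end", "target",
                    "score", "rpkm", "cell_line",
                ],
            )

        paths["eqtl_single"] = out_dir / "eqtl_single.tsv"
        write_table(eqtl_df(self.single_tissue), paths["eqtl_single"])
        paths["eqtl_multi"] = out_dir / "eqtl_multi.tsv"
        write_table(eqtl_df(self.multi_tissue), paths["eqtl_multi"])
        paths["eqtl_probe"] = out_dir / "eqtl_probe.tsv"
        write_table(eqtl_df(self.probe), paths["eqtl_probe"])
        paths["enhancers_bed"] = out_dir / "enhancers.bed"
        write_bed_intervals(self.enhancers, paths["enhancers_bed"])
        paths["fantom_associations"] = out_dir / "fantom_associations.tsv"
        write_table(assoc_df(self.fantom_associations), paths["fantom_associations"])
        paths["impet_pairs"] = out_dir / "impet_pairs.tsv"
        write_table(assoc_df(self.impet_pairs), paths["impet_pairs"])
        paths["tx2gene"] = out_dir / "tx2gene.tsv"
        write_table(
            pd.DataFrame(
                sorted(self.tx2gene.items()), columns=["transcript", "gene"]
            ),
            paths["tx2gene"],
        )
        return paths


def _enhancer_at(panel: HaplotypePanel, rsid: str, name: str) -> GenomicInterval:
    i = panel.index_of(rsid)
    pos0 = int(panel.variants["pos0"].iloc[i])
    chrom = str(panel.variants["chrom"].iloc[i])
    start = max(0, pos0 - ENHANCER_HALF_WIDTH_BP)
    return GenomicInterval(chrom, start, pos0 + ENHANCER_HALF_WIDTH_BP, name)


def simulate_regulatory_catalogs(
    panel: HaplotypePanel,
    gene_models: Sequence[GeneModel],
    truth: PlantedTruth,
    seed: int = 0,
    n_decoy_rows: int = 40,
) -> RegulatoryCatalogs:
    """Catalogs in which every planted (SNP, gene) pair passes exactly one
    source's filter, plus decoy rows that fail every filter.

    Planted pairs are assigned to sources cyclically (gtex_single,
    gtex_multi, probe_eqtl, fantom5, impet) so all five paths are
    exercised.  Decoys: single-tissue rows with q ~ U(0.06, 1), multi-
    tissue rows with posterior ~ U(0, 0.79), probe rows with unannotated
    gene names, zero-RPKM predicted-enhancer targets, an unmapped
    transcript target, and enhancers in empty regions.
    """
    model_genes = {m.gene for m in gene_models}
    rng = np.random.default_rng(seed)

    pairs: list[tuple[str, str]] = []
    shared_snps = sorted(truth.shared_signal_snps)
    for i, gene in enumerate(sorted(truth.shared_target_genes)):
        pairs.append((shared_snps[i % len(shared_snps)], gene))
    for phen in truth.phenotypes:
        usnps = sorted(truth.unique_signal_snps[phen])
        for i, gene in enumerate(sorted(truth.unique_target_genes[phen])):
            pairs.append((usnps[i % len(usnps)], gene))
    for rsid, gene in pairs:
        if gene not in model_genes:
            raise ValueError(f"target gene {gene!r} absent from gene models")
        if rsid not in panel:
            raise ValueError(f"planted rsid {rsid!r} absent from panel")

    single: list[EqtlRecord] = []
    multi: list[EqtlRecord] = []
    probe: list[EqtlRecord] = []
    enhancers: list[GenomicInterval] = []
    fantom: list[EnhancerAssociation] = []
    impet: list[EnhancerAssociation] = []
    tx2gene: dict[str, str] = {}

    sources = ("gtex_single", "gtex_multi", "probe_eqtl", "fantom5", "impet")
    for i, (rsid, gene) in enumerate(pairs):
        source = sources[i % len(sources)]
        if source == "gtex_single":
            single.append(
                EqtlRecord(rsid, gene, tissue="Lung", qvalue=round(rng.uniform(0.001, 0.05), 6))
            )
        elif source == "gtex_multi":
            multi.append(
                EqtlRecord(rsid, gene, tissue="multi", posterior=round(rng.uniform(0.85, 0.99), 6))
            )
        elif source == "probe_eqtl":
            # two probes for the same pair: exercises the merge rule
            q = round(rng.uniform(0.001, 0.05), 6)
            probe.append(EqtlRecord(rsid, gene, tissue="Lung", qvalue=q, probe_id=f"P{i}a"))
            probe.append(
                EqtlRecord(rsid, gene, tissue="Lung", qvalue=round(min(q + 0.01, 0.09), 6),
                           probe_id=f"P{i}b")
            )
        elif source == "fantom5":
            enh = _enhancer_at(panel, rsid, f"FANTOM_E{i}")
            enhancers.append(enh)
            fantom.append(EnhancerAssociation(enh, gene, score=round(rng.uniform(0.5, 1.0), 4)))
        else:  # impet
            enh = _enhancer_at(panel, rsid, f"IMPET_E{i}")
            enhancers.append(enh)
            tx = f"TX_{gene}"
            tx2gene[tx] = gene
            for cell_line in ("IMR90", "NHLF"):
                impet.append(
                    EnhancerAssociation(enh, tx, rpkm=round(rng.uniform(1.0, 50.0), 3),
                                        cell_line=cell_line)
                )

    # --- decoys: all fail their source's filter ---
    decoy_genes = sorted(g for g in model_genes if g.startswith("DECOY"))
    null_rsids = [
        r for r in panel.rsids
        if r not in truth.shared_signal_snps
        and all(r not in s for s in truth.unique_signal_snps.values())
    ]
    for d in range(n_decoy_rows):
        rsid = null_rsids[int(rng.integers(len(null_rsids)))]
        gene = decoy_genes[d % len(decoy_genes)] if decoy_genes else "DECOY1"
        single.append(
            EqtlRecord(rsid, gene, tissue="Lung", qvalue=round(rng.uniform(0.06, 1.0), 6))
        )
        multi.append(
            EqtlRecord(rsid, gene, tissue="multi", posterior=round(rng.uniform(0.0, 0.79), 6))
        )
        probe.append(
            EqtlRecord(rsid, "", tissue="Lung", qvalue=round(rng.uniform(0.0, 0.1), 6),
                       probe_id=f"PD{d}")
        )
    if pairs:
        # zero-RPKM target and an unmapped transcript on a planted enhancer
        host = enhancers[0] if enhancers else _enhancer_at(panel, pairs[0][0], "IMPET_D0")
        if not enhancers:
            enhancers.append(host)
        impet.append(EnhancerAssociation(host, "TX_SILENT", rpkm=0.0, cell_line="IMR90"))
        impet.append(EnhancerAssociation(host, "TX_UNKNOWN", rpkm=5.0, cell_line="NHLF"))
        tx2gene.setdefault("TX_SILENT", "DECOY1")
    # enhancers in empty territory (no SNP inside, no association)
    far = 10 ** 9
    for d in range(3):
        enhancers.append(GenomicInterval("1", far + d * 10_000, far + d * 10_000 + 200,
                                         f"EMPTY_E{d}"))
    return RegulatoryCatalogs(
        single_tissue=single,
        multi_tissue=multi,
        probe=probe,
        enhancers=enhancers,
        fantom_associations=fantom,
        impet_pairs=impet,
        tx2gene=tx2gene,
    )


# ---------------------------------------------------------------------------
# Pathways
# ---------------------------------------------------------------------------


def simulate_pathways(
    gene_universe: Sequence[str],
    truth: PlantedTruth,
    n_pathways: int = 20,
    seed: int = 0,
    size_range: tuple[int, int] = (10, 30),
) -> PathwayCollection:
    """A pathway collection with one planted enriched pathway.

    The planted pathway contains every planted target gene (shared and
    unique) plus fillers from the universe; the remaining pathways are
    uniform draws from the universe.
    """
    universe = sorted(set(gene_universe))
    planted_genes = set(truth.shared_target_genes)
    for genes in truth.unique_target_genes.values():
        planted_genes |= genes
    if not planted_genes <= set(universe):
        raise ValueError("planted target genes must lie in the gene universe")
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError("universe smaller than requested pathway sizes")
    if n_pathways < 1:
        raise ValueError("need at least one pathway")
    rng = np.random.default_rng(seed)
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    planted = set(planted_genes)
    n_fill = max(0, lo - len(planted))
    fillers = [g for g in universe if g not in planted]
    if n_fill:
        pick = rng.choice(len(fillers), size=n_fill, replace=False)
        planted |= {fillers[i] for i in pick}
    pathways[truth.enriched_pathway_id] = planted
    descriptions[truth.enriched_pathway_id] = "planted enriched pathway"
    for j in range(n_pathways - 1):
        size = int(rng.integers(lo, hi + 1))
        pick = rng.choice(len(universe), size=size, replace=False)
        pid = f"PW{j + 1:03d}"
        pathways[pid] = {universe[i] for i in pick}
        descriptions[pid] = f"random pathway {j + 1}"
    return PathwayCollection(pathways, descriptions)


# ---------------------------------------------------------------------------
# Whole-study convenience layer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyParams:
    """Default conditions for a full synthetic study.

    Three phenotypes share ``n_shared`` planted signal SNPs (one per LD
    block) whose target genes co-locate on a single sub-1-Mb locus; each
    phenotype additionally carries ``n_unique`` private signal SNPs with
    private target genes on isolated loci.  The gene universe is the
    planted targets plus ``n_decoy_genes`` decoys.
    """

    ld: LdBlockSpec = field(default_factory=LdBlockSpec)
    n_haplotypes: int = 600
    phenotypes: tuple[str, ...] = PHENOTYPES
    n_shared: int = 3
    n_unique: int = 2
    alpha_signal: float = 1e-4
    n_decoy_genes: int = 191
    n_pathways: int = 20

    def __post_init__(self) -> None:
        needed = self.n_shared + len(self.phenotypes) * self.n_unique
        if needed > self.ld.n_blocks:
            raise ValueError("not enough LD blocks to host all planted signals")


@dataclass
class SyntheticStudy:
    """A complete, self-consistent set of pipeline inputs plus truth."""

    params: StudyParams
    truth: PlantedTruth
    panel: HaplotypePanel
    gwas: dict[str, list[SnpAssociation]]
    gene_models: list[GeneModel]
    catalogs: RegulatoryCatalogs
    pathways: PathwayCollection
    chip_snps: list[str]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every input file the pipeline needs; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = self.catalogs.write(out_dir)
        paths["panel_vcf"] = out_dir / "panel.vcf"
        write_haplotype_panel(self.panel, paths["panel_vcf"])
        paths["gwas_snps"] = out_dir / "gwas_snps.tsv"
        all_snps = [s for phen in self.params.phenotypes for s in self.gwas[phen]]
        write_snp_table(all_snps, paths["gwas_snps"])
        paths["gene_models"] = out_dir / "gene_models.tsv"
        write_gene_models(self.gene_models, paths["gene_models"])
        paths["pathways_gmt"] = out_dir / "pathways.gmt"
        write_gmt(self.pathways, paths["pathways_gmt"])
        paths["chip_snps"] = out_dir / "chip_snps.txt"
        with open(paths["chip_snps"], "w") as fh:
            fh.write("\n".join(self.chip_snps) + "\n")
        return paths


def simulate_study(params: StudyParams | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a full synthetic study with planted truth.

    Deterministic given (params, seed); sub-generators receive distinct
    seeds derived from *seed* via numpy's seed-sequence spawning.
    """
    if params is None:
        params = StudyParams()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    spec = params.ld
    panel = simulate_haplotype_panel(spec, params.n_haplotypes, seeds[0])

    shared_blocks = list(range(params.n_shared))
    shared_snps = frozenset(block_center_rsids(spec, shared_blocks))
    unique_snps: dict[str, frozenset[str]] = {}
    cursor = params.n_shared
    for phen in params.phenotypes:
        blocks = list(range(cursor, cursor + params.n_unique))
        unique_snps[phen] = frozenset(block_center_rsids(spec, blocks))
        cursor += params.n_unique
    shared_genes = frozenset(f"SHR{i + 1}" for i in range(params.n_shared))
    unique_genes = {
        phen: frozenset(f"UNQ_{phen}_{i + 1}" for i in range(params.n_unique))
        for phen in params.phenotypes
    }
    truth = PlantedTruth(
        shared_signal_snps=shared_snps,
        unique_signal_snps=unique_snps,
        shared_target_genes=shared_genes,
        unique_target_genes=unique_genes,
        enriched_pathway_id="PW_PLANTED",
    )
    gene_models = make_gene_models(truth, params.n_decoy_genes)
    gwas = simulate_gwas_summaries(panel, truth, params.alpha_signal, seeds[1])
    catalogs = simulate_regulatory_catalogs(panel, gene_models, truth, seeds[2])
    universe = sorted({m.gene for m in gene_models})
    pathways = simulate_pathways(universe, truth, params.n_pathways, seeds[3])
    return SyntheticStudy(
        params=params,
        truth=truth,
        panel=panel,
        gwas=gwas,
        gene_models=gene_models,
        catalogs=catalogs,
        pathways=pathways,
        chip_snps=list(panel.rsids),
    )
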