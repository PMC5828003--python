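"""Genomic-location categories for SNPs, and identifier remapping.

Each SNP receives exactly one of four categories — coding, utr, intron,
intergenic — from a set of gene models, using the precedence
coding > utr > intron across all overlapping transcripts.  A position
inside a gene span but in no CDS or UTR is an intron; a position
overlapping no gene span is intergenic.  The four categories partition any
SNP list, so per-phenotype counts always sum to the total.

:func:`remap_identifiers` applies a pre-computed old→new identifier and
coordinate table (the output of an external liftover / dbSNP merge, which
this package does not compute itself).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import FormatError, SnpAssociation, read_table

logger = logging.getLogger("regshare")

CATEGORIES = ("coding", "utr", "intron", "intergenic")

Interval = tuple[int, int]


def _merge(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _contains(intervals: Sequence[Interval], pos0: int) -> bool:
    return any(s <= pos0 < e for s, e in intervals)


@dataclass
class GeneModel:
    """One gene's feature intervals (0-based half-open).

    ``span`` is the full gene extent; ``cds``/``utr``/``exons`` are merged,
    non-overlapping interval lists.  CDS and UTR must lie within exons,
    which must lie within the span.
    """

    gene: str
    chrom: str
    strand: str = "+"
    span: Interval = (0, 1)
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = _merge(self.exons)
        self.cds = _merge(self.cds)
        self.utr = _merge(self.utr)
        s, e = self.span
        if not (0 <= s < e):
            raise ValueError(f"{self.gene}: invalid span {self.span}")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a 6-column TSV.

    Columns: gene, chrom, strand, feature_type in {gene, exon, cds, utr},
    start, end (0-based half-open).  The gene span comes from the ``gene``
    rows; if absent it is the hull of the exons.
    """
    df = read_table(path, ["gene", "chrom", "strand", "feature_type", "start", "end"])
    models: dict[str, dict] = {}
    for r in df.itertuples():
        key = str(r.gene)
        rec = models.setdefault(
            key,
            {"chrom": str(r.chrom), "strand": str(r.strand), "gene": None,
             "exon": [], "cds": [], "utr": []},
        )
        ftype = str(r.feature_type).lower()
        iv = (int(r.start), int(r.end))
        if ftype == "gene":
            rec["gene"] = iv
        elif ftype in ("exon", "cds", "utr"):
            rec[ftype].append(iv)
        else:
            raise FormatError(f"{path}: unknown feature_type {ftype!r}")
    out = []
    for gene, rec in models.items():
        exons = rec["exon"] or rec["cds"] + rec["utr"]
        span = rec["gene"]
        if span is None:
            hull = _merge(exons)
            if not hull:
                raise FormatError(f"{path}: gene {gene!r} has no intervals")
            span = (hull[0][0], hull[-1][1])
        out.append(
            GeneModel(gene=gene, chrom=rec["chrom"], strand=rec["strand"],
                      span=span, exons=exons, cds=rec["cds"], utr=rec["utr"])
        )
    return out


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for m in models:
        rows.append((m.gene, m.chrom, m.strand, "gene", m.span[0], m.span[1]))
        for ftype, ivs in (("exon", m.exons), ("cds", m.cds), ("utr", m.utr)):
            rows.extend((m.gene, m.chrom, m.strand, ftype, s, e) for s, e in ivs)
    pd.DataFrame(
        rows, columns=["gene", "chrom", "strand", "feature_type", "start", "end"]
    ).to_csv(path, sep="\t", index=False)


def index_models(models: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_chrom[m.chrom].append(m)
    return dict(by_chrom)


def annotate_location(
    snp: SnpAssociation,
    models: Sequence[GeneModel] | Mapping[str, Sequence[GeneModel]],
) -> str:
    """Single category for one SNP: coding > utr > intron > intergenic.

    The precedence is applied across *all* transcripts overlapping the
    position, so a position coding in any transcript is "coding" even if
    untranslated in another.  Unknown chromosomes yield "intergenic".
    """
    if isinstance(models, Mapping):
        candidates = models.get(snp.chrom, [])
    else:
        candidates = [m for m in models if m.chrom == snp.chrom]
    pos0 = snp.pos0
    in_span = False
    in_utr = False
    for m in candidates:
        s, e = m.span
        if not (s <= pos0 < e):
            continue
        in_span = True
        if _contains(m.cds, pos0):
            return "coding"
        if _contains(m.utr, pos0):
            in_utr = True
    if in_utr:
        return "utr"
    return "intron" if in_span else "intergenic"


@dataclass(frozen=True)
class LocationSummary:
    """Per-phenotype counts of the four location categories."""

    phenotype: str
    total: int
    coding: int
    intron: int
    utr: int
    intergenic: int

    def __post_init__(self) -> None:
        if self.coding + self.intron + self.utr + self.intergenic != self.total:
            raise ValueError("category counts do not sum to total")


def summarize_locations(
    snps: Iterable[SnpAssociation],
    models: Sequence[GeneModel] | Mapping[str, Sequence[GeneModel]],
) -> dict[str, LocationSummary]:
    """Category counts per phenotype; counts partition each SNP list."""
    if not isinstance(models, Mapping):
        models = index_models(models)
    counts: dict[str, dict[str, int]] = defaultdict(
        lambda: {c: 0 for c in CATEGORIES}
    )
    for snp in snps:
        counts[snp.phenotype][annotate_location(snp, models)] += 1
    return {
        phen: LocationSummary(
            phenotype=phen,
            total=sum(c.values()),
            coding=c["coding"],
            intron=c["intron"],
            utr=c["utr"],
            intergenic=c["intergenic"],
        )
        for phen, c in counts.items()
    }


def remap_identifiers(
    snps: Sequence[SnpAssociation],
    mapping: pd.DataFrame,
) -> tuple[list[SnpAssociation], list[SnpAssociation]]:
    """Apply an old→new identifier/coordinate table to a SNP list.

    ``mapping`` needs columns old_id, new_id, new_chrom, new_pos; old_id
    must be unique.  Returns (remapped, unmapped).  SNPs absent from the
    table are dropped and reported; when several old ids merge into one new
    id within a phenotype, the record with the smallest p-value is kept.
    """
    required = ["old_id", "new_id", "new_chrom", "new_pos"]
    missing = [c for c in required if c not in mapping.columns]
    if missing:
        raise ValueError(f"mapping table missing column(s) {missing}")
    if mapping["old_id"].duplicated().any():
        dups = mapping.loc[mapping["old_id"].duplicated(), "old_id"].tolist()
        raise ValueError(f"duplicate old_id in mapping: {sorted(set(dups))}")
    table = {
        str(r.old_id): (str(r.new_id), str(r.new_chrom), int(r.new_pos))
        for r in mapping.itertuples()
    }
    best: dict[tuple[str, str], SnpAssociation] = {}
    order: list[tuple[str, str]] = []
    unmapped: list[SnpAssociation] = []
    for snp in snps:
        hit = table.get(snp.rsid)
        if hit is None:
            unmapped.append(snp)
            continue
        new_id, new_chrom, new_pos = hit
        cand = SnpAssociation(new_id, new_chrom, new_pos, snp.pvalue, snp.phenotype)
        key = (new_id, snp.phenotype)
        if key not in best:
            best[key] = cand
            order.append(key)
        elif cand.pvalue < best[key].pvalue:
            best[key] = cand
    if unmapped:
        logger.warning("remap_identifiers: %d SNP(s) unmapped, dropped", len(unmapped))
    return [best[k] for k in order], unmapped
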