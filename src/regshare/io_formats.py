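"""Readers, writers and domain types for the formats the pipeline touches.

The pipeline consumes per-phenotype GWAS summary tables (TSV), a phased
haplotype reference panel (VCF, GT-only use), interval sets (BED3/BED4),
pathway collections (GMT) and a number of tabular catalogs (TSV with a
mandatory header row).  All internal coordinates are 0-based half-open;
VCF positions are converted on read (pos - 1) and back on write, so the
single internal convention removes off-by-one risk at the BED/VCF boundary.

SNP association records keep their 1-based ``pos`` field as printed in GWAS
summary tables and expose a ``pos0`` property for interval work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("regshare")

#: canonical column order for SNP association tables
SNP_TABLE_COLUMNS = ["rsid", "chrom", "pos", "pvalue", "phenotype"]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpAssociation:
    """One genotyped SNP with its phenotype label and association p-value.

    ``pos`` is 1-based (as printed in GWAS summary tables); use ``pos0``
    for 0-based half-open interval arithmetic.
    """

    rsid: str
    chrom: str
    pos: int
    pvalue: float
    phenotype: str

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos} for {self.rsid}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(
                f"pvalue must be in (0, 1], got {self.pvalue} for {self.rsid}"
            )

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1


@dataclass(frozen=True)
class GenomicInterval:
    """A BED-convention interval: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if not self.name:
            object.__setattr__(self, "name", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class HaplotypePanel:
    """Phased binary haplotype matrix over biallelic variants.

    ``matrix`` is (n_haplotypes, n_variants) with 0 = REF and 1 = ALT.
    ``variants`` is a DataFrame with columns rsid, chrom, pos0, ref, alt,
    sorted by (chrom, pos0).  Two haplotype rows per diploid sample.
    """

    def __init__(self, variants: pd.DataFrame, matrix: np.ndarray):
        variants = variants.reset_index(drop=True)
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or matrix.shape[1] != len(variants):
            raise ValueError("matrix shape does not match variant table")
        if matrix.shape[0] % 2 != 0:
            raise ValueError("n_haplotypes must be even (phased diploids)")
        if matrix.size and not np.isin(matrix, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")
        order = np.lexsort((variants["pos0"].to_numpy(), variants["chrom"].to_numpy()))
        variants = variants.iloc[order].reset_index(drop=True)
        matrix = matrix[:, order]
        dup = variants.duplicated(subset=["chrom", "pos0", "alt"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos, alt) in panel")
        self.variants = variants
        self.matrix = matrix
        self._index: dict[str, int] = {
            rsid: i for i, rsid in enumerate(variants["rsid"])
        }

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    @property
    def rsids(self) -> list[str]:
        return list(self.variants["rsid"])

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def index_of(self, rsid: str) -> int:
        try:
            return self._index[rsid]
        except KeyError:
            raise KeyError(f"rsid {rsid!r} not in panel") from None

    def column(self, rsid: str) -> np.ndarray:
        return self.matrix[:, self.index_of(rsid)]

    def alt_freqs(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def maf(self) -> np.ndarray:
        f = self.alt_freqs()
        return np.minimum(f, 1.0 - f)


class PathwayCollection:
    """Named gene sets with one-line descriptions (GMT semantics)."""

    def __init__(
        self,
        pathways: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self.pathways: dict[str, frozenset[str]] = {}
        self.descriptions: dict[str, str] = {}
        for pid, genes in pathways.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")
            if pid in self.pathways:
                raise ValueError(f"duplicate pathway id {pid!r}")
            self.pathways[pid] = genes
            self.descriptions[pid] = (descriptions or {}).get(pid, "")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.pathways[pid]

    def items(self):
        return self.pathways.items()

    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.pathways.values():
            out |= genes
        return frozenset(out)


# ---------------------------------------------------------------------------
# VCF haplotype panel
# ---------------------------------------------------------------------------


def read_haplotype_panel(path: str | Path) -> HaplotypePanel:
    """Read a phased VCF into a binary haplotype matrix.

    Only biallelic SNV records are kept; multi-allelic records are skipped
    with a counted warning.  Genotypes must be phased ("|") and complete:
    an unphased or missing genotype aborts with the offending record named.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    vcf = VCF(str(path))
    n_samples = len(vcf.samples)
    if n_samples == 0:
        raise FormatError(f"{path}: VCF has no sample columns")
    rows = []
    columns = []
    n_skipped_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped_multiallelic += 1
            continue
        gts = rec.genotypes  # [a0, a1, phased] per sample
        col = np.empty(2 * n_samples, dtype=np.uint8)
        for i, gt in enumerate(gts):
            if len(gt) < 3 or gt[0] < 0 or gt[1] < 0:
                raise FormatError(
                    f"{path}: missing genotype at {rec.CHROM}:{rec.POS} ({rec.ID})"
                )
            if not gt[-1]:
                raise FormatError(
                    f"{path}: unphased genotype at {rec.CHROM}:{rec.POS} ({rec.ID})"
                )
            col[2 * i] = gt[0]
            col[2 * i + 1] = gt[1]
        rsid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append((rsid, rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
        columns.append(col)
    if not rows:
        raise FormatError(f"{path}: no biallelic records found")
    if n_skipped_multiallelic:
        logger.warning(
            "%s: skipped %d multi-allelic record(s)", path, n_skipped_multiallelic
        )
    variants = pd.DataFrame(rows, columns=["rsid", "chrom", "pos0", "ref", "alt"])
    matrix = np.column_stack(columns)
    panel = HaplotypePanel(variants, matrix)
    panel.n_skipped_multiallelic = n_skipped_multiallelic  # type: ignore[attr-defined]
    return panel


def write_haplotype_panel(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal phased VCF (GT only, synthetic samples)."""
    path = Path(path)
    n_samples = panel.n_haplotypes // 2
    samples = [f"S{i}" for i in range(n_samples)]
    chroms = sorted(set(panel.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, row in panel.variants.iterrows():
            col = panel.matrix[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples)
            )
            fh.write(
                f"{row.chrom}\t{row.pos0 + 1}\t{row.rsid}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GMT pathways
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file: ``id<TAB>description<TAB>gene...`` per line."""
    path = Path(path)
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    f"at least one gene ({len(fields)} field(s) found)"
                )
            pid, desc = fields[0], fields[1]
            if pid in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene list for {pid!r}")
            pathways[pid] = genes
            descriptions[pid] = desc
    if not pathways:
        raise FormatError(f"{path}: no pathways found")
    return PathwayCollection(pathways, descriptions)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in collection:
            genes = "\t".join(sorted(collection[pid]))
            fh.write(f"{pid}\t{collection.descriptions.get(pid, '')}\t{genes}\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals, preserving 0-based half-open coordinates.

    Unnamed intervals receive the canonical name ``chrom:start-end`` so
    downstream joins have stable keys.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from None
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"[{start}, {end})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] else ""
            out.append(GenomicInterval(chrom, start, end, name))
    return out


def write_bed_intervals(
    intervals: Sequence[GenomicInterval], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_table(
    path: str | Path, required_columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Read a header-full TSV; error if required columns are missing."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "rsid", "gene", "phenotype"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> list[SnpAssociation]:
    """Read a GWAS summary SNP table (rsid, chrom, pos, pvalue, phenotype)."""
    df = read_table(path, SNP_TABLE_COLUMNS)
    return [
        SnpAssociation(
            rsid=str(r.rsid),
            chrom=str(r.chrom),
            pos=int(r.pos),
            pvalue=float(r.pvalue),
            phenotype=str(r.phenotype),
        )
        for r in df.itertuples()
    ]


def write_snp_table(snps: Iterable[SnpAssociation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.rsid, s.chrom, s.pos, s.pvalue, s.phenotype) for s in snps],
        columns=SNP_TABLE_COLUMNS,
    )
    write_table(df, path)


def validate_file(path: str | Path, fmt: str) -> dict:
    """Parse *path* as *fmt* in {vcf,bed,gmt,tsv}; return summary counts."""
    if fmt == "vcf":
        panel = read_haplotype_panel(path)
        return {
            "format": "vcf",
            "n_variants": panel.n_variants,
            "n_haplotypes": panel.n_haplotypes,
        }
    if fmt == "bed":
        ivs = read_bed_intervals(path)
        return {"format": "bed", "n_intervals": len(ivs)}
    if fmt == "gmt":
        coll = read_gmt(path)
        return {"format": "gmt", "n_pathways": len(coll)}
    if fmt == "tsv":
        df = read_table(path)
        return {"format": "tsv", "n_rows": len(df), "columns": list(df.columns)}
    raise ValueError(f"unknown format {fmt!r}")
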