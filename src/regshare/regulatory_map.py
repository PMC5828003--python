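"""SNP-to-target-gene mapping through eQTL catalogs and enhancer sets.

Five evidence sources feed the germline-regulated gene sets, each with its
own significance filter:

* ``gtex_single`` — tissue-specific eQTLs, significant at q-value <= 0.05
  (inclusive boundary);
* ``gtex_multi``  — multi-tissue eQTLs, significant at posterior
  probability > 0.8 (strict boundary; the averaged posterior over the
  contributing models is the one consumed);
* ``probe_eqtl``  — probe-level lung eQTLs, consumed as a pre-filtered
  catalog after cleaning (unnamed target genes removed, duplicate probes
  for one gene merged keeping the smallest q-value);
* ``fantom5``     — SNPs inside transcribed (permissive) enhancer
  intervals, joined to the enhancers' correlated promoter target genes;
* ``impet``       — SNPs inside predicted enhancer intervals with
  transcript-level targets: zero-RPKM targets are removed *before*
  transcript→gene collapsing, and hits are merged across cell lines.

The boundary semantics (<= for q, > for posterior) are deliberate and
pinned by tests.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, SnpAssociation

logger = logging.getLogger("regshare")

SOURCES = ("gtex_single", "gtex_multi", "probe_eqtl", "fantom5", "impet")


@dataclass(frozen=True)
class EqtlRecord:
    """One SNP→gene eQTL row; carries a q-value and/or a posterior."""

    rsid: str
    gene: str
    tissue: str = ""
    qvalue: float | None = None
    posterior: float | None = None
    probe_id: str | None = None

    def __post_init__(self) -> None:
        if self.qvalue is None and self.posterior is None:
            raise ValueError(f"{self.rsid}: need qvalue or posterior")
        for name in ("qvalue", "posterior"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.rsid}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class EnhancerAssociation:
    """An enhancer interval linked to a target gene or transcript."""

    enhancer: GenomicInterval
    target: str
    score: float | None = None
    rpkm: float | None = None
    cell_line: str | None = None

    def __post_init__(self) -> None:
        if not self.target:
            raise ValueError("enhancer association target must be non-empty")
        if self.rpkm is not None and self.rpkm < 0:
            raise ValueError("rpkm must be >= 0")


@dataclass(frozen=True)
class RegulatoryHit:
    """A SNP→gene link with its evidence source.

    ``evidence`` holds the q-value or posterior that passed the filter,
    or 1.0 for a plain interval hit.
    """

    rsid: str
    gene: str
    source: str
    evidence: float = 1.0

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


def _dedup_hits(hits: Iterable[RegulatoryHit], keep: str) -> list[RegulatoryHit]:
    """Collapse duplicate (rsid, gene, source) keys, keeping the best evidence."""
    best: dict[tuple[str, str, str], RegulatoryHit] = {}
    order: list[tuple[str, str, str]] = []
    for h in hits:
        key = (h.rsid, h.gene, h.source)
        if key not in best:
            best[key] = h
            order.append(key)
        elif (keep == "min" and h.evidence < best[key].evidence) or (
            keep == "max" and h.evidence > best[key].evidence
        ):
            best[key] = h
    return [best[k] for k in order]


def map_eqtls_single(
    snps: set[str],
    catalog: Sequence[EqtlRecord],
    q_max: float = 0.05,
) -> list[RegulatoryHit]:
    """Tissue-specific eQTL hits: catalog rows with rsid in *snps* and
    q-value <= *q_max* (inclusive)."""
    hits = [
        RegulatoryHit(r.rsid, r.gene, "gtex_single", r.qvalue)
        for r in catalog
        if r.rsid in snps and r.qvalue is not None and r.qvalue <= q_max
    ]
    return _dedup_hits(hits, keep="min")


def map_eqtls_multi(
    snps: set[str],
    catalog: Sequence[EqtlRecord],
    posterior_min: float = 0.8,
) -> list[RegulatoryHit]:
    """Multi-tissue eQTL hits: posterior strictly greater than *posterior_min*."""
    hits = [
        RegulatoryHit(r.rsid, r.gene, "gtex_multi", r.posterior)
        for r in catalog
        if r.rsid in snps and r.posterior is not None and r.posterior > posterior_min
    ]
    return _dedup_hits(hits, keep="max")


_PLACEHOLDER_GENES = {"", ".", "-", "na", "nan", "none", "null"}


def clean_probe_catalog(catalog: Sequence[EqtlRecord]) -> list[EqtlRecord]:
    """Clean a probe-level catalog: drop rows without an annotated gene
    name and merge duplicate probes for the same (rsid, gene), keeping the
    smallest q-value."""
    best: dict[tuple[str, str], EqtlRecord] = {}
    order: list[tuple[str, str]] = []
    for r in catalog:
        if r.gene.lower() in _PLACEHOLDER_GENES:
            continue
        key = (r.rsid, r.gene)
        if key not in best:
            best[key] = r
            order.append(key)
        else:
            old = best[key]
            q_new = math.inf if r.qvalue is None else r.qvalue
            q_old = math.inf if old.qvalue is None else old.qvalue
            if q_new < q_old:
                best[key] = r
    return [best[k] for k in order]


def map_probe_eqtls(
    snps: set[str],
    catalog: Sequence[EqtlRecord],
    q_max: float | None = None,
) -> list[RegulatoryHit]:
    """Probe-level eQTL hits after cleaning.

    The catalog is assumed pre-filtered for significance upstream (e.g. at
    10% FDR), so no threshold is applied unless *q_max* is given.
    """
    cleaned = clean_probe_catalog(catalog)
    hits = []
    for r in cleaned:
        if r.rsid not in snps:
            continue
        if q_max is not None and (r.qvalue is None or r.qvalue > q_max):
            continue
        ev = 1.0 if r.qvalue is None else r.qvalue
        hits.append(RegulatoryHit(r.rsid, r.gene, "probe_eqtl", ev))
    return _dedup_hits(hits, keep="min")


def intersect_enhancers(
    snps: Iterable[SnpAssociation],
    enhancers: Sequence[GenomicInterval],
) -> list[tuple[str, GenomicInterval]]:
    """All (rsid, enhancer) pairs with the SNP inside the interval.

    Half-open semantics: a pair is emitted iff start <= pos0 < end on a
    matching chromosome.  Equivalent to the all-pairs scan.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in enhancers:
        trees[iv.chrom].addi(iv.start, iv.end, iv)
    out: list[tuple[str, GenomicInterval]] = []
    for snp in snps:
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        for node in sorted(tree.at(snp.pos0)):
            out.append((snp.rsid, node.data))
    return out


def enhancer_targets_fantom(
    hits: Sequence[tuple[str, GenomicInterval]],
    associations: Sequence[EnhancerAssociation],
) -> list[RegulatoryHit]:
    """Join SNP-in-enhancer hits to transcribed-enhancer target genes.

    Associations are keyed by enhancer interval identity (chrom, start,
    end); enhancers with no association contribute nothing (counted).
    Duplicate (rsid, gene) pairs are collapsed.
    """
    targets: dict[tuple[str, int, int], list[EnhancerAssociation]] = defaultdict(list)
    for assoc in associations:
        targets[assoc.enhancer.key].append(assoc)
    out: list[RegulatoryHit] = []
    n_orphans = 0
    for rsid, enh in hits:
        assocs = targets.get(enh.key)
        if not assocs:
            n_orphans += 1
            continue
        for assoc in assocs:
            out.append(RegulatoryHit(rsid, assoc.target, "fantom5", 1.0))
    if n_orphans:
        logger.warning(
            "enhancer_targets_fantom: %d hit(s) in enhancers without "
            "target associations, skipped",
            n_orphans,
        )
    return _dedup_hits(out, keep="max")


def enhancer_targets_impet(
    hits: Sequence[tuple[str, GenomicInterval]],
    pairs: Sequence[EnhancerAssociation],
    tx2gene: Mapping[str, str],
) -> list[RegulatoryHit]:
    """Join SNP-in-enhancer hits to predicted-enhancer target genes.

    Zero-RPKM (unexpressed) targets are removed before transcript→gene
    mapping; transcripts absent from *tx2gene* are dropped with a count;
    hits are merged across cell lines and (rsid, gene) deduplicated.
    """
    by_enh: dict[tuple[str, int, int], list[EnhancerAssociation]] = defaultdict(list)
    for p in pairs:
        if p.rpkm is not None and p.rpkm == 0:
            continue  # unexpressed target, removed before mapping
        by_enh[p.enhancer.key].append(p)
    out: list[RegulatoryHit] = []
    n_unmapped = 0
    for rsid, enh in hits:
        for p in by_enh.get(enh.key, []):
            gene = tx2gene.get(p.target)
            if gene is None:
                n_unmapped += 1
                continue
            out.append(RegulatoryHit(rsid, gene, "impet", 1.0))
    if n_unmapped:
        logger.warning(
            "enhancer_targets_impet: %d transcript target(s) without a "
            "gene mapping, dropped",
            n_unmapped,
        )
    return _dedup_hits(out, keep="max")


# --- tabular adapters -------------------------------------------------------


def eqtl_records_from_table(df: pd.DataFrame) -> list[EqtlRecord]:
    """Build EqtlRecords from a TSV table (columns rsid, gene, and any of
    tissue, qvalue, posterior, probe_id)."""
    def _opt(row, col):
        if col not in df.columns:
            return None
        v = getattr(row, col)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    out = []
    for r in df.itertuples():
        out.append(
            EqtlRecord(
                rsid=str(r.rsid),
                gene=str(r.gene),
                tissue=str(_opt(r, "tissue") or ""),
                qvalue=_opt(r, "qvalue"),
                posterior=_opt(r, "posterior"),
                probe_id=_opt(r, "probe_id"),
            )
        )
    return out


def enhancer_associations_from_table(df: pd.DataFrame) -> list[EnhancerAssociation]:
    """Build EnhancerAssociations from a normalized TSV (columns enh_chrom,
    enh_start, enh_end, target, and any of score, rpkm, cell_line)."""
    def _opt(row, col):
        if col not in df.columns:
            return None
        v = getattr(row, col)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    out = []
    for r in df.itertuples():
        out.append(
            EnhancerAssociation(
                enhancer=GenomicInterval(
                    str(r.enh_chrom), int(r.enh_start), int(r.enh_end)
                ),
                target=str(r.target),
                score=_opt(r, "score"),
                rpkm=_opt(r, "rpkm"),
                cell_line=_opt(r, "cell_line"),
            )
        )
    return out
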