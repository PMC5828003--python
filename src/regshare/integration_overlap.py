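"""Gene-set integration, locus clustering, exclusive overlaps and the
randomization null for cross-phenotype SNP overlap.

A phenotype's germline-regulated gene set is the union of its target genes
over all evidence sources, with per-gene provenance.  Gene spans chain into
independent loci by single-linkage within 1 Mb (bedtools-cluster
semantics: overlapping intervals always co-cluster; the gap is measured
from the cluster's running max end to the next start).  Multi-set overlap
is reported as exclusive intersection cells (UpSet semantics), and the
significance of an observed cross-phenotype SNP overlap is assessed by
drawing size-matched random sets from an LD-pruned background pool.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .regulatory_map import RegulatoryHit


@dataclass
class GeneSet:
    """Per-phenotype germline-regulated genes with per-gene provenance."""

    phenotype: str
    genes: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.provenance) != self.genes:
            raise ValueError("provenance keys must equal the gene set")


def union_sources(
    hits: Iterable[RegulatoryHit], phenotype: str
) -> GeneSet:
    """Union of target genes over all sources, recording which sources
    contributed each gene (duplicates within a phenotype removed)."""
    genes: set[str] = set()
    provenance: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        genes.add(h.gene)
        provenance[h.gene].add(h.source)
    return GeneSet(phenotype=phenotype, genes=genes, provenance=dict(provenance))


def source_gene_sets(hits: Iterable[RegulatoryHit]) -> dict[str, set[str]]:
    """Genes per evidence source (for per-source overlap reports)."""
    out: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        out[h.source].add(h.gene)
    return dict(out)


@dataclass(frozen=True)
class Locus:
    """One independent locus: a maximal 1-Mb chain of gene spans."""

    chrom: str
    start: int
    end: int
    genes: frozenset[str]


@dataclass
class LocusClustering:
    clusters: list[Locus]
    distance_bp: int

    @property
    def n_loci(self) -> int:
        return len(self.clusters)


def cluster_loci(
    spans: Sequence[tuple[str, str, int, int]],
    distance_bp: int = 1_000_000,
) -> LocusClustering:
    """Chain gene spans into independent loci per chromosome.

    *spans* holds (gene, chrom, start, end) with unique gene names.
    Single-linkage: after sorting by start, a gene joins the current
    cluster iff the gap from the cluster's running max end to its start is
    <= *distance_bp* (overlap counts as gap 0); otherwise a new cluster
    starts.  Genes on different chromosomes never co-cluster.
    """
    names = [s[0] for s in spans]
    if len(set(names)) != len(names):
        raise ValueError("gene names in spans must be unique")
    by_chrom: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    for gene, chrom, start, end in spans:
        if start >= end:
            raise ValueError(f"{gene}: invalid span [{start}, {end})")
        by_chrom[chrom].append((gene, start, end))
    clusters: list[Locus] = []
    for chrom in sorted(by_chrom):
        members: list[str] = []
        cur_start = cur_end = None
        for gene, start, end in sorted(by_chrom[chrom], key=lambda t: (t[1], t[2])):
            if cur_end is not None and start - cur_end <= distance_bp:
                members.append(gene)
                cur_end = max(cur_end, end)
            else:
                if members:
                    clusters.append(
                        Locus(chrom, cur_start, cur_end, frozenset(members))
                    )
                members = [gene]
                cur_start, cur_end = start, end
        if members:
            clusters.append(Locus(chrom, cur_start, cur_end, frozenset(members)))
    return LocusClustering(clusters=clusters, distance_bp=distance_bp)


@dataclass
class OverlapReport:
    """Exclusive intersection cells over labeled sets (UpSet semantics).

    ``exclusive_cells[S]`` counts elements in every set of S and in no
    other set; the cells partition the union.
    """

    set_labels: list[str]
    exclusive_cells: dict[frozenset, int]
    exclusive_members: dict[frozenset, frozenset]
    union_size: int

    def cell(self, *labels: str) -> int:
        return self.exclusive_cells.get(frozenset(labels), 0)

    def members(self, *labels: str) -> frozenset:
        return self.exclusive_members.get(frozenset(labels), frozenset())

    def to_json_dict(self) -> dict:
        return {
            "set_labels": self.set_labels,
            "union_size": self.union_size,
            "exclusive_cells": {
                "&".join(sorted(k)): v for k, v in self.exclusive_cells.items()
            },
            "exclusive_members": {
                "&".join(sorted(k)): sorted(v)
                for k, v in self.exclusive_members.items()
            },
        }


def upset_counts(sets: Mapping[str, Iterable]) -> OverlapReport:
    """Exclusive intersection cells for >= 2 labeled sets."""
    labels = list(sets)
    if len(labels) < 2:
        raise ValueError("need at least 2 sets")
    frozen = {label: set(sets[label]) for label in labels}
    membership: dict = defaultdict(set)
    union: set = set()
    for label, s in frozen.items():
        union |= s
    for el in union:
        key = frozenset(l for l in labels if el in frozen[l])
        membership[key].add(el)
    from itertools import combinations

    cells: dict[frozenset, int] = {}
    members: dict[frozenset, frozenset] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            key = frozenset(combo)
            els = frozenset(membership.get(key, frozenset()))
            cells[key] = len(els)
            members[key] = els
    report = OverlapReport(
        set_labels=labels,
        exclusive_cells=cells,
        exclusive_members=members,
        union_size=len(union),
    )
    assert sum(cells.values()) == len(union)
    return report


@dataclass
class RandomizationResult:
    """Null distribution of the all-sets overlap under size-matched
    random draws from the background pool."""

    n_trials: int
    observed_overlap: int
    overlap_distribution: dict[int, int]
    empirical_p: float
    expected_overlap: float

    def __post_init__(self) -> None:
        if sum(self.overlap_distribution.values()) != self.n_trials:
            raise ValueError("overlap distribution frequencies must sum to n_trials")


def expected_overlap(set_sizes: Sequence[int], pool_size: int) -> float:
    """Analytic E[|∩ sets|] for independent uniform draws without
    replacement: sum over pool elements of prod_i (n_i / N)."""
    p = 1.0
    for n in set_sizes:
        p *= n / pool_size
    return pool_size * p


def randomization_test(
    set_sizes: Sequence[int],
    pool: Iterable[str],
    n_trials: int = 10_000,
    seed: int | None = None,
    observed_overlap: int = 0,
) -> RandomizationResult:
    """Resampling null for the overlap of size-matched SNP sets.

    Each trial draws one subset per size uniformly without replacement
    from the pool, independently across sets (the same SNP may land in
    several subsets), and records the size of the intersection of all
    subsets.  The empirical p-value for the observed overlap uses the
    (1 + k) / (1 + n_trials) correction; the raw frequency is available in
    ``overlap_distribution``.
    """
    pool = list(set(pool))
    n_pool = len(pool)
    if n_pool == 0:
        raise ValueError("empty background pool")
    set_sizes = [int(s) for s in set_sizes]
    for s in set_sizes:
        if s < 1 or s > n_pool:
            raise ValueError(f"set size {s} outside [1, {n_pool}]")
    rng = np.random.default_rng(seed)
    k = len(set_sizes)
    counts: Counter[int] = Counter()
    # vectorised path: rank a uniform matrix per set; the n smallest ranks
    # per row form a uniform subset without replacement
    max_cells = 20_000_000
    chunk = max(1, min(n_trials, max_cells // max(1, n_pool * k)))
    done = 0
    while done < n_trials:
        t = min(chunk, n_trials - done)
        inter = np.ones((t, n_pool), dtype=bool)
        for size in set_sizes:
            u = rng.random((t, n_pool))
            thresh = np.partition(u, size - 1, axis=1)[:, size - 1 : size]
            inter &= u <= thresh
        for v in inter.sum(axis=1):
            counts[int(v)] += 1
        done += t
    n_ge = sum(c for v, c in counts.items() if v >= observed_overlap)
    return RandomizationResult(
        n_trials=n_trials,
        observed_overlap=observed_overlap,
        overlap_distribution=dict(sorted(counts.items())),
        empirical_p=(1 + n_ge) / (n_trials + 1),
        expected_overlap=expected_overlap(set_sizes, n_pool),
    )
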