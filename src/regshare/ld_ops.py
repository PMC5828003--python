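"""Linkage-disequilibrium primitives on phased haplotype panels.

r² is computed on phased haplotype columns (not genotype dosages):
r² = D² / (p_a q_a p_b q_b) with D = p_ab − p_a p_b over haplotype
frequencies.  Two consumers sit on top of it:

* :func:`ld_expand` grows a list of tag SNPs into all panel variants in
  strong LD (r² above a threshold, default 0.8) within a physical window
  (default ±1 Mb) of each tag — the standard proxy-SNP expansion used to
  annotate GWAS signals beyond the genotyped marker itself.
* :func:`ld_prune` is a greedy sliding-window pruner in the style of
  PLINK ``--indep-pairwise``: within each window of consecutive variants,
  one member of every strongly linked pair (r² at or above a threshold,
  default 0.5) is removed until no violating pair remains, then the window
  slides forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import HaplotypePanel, SnpAssociation


class MonomorphicError(ValueError):
    """r² is undefined when either locus carries a single allele."""


@dataclass(frozen=True)
class LdParams:
    """Thresholds and window sizes for LD expansion and pruning.

    ``r2_expand``
        strict lower bound on r² for a variant to count as a proxy (default
        0.8; proxies satisfy r² > r2_expand).
    ``r2_prune``
        pruning threshold: pairs with r² >= r2_prune are considered strongly
        linked and one member is removed (default 0.5).
    ``window_bp``
        physical half-window for expansion, in bp on each side of the tag
        (default 1,000,000).
    ``prune_window_variants`` / ``prune_step_variants``
        sliding-window size and step, in variant counts, for pruning
        (defaults 50 / 5).
    """

    r2_expand: float = 0.8
    r2_prune: float = 0.5
    window_bp: int = 1_000_000
    prune_window_variants: int = 50
    prune_step_variants: int = 5

    def __post_init__(self) -> None:
        for name in ("r2_expand", "r2_prune"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.prune_window_variants < 2 or self.prune_step_variants < 1:
            raise ValueError("invalid pruning window/step")


@dataclass(frozen=True)
class LdPair:
    """One r² evaluation between two variants."""

    rsid_a: str
    rsid_b: str
    r2: float
    distance_bp: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 outside [0, 1]")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be >= 0")


def compute_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Squared haplotype correlation r² = D²/(p_a q_a p_b q_b).

    Both columns must be binary vectors of equal length (>= 2) and
    polymorphic; monomorphic input raises :class:`MonomorphicError`.
    The result is clipped to [0, 1] against floating-point error.
    """
    a = np.asarray(col_a, dtype=np.float64)
    b = np.asarray(col_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length haplotype vectors of size >= 2")
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicError("undefined r2 at monomorphic locus")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(min(max(r2, 0.0), 1.0))


def _r2_one_vs_many(matrix: np.ndarray, i: int, others: np.ndarray) -> np.ndarray:
    """Vectorised r² of column *i* against columns *others*.

    Monomorphic columns yield NaN (r² undefined) rather than raising.
    """
    n = matrix.shape[0]
    a = matrix[:, i].astype(np.float64)
    block = matrix[:, others].astype(np.float64)
    p_a = a.mean()
    p_b = block.mean(axis=0)
    p_ab = (a @ block) / n
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (p_ab - p_a * p_b) ** 2 / denom
    r2 = np.where(denom > 0, r2, np.nan)
    return np.clip(r2, 0.0, 1.0)


def partition_tags(
    tags: Iterable[SnpAssociation | str], panel: HaplotypePanel
) -> tuple[list[str], list[str]]:
    """Split tag rsids into (present-in-panel, absent-from-panel)."""
    present: list[str] = []
    absent: list[str] = []
    for tag in tags:
        rsid = tag if isinstance(tag, str) else tag.rsid
        (present if rsid in panel else absent).append(rsid)
    return present, absent


def ld_expand(
    tags: Sequence[SnpAssociation | str],
    panel: HaplotypePanel,
    params: LdParams | None = None,
) -> set[str]:
    """Expand tag SNPs to the union of their strong-LD proxies.

    For every tag present in the panel, all panel variants on the same
    chromosome within ``params.window_bp`` of the tag and with
    r²(tag, variant) > ``params.r2_expand`` are added; the tag itself is
    always included.  Tags absent from the panel are skipped (a chip/panel
    identifier mismatch is expected with real data); duplicates across tag
    sets are removed by the set union.
    """
    if params is None:
        params = LdParams()
    tags = list(tags)
    if not tags:
        raise ValueError("empty tag list")
    present, absent = partition_tags(tags, panel)
    if absent:
        import logging

        logging.getLogger("regshare").warning(
            "ld_expand: %d tag(s) absent from panel, skipped", len(absent)
        )
    chroms = panel.variants["chrom"].to_numpy()
    pos0 = panel.variants["pos0"].to_numpy()
    out: set[str] = set()
    rsids = np.asarray(panel.rsids, dtype=object)
    for rsid in present:
        i = panel.index_of(rsid)
        out.add(rsid)
        in_window = (chroms == chroms[i]) & (
            np.abs(pos0 - pos0[i]) <= params.window_bp
        )
        in_window[i] = False
        cand = np.flatnonzero(in_window)
        if cand.size == 0:
            continue
        r2 = _r2_one_vs_many(panel.matrix, i, cand)
        hit = cand[np.nan_to_num(r2, nan=-1.0) > params.r2_expand]
        out.update(rsids[hit])
    return out


def r2_matrix(matrix: np.ndarray, cols: Sequence[int]) -> np.ndarray:
    """Pairwise r² among the selected haplotype columns.

    Entries involving a monomorphic column are NaN; the diagonal is 1
    for polymorphic columns.
    """
    n = matrix.shape[0]
    block = matrix[:, list(cols)].astype(np.float64)
    p = block.mean(axis=0)
    joint = (block.T @ block) / n
    d = joint - np.outer(p, p)
    var = p * (1.0 - p)
    denom = np.outer(var, var)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = d * d / denom
    r2 = np.where(denom > 0, r2, np.nan)
    return np.clip(r2, 0.0, 1.0)


def ld_prune(
    snps: Iterable[str],
    panel: HaplotypePanel,
    params: LdParams | None = None,
) -> set[str]:
    """Greedy sliding-window LD pruning of an rsid list.

    Input order is ignored; variants are processed in panel coordinate
    order, per chromosome.  Within each window of
    ``params.prune_window_variants`` consecutive kept variants, while any
    pair has r² >= ``params.r2_prune``, the member with the smaller minor
    allele frequency is removed (tie: the one with the larger coordinate);
    the window then advances by ``params.prune_step_variants`` kept
    variants.  Monomorphic variants have undefined r² and are always kept.
    Returns the kept set.
    """
    if params is None:
        params = LdParams()
    idx = sorted({panel.index_of(r) for r in snps})
    if not idx:
        return set()
    maf = panel.maf()
    pos0 = panel.variants["pos0"].to_numpy()
    chroms = panel.variants["chrom"].to_numpy()
    kept_all: list[int] = []
    for chrom in sorted(set(chroms[idx])):
        chrom_idx = [i for i in idx if chroms[i] == chrom]
        local = {g: l for l, g in enumerate(chrom_idx)}
        r2 = r2_matrix(panel.matrix, chrom_idx)
        kept = list(chrom_idx)
        start = 0
        while start < len(kept):
            removed = True
            while removed:
                removed = False
                stop = min(start + params.prune_window_variants, len(kept))
                window = kept[start:stop]
                for x in range(len(window)):
                    for y in range(x + 1, len(window)):
                        i, j = window[x], window[y]
                        v = r2[local[i], local[j]]
                        if np.isnan(v) or v < params.r2_prune:
                            continue
                        # drop the worse-tagged member: smaller MAF,
                        # tie-break on larger coordinate
                        if maf[i] < maf[j] or (
                            maf[i] == maf[j] and pos0[i] > pos0[j]
                        ):
                            kept.remove(i)
                        else:
                            kept.remove(j)
                        removed = True
                        break
                    if removed:
                        break
            start += params.prune_step_variants
        kept_all.extend(kept)
    rsids = panel.rsids
    return {rsids[i] for i in kept_all}
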