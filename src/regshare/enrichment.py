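"""Hypergeometric over-representation test with Benjamini–Hochberg FDR.

For a query gene set of size n drawn from a background universe of size N,
and a pathway covering K background genes, the raw enrichment p-value is
the upper tail P(X >= k) of X ~ Hypergeometric(N, K, n) at the observed
overlap k (point mass included — the standard over-representation
convention).  Raw p-values across all tested pathways are adjusted with
the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import PathwayCollection


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's over-representation outcome."""

    pathway_id: str
    overlap_genes: frozenset[str]
    k_overlap: int
    n_query: int
    K_pathway: int
    N_background: int
    p_raw: float
    p_adjusted: float
    significant: bool = False

    def __post_init__(self) -> None:
        if self.k_overlap > min(self.n_query, self.K_pathway):
            raise ValueError("overlap exceeds query or pathway size")
        if not (0.0 < self.p_raw <= 1.0 and 0.0 < self.p_adjusted <= 1.0):
            raise ValueError("p-values must lie in (0, 1]")
        if self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")


def hypergeometric_test(
    query: Iterable[str],
    pathway: Iterable[str],
    background: Iterable[str],
) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for the query/pathway
    overlap against the background universe.

    The query must be a subset of the background; the pathway is first
    intersected with the background (genes outside the universe cannot be
    drawn).
    """
    query = set(query)
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    if not query:
        raise ValueError("empty query gene set")
    if not query <= background:
        raise ValueError(
            f"query has {len(query - background)} gene(s) outside the background"
        )
    eff_pathway = set(pathway) & background
    N = len(background)
    K = len(eff_pathway)
    n = len(query)
    k = len(query & eff_pathway)
    # survival function at k-1 gives P(X >= k), point mass included
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0) if k > 0 else 1.0


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} (p_(j) * m / j) over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adj]


def enrich_pathways(
    genes: Iterable[str],
    collection: PathwayCollection,
    background: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every pathway in the collection against one query gene set.

    Query genes outside the background are dropped (they cannot be drawn
    from the universe).  Adjustment spans ALL tested pathways; results are
    sorted by raw p, ties broken by pathway id, and flagged significant at
    p_adjusted <= alpha.
    """
    background = set(background)
    query = set(genes) & background
    if not query:
        raise ValueError("query gene set is empty after background restriction")
    pids = sorted(collection)
    raws = []
    metas = []
    for pid in pids:
        pw = set(collection[pid]) & background
        overlap = frozenset(query & pw)
        raws.append(hypergeometric_test(query, pw, background) if pw else 1.0)
        metas.append((pid, overlap, len(pw)))
    adj = bh_adjust(raws)
    results = [
        EnrichmentResult(
            pathway_id=pid,
            overlap_genes=overlap,
            k_overlap=len(overlap),
            n_query=len(query),
            K_pathway=K,
            N_background=len(background),
            p_raw=p,
            p_adjusted=a,
            significant=a <= alpha,
        )
        for (pid, overlap, K), p, a in zip(metas, raws, adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.pathway_id))
    return results
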