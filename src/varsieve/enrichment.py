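"""Gene-set over-representation analysis.

For a query of n genes drawn from an N-gene universe, a term containing K
universe genes, and k query genes inside the term, the enrichment p-value is
the upper-tail hypergeometric probability of seeing at least k hits:

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

The observed k is included in the tail (the >= k convention used by
over-representation tools).  P-values are adjusted by Benjamini–Hochberg
within each namespace separately — mirroring the practice of running the
three GO classes (BP / CC / MF) and KEGG as separate analyses — and results
are sorted by (q, p, term) for deterministic reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "hypergeom_p", "bh_adjust", "enrich", "results_frame"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation outcome.

    k: query genes in the term; K: universe genes in the term; n: query
    size; N: universe size; p: upper-tail hypergeometric probability;
    q: BH-adjusted value (within the term's namespace).
    """

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    namespace: str = "default"


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Exact and stable for universes up to at least 1e5 genes (computed in log
    space by scipy's survival function).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got k={k} K={K} n={n} N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k) for the discrete hypergeometric
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the p-sorted sequence, clipped
    to 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    namespaces: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Test every gene set for over-representation in the query.

    Query genes outside the universe are dropped with a warning; an empty
    query (before or after restriction) is an error.  Terms are restricted
    to the universe and skipped when no universe gene remains (K = 0).  BH
    adjustment runs within each namespace; ``namespaces`` maps term name to
    namespace and defaults to a single shared namespace.
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query = frozenset(query_genes)
    if not query:
        raise ValueError("query gene list is empty")
    dropped = query - universe_set
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe dropped: "
            f"{sorted(dropped)[:5]}{'…' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    query &= universe_set
    if not query:
        raise ValueError("no query gene is inside the universe")

    n, N = len(query), len(universe_set)
    partial: list[EnrichmentResult] = []
    for term in sorted(gene_sets):
        members = frozenset(gene_sets[term]) & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        ns = namespaces.get(term, "default") if namespaces else "default"
        partial.append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=N, p=hypergeom_p(k, K, n, N), q=np.nan, namespace=ns
            )
        )

    results: list[EnrichmentResult] = []
    for ns in sorted({r.namespace for r in partial}):
        group = [r for r in partial if r.namespace == ns]
        qs = bh_adjust([r.p for r in group])
        for r, q in zip(group, qs):
            results.append(EnrichmentResult(r.term, r.k, r.K, r.n, r.N, r.p, float(q), ns))
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "namespace": r.namespace,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ],
        columns=["term", "namespace", "k", "K", "n", "N", "p", "q"],
    )
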