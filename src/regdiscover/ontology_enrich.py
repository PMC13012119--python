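"""Over-representation analysis: one-sided hypergeometric test with
Benjamini-Hochberg FDR control.

Given a query gene set, term-to-gene annotations (GMT) and an explicit
background universe, each term is tested for over-representation of query
genes with the upper tail of the hypergeometric distribution,
``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)`` where N is the universe size,
K the term size after universe intersection, n the query size and k the
overlap.  Tail probabilities are accumulated in log space via log-gamma so
large universes neither overflow nor underflow.  The background universe is
a required argument: it is never defaulted silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = ["TermAnnotation", "EnrichmentTestResult", "hypergeom_upper_tail",
           "bh_adjust", "enrich_terms", "read_gmt", "top_terms",
           "write_results"]


@dataclass(frozen=True)
class TermAnnotation:
    term: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term!r} has an empty gene set")


@dataclass(frozen=True)
class EnrichmentTestResult:
    term: str
    name: str
    overlap_k: int
    term_size_K: int
    query_size_n: int
    universe_size_N: int
    p_value: float
    q_value: float


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``.

    Summed in log space over the support ``i = k .. min(K, n)``; exact to
    well below 1e-12 relative error for universes up to ~1e4.
    """
    if not 0 <= K <= N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_choose(K, i) + _log_choose(N - K, n - i) - _log_choose(N, n)
    return float(np.exp(logsumexp(log_terms)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def read_gmt(path) -> list[TermAnnotation]:
    """Read GMT: ``term<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    terms: list[TermAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, "
                                 "description and at least one gene")
            terms.append(TermAnnotation(parts[0], parts[1],
                                        frozenset(g for g in parts[2:] if g)))
    return terms


def enrich_terms(query, annotations: list[TermAnnotation], universe
                 ) -> list[EnrichmentTestResult]:
    """Test every annotation term against the query over the given universe.

    Annotations are intersected with the universe first; terms emptied by the
    intersection are dropped.  Results are sorted ascending by p-value, ties
    broken by term id, with BH q-values computed across the reported terms.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query")
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")

    N, n = len(universe), len(query)
    rows = []
    for ann in annotations:
        term_genes = ann.genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append((ann.term, ann.name, k, K, p))
    rows.sort(key=lambda r: (r[4], r[0]))
    q = bh_adjust([r[4] for r in rows]) if rows else []
    return [
        EnrichmentTestResult(term, name, k, K, n, N, p, float(qv))
        for (term, name, k, K, p), qv in zip(rows, q)
    ]


def top_terms(results: list[EnrichmentTestResult], n: int) -> list[EnrichmentTestResult]:
    """First ``n`` results by (p, term id) order — the 'top N' helper."""
    return results[:n]


def write_results(results: list[EnrichmentTestResult], path) -> None:
    pd.DataFrame([{
        "term": r.term, "name": r.name, "k": r.overlap_k, "K": r.term_size_K,
        "n": r.query_size_n, "N": r.universe_size_N,
        "p": f"{r.p_value:.6g}", "q": f"{r.q_value:.6g}",
    } for r in results]).to_csv(path, sep="\t", index=False)
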