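"""Hypergeometric term enrichment of hit gene sets against a background.

Given a query set of n genes out of a background of N (the screened strain
collection, by default 4691 genes), and a term annotating K background
genes of which k fall in the query, the enrichment P-value is the exact
upper tail P(X >= k) of the hypergeometric distribution.  Only terms with
k >= 1 are tested; the number of tested terms m is the multiple-testing
family size (Bonferroni by default, Benjamini–Hochberg available).

Results are reported in the "k/n, x.x% vs y.y%" style used for screen
write-ups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "hypergeom_tail",
    "enrich",
    "format_fraction",
]

DEFAULT_BACKGROUND_SIZE = 4691


@dataclass
class AnnotationTable:
    """Term -> gene-set mapping over a fixed background gene list.

    Annotated genes outside the background are dropped with a warning;
    empty terms are rejected.
    """

    terms: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        self.background = set(self.background)
        cleaned: dict[str, set[str]] = {}
        for term, genes in self.terms.items():
            genes = set(genes)
            if not genes:
                raise ValueError(f"term {term!r} annotates no genes")
            extra = genes - self.background
            if extra:
                warnings.warn(
                    f"term {term!r}: dropping {len(extra)} gene(s) outside the "
                    "background",
                    stacklevel=2,
                )
            cleaned[term] = genes & self.background
        self.terms = cleaned

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], background: Iterable[str]
    ) -> "AnnotationTable":
        """Build from (term, gene) rows, the two-column TSV layout."""
        terms: dict[str, set[str]] = {}
        for term, gene in pairs:
            terms.setdefault(term, set()).add(gene)
        return cls(terms=terms, background=set(background))


@dataclass
class EnrichmentResult:
    """One term's counts, percentages and raw/corrected P-values."""

    term: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_corrected: float

    @property
    def query_pct(self) -> float:
        return 100.0 * self.k / self.n

    @property
    def bg_pct(self) -> float:
        return 100.0 * self.K / self.N

    def describe(self) -> str:
        return (
            f"{format_fraction(self.k, self.n)} vs. {self.bg_pct:.1f}% "
            "in the background"
        )


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper tail P(X >= k) drawing n from N with K marked.

    k = 0 gives 1.0 (the whole support); K = N gives 1.0 (every draw is
    marked).  Bounds: 0 <= k <= n <= N and 0 <= K <= N, with k <= K.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"invalid hypergeometric parameters k={k} n={n} K={K} N={N}")
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    annotations: AnnotationTable,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Test every term with at least one query gene; sorted by corrected P.

    Query genes outside the background are dropped with a warning and n is
    adjusted.  ``correction`` is "bonferroni" (P_corr = min(1, m·P)) or
    "bh" (Benjamini–Hochberg).  Significance is P_corrected < alpha.
    """
    query = set(query)
    if not query:
        return []
    outside = query - annotations.background
    if outside:
        warnings.warn(
            f"dropping {len(outside)} query gene(s) outside the background",
            stacklevel=2,
        )
        query = query & annotations.background
    n = len(query)
    N = len(annotations.background)
    tested: list[tuple[str, int, int]] = []
    for term, genes in annotations.terms.items():
        k = len(query & genes)
        if k >= 1:
            tested.append((term, k, len(genes)))
    if not tested:
        return []
    p_raw = [hypergeom_tail(k, n, K, N) for _, k, K in tested]
    if correction == "bonferroni":
        p_corr = [min(1.0, len(tested) * p) for p in p_raw]
    elif correction == "bh":
        p_corr = list(multipletests(p_raw, method="fdr_bh")[1])
    else:
        raise ValueError(f"unknown correction {correction!r}")
    results = [
        EnrichmentResult(term=t, k=k, n=n, K=K, N=N, p_raw=pr, p_corrected=pc)
        for (t, k, K), pr, pc in zip(tested, p_raw, p_corr)
    ]
    results.sort(key=lambda r: (r.p_corrected, r.p_raw, r.term))
    return results


def results_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Flatten results for TSV output."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "query_pct": round(r.query_pct, 1),
                "bg_pct": round(r.bg_pct, 1),
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
            }
            for r in results
        ]
    )


def format_fraction(k: int, n: int) -> str:
    """Report style "k/n, p.p%" with the percentage to one decimal."""
    if n <= 0:
        raise ValueError("n must be > 0")
    return f"{k}/{n}, {100.0 * k / n:.1f}%"
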