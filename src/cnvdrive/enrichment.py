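"""Hypergeometric over-representation analysis against GMT gene sets.

For a query of n genes drawn from a universe of N genes, of which K belong
to a term, and an observed overlap of k, the enrichment p-value is the
upper-tail hypergeometric probability P(X >= k).  An optional EASE-style
variant (the overlap penalized by one gene, as popularized by web annotation
servers) is available behind a flag; the plain tail is the default.

The universe defaults, at the pipeline level, to the genes measured on the
expression platform rather than the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .formats_io import GeneSetCollection


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    description: str
    k: int  # overlap of query and term within the universe
    K: int  # term size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p_value: float
    q_value_bh: float
    significant: bool
    hits: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise DataError(f"term {self.term}: overlap exceeds margins")
        if not 0 < self.p_value <= 1:
            raise DataError(f"term {self.term}: p-value out of (0, 1]")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); k = 0 gives exactly 1."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise DataError(f"inconsistent hypergeometric margins k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Test every gene set for over-representation of the query.

    Symbols are upper-cased for matching; each set is intersected with the
    universe before testing.  Results are sorted ascending by p-value, with
    Benjamini-Hochberg q-values as an auxiliary column and a significance
    flag at ``p < alpha``.  ``ease=True`` removes one gene from the overlap
    before taking the tail (conservative, annotation-server style).
    """
    universe_set = {g.strip().upper() for g in universe}
    query_set = {g.strip().upper() for g in query}
    if not universe_set:
        raise DataError("empty universe")
    if not query_set:
        raise DataError("empty query")
    stray = query_set - universe_set
    if stray:
        raise DataError(
            f"query genes outside the universe: {', '.join(sorted(stray)[:5])}"
        )
    N, n = len(universe_set), len(query_set)
    rows = []
    for gs in gene_sets:
        members = gs.genes & universe_set
        hits = tuple(sorted(members & query_set))
        k, K = len(hits), len(members)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(k_eff, K, n, N)
        rows.append((gs, k, K, p, hits))
    q_values = multipletests([r[3] for r in rows], method="fdr_bh")[1] if rows else []
    results = [
        EnrichmentResult(
            term=gs.term,
            description=gs.description,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            q_value_bh=float(q),
            significant=p < alpha,
            hits=hits,
        )
        for (gs, k, K, p, hits), q in zip(rows, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
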