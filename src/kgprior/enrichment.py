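"""Over-representation analysis of predicted gene sets.

One-sided Fisher exact test of a query gene set against each set of a
collection, relative to an explicit background — for predicted disease
genes the natural background is every graph gene the relevant definition
did *not* link to the disease, i.e. the genes that could have been
predicted.  Multiple testing is controlled by Bonferroni by default
(Benjamini–Hochberg is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import GeneSetCollection
from .stats import hypergeom_tail

__all__ = ["EnrichmentResult", "overrepresentation_test", "rank_top"]


@dataclass
class EnrichmentResult:
    """One term's 2×2 over-representation outcome.

    ``k`` of the ``n_query`` query genes fall in the term, which covers ``K``
    of the ``N`` background genes; ``fold = (k/n_query)/(K/N)``.
    """

    term_id: str
    term_name: str
    k: int
    n_query: int
    K: int
    N: int
    fold: float
    p_raw: float
    p_adj: float
    significant: bool


def _bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvals[i] * m / rank)
        adj[i] = prev
    return adj


def overrepresentation_test(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """One-sided Fisher over-representation of the query in each term.

    The one-sided Fisher p equals the hypergeometric upper tail of the
    overlap, so all terms share the exact machinery used elsewhere.  Only
    terms with at least one background gene are tested, and ``m`` (the
    Bonferroni factor) counts exactly those terms.  Results are sorted by
    adjusted p, then descending fold, then term id.
    """
    query = {g.upper() for g in query_genes}
    bg = {g.upper() for g in background}
    stray = sorted(query - bg)
    if stray:
        raise ValueError(f"query genes missing from background: {stray}")
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    N, n = len(bg), len(query)

    tested = []
    for term_id in sorted(collection.sets):
        term_name, genes = collection.sets[term_id]
        term_bg = {g.upper() for g in genes} & bg
        if not term_bg:
            continue
        K = len(term_bg)
        k = len(term_bg & query)
        p = hypergeom_tail(k, K, n, N)
        fold = (k / n) / (K / N) if n else 0.0
        tested.append((term_id, term_name, k, K, p, fold))

    m = len(tested)
    raw = [t[4] for t in tested]
    if correction == "bonferroni":
        adj = [min(1.0, p * m) for p in raw]
    else:
        adj = _bh_adjust(raw)

    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=term_name,
            k=k,
            n_query=n,
            K=K,
            N=N,
            fold=fold,
            p_raw=p,
            p_adj=pa,
            significant=pa < alpha,
        )
        for (term_id, term_name, k, K, p, fold), pa in zip(tested, adj)
    ]
    results.sort(key=lambda r: (r.p_adj, -r.fold, r.term_id))
    return results


def rank_top(results: Sequence[EnrichmentResult], n: int = 20) -> list[EnrichmentResult]:
    """Significant results re-ranked by descending enrichment fold, top n.

    Ties resolve by adjusted p, then term id — the ranking used when
    reporting the most-enriched processes of a predicted gene set.
    """
    sig = [r for r in results if r.significant]
    sig.sort(key=lambda r: (-r.fold, r.p_adj, r.term_id))
    return sig[:n]
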