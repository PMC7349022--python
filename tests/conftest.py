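"""Shared fixtures and the independent hypergeometric enumeration oracle."""

from __future__ import annotations

import itertools
from fractions import Fraction

import pytest

from kgprior.graph import EdgeRecord, EdgeType, KnowledgeGraph, build_graph


def enumeration_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(at least k successes) by brute-force enumeration of all draws.

    Counts every size-n subset of an N-item population whose first K items
    are the successes.  Exact rational arithmetic, independent of any
    library distribution; only feasible for small N.
    """
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return Fraction(hits, total) if total else Fraction(1)


def enumeration_tail_table(K: int, n: int, N: int) -> list[Fraction]:
    """Tail P(X >= k) for every k in 0..min(K, n), from one enumeration pass."""
    kmax = min(K, n)
    counts = [0] * (kmax + 1)
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        counts[sum(1 for x in draw if x < K)] += 1
    tails = []
    running = total
    for k in range(kmax + 1):
        tails.append(Fraction(running, total))
        running -= counts[k]
    return tails


@pytest.fixture
def tiny_graph() -> KnowledgeGraph:
    """Two positives sharing one GO term and an interaction, plus bystanders."""
    edges = [
        EdgeRecord("gene:A", "go:GO:1", EdgeType.ANNOTATED_WITH),
        EdgeRecord("gene:B", "go:GO:1", EdgeType.ANNOTATED_WITH),
        EdgeRecord("gene:A", "gene:B", EdgeType.INTERACTS_WITH),
        EdgeRecord("gene:C", "go:GO:2", EdgeType.ANNOTATED_WITH),
        EdgeRecord("gene:D", "go:GO:2", EdgeType.ANNOTATED_WITH),
        EdgeRecord("gene:A", "disease:D1", EdgeType.ASSOCIATED_WITH),
        EdgeRecord("gene:B", "disease:D1", EdgeType.ASSOCIATED_WITH),
    ]
    return build_graph(edges)


@pytest.fixture
def planted_graph() -> tuple[KnowledgeGraph, list[str], str]:
    """Deterministic module graph: 10 positives share feature F; 50 noise terms.

    The planted annotation F is carried by every positive and no other gene
    (p_in = 1, p_out = 0); each of the 50 noise terms is carried by exactly
    two fixed background genes.
    """
    edges = []
    positives = [f"gene:P{i}" for i in range(10)]
    background = [f"gene:N{i:02d}" for i in range(40)]
    for p in positives:
        edges.append(EdgeRecord(p, "go:GO:PLANTED", EdgeType.ANNOTATED_WITH))
        edges.append(EdgeRecord(p, "disease:TARGET", EdgeType.ASSOCIATED_WITH))
    for j in range(50):
        for g in (background[j % 40], background[(j + 7) % 40]):
            edges.append(EdgeRecord(g, f"go:GO:NOISE{j:02d}", EdgeType.ANNOTATED_WITH))
    return build_graph(edges), positives, "disease:TARGET"
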