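"""Synthetic knowledge graphs with a planted, partially hidden disease module.

The generator emulates the statistical structure the prioritisation
pipeline assumes: a gene universe in which a planted set of disease genes
shares enriched neighbourhood features — annotation terms, interaction-hub
partners, and co-disease links — at a controllable strength (``p_in`` vs
``p_out``), on top of uniform background noise.  A fraction of the planted
genes is *hidden*: they carry the planted features but no association edge
to the target disease, exactly the situation link-deletion cross-validation
simulates, so hidden genes are recoverable ground truth for end-to-end
benchmarks.

:func:`write_fixture_suite` round-trips a generated graph through every
on-disk format the readers support (MITAB, GAF, DisGeNet-style TSV, gene
lists, MAGMA ``.genes.out``), coupling small GWAS p-values to the hidden
genes only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .graph import (
    DiseaseDefinition,
    EdgeRecord,
    EdgeType,
    KnowledgeGraph,
    annotation_node,
    build_graph,
    disease_node,
    gene_node,
)

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_kg", "write_fixture_suite"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-module graph generator.

    Defaults are the package's standard benchmark conditions: a 300-gene
    universe with a 30-gene planted module, one third hidden, eight planted
    features carried by planted genes with probability 0.9 and by background
    genes with probability 0.05, over 2% background noise density.
    """

    n_genes: int = 300
    n_annotations: int = 50
    n_other_diseases: int = 5
    n_planted: int = 30
    hidden_fraction: float = 1 / 3
    n_planted_features: int = 8
    p_in: float = 0.9
    p_out: float = 0.05
    background_density: float = 0.02
    seed: int = 0
    disease_id: str = "D0000001"

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError(f"need 0 <= p_out < p_in <= 1, got {self.p_out}, {self.p_in}")
        if not (0 <= self.hidden_fraction < 1):
            raise ValueError(f"hidden_fraction must be in [0,1), got {self.hidden_fraction}")
        if not (0 <= self.background_density <= 1):
            raise ValueError("background_density must be in [0,1]")
        for name in ("n_genes", "n_annotations", "n_other_diseases", "n_planted",
                     "n_planted_features"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted exceeds n_genes")

    @property
    def disease_node(self) -> str:
        return disease_node(self.disease_id)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated graph (gene node ids)."""

    disease: str
    planted_visible: frozenset[str]
    planted_hidden: frozenset[str]
    planted_features: tuple[str, ...]

    @property
    def planted(self) -> frozenset[str]:
        return self.planted_visible | self.planted_hidden

    def visible_definition(self, name: str = "synthetic") -> DiseaseDefinition:
        """The training gene list: planted genes whose disease link is visible."""
        genes = tuple(sorted(g.split(":", 1)[1] for g in self.planted_visible))
        return DiseaseDefinition(name=name, disease_node=self.disease, genes=genes)

    def full_definition(self, name: str = "synthetic-full") -> DiseaseDefinition:
        """All planted genes, hidden included.

        This is the list to cross-validate: in the real analysis the known
        gene list and the disease links in the graph coincide, and the
        link-deletion protocol itself creates the hidden genes fold by fold.
        """
        genes = tuple(sorted(g.split(":", 1)[1] for g in self.planted))
        return DiseaseDefinition(name=name, disease_node=self.disease, genes=genes)


def _gene(i: int) -> str:
    return gene_node(f"G{i:04d}")


def generate_kg(spec: SyntheticSpec) -> tuple[KnowledgeGraph, SyntheticTruth]:
    """Generate a planted-module knowledge graph; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    genes = [_gene(i) for i in range(spec.n_genes)]
    noise_ann = [annotation_node(f"GO:SYN{i:05d}") for i in range(spec.n_annotations)]
    other_dis = [disease_node(f"C{i:07d}") for i in range(spec.n_other_diseases)]

    planted_idx = rng.choice(spec.n_genes, size=spec.n_planted, replace=False)
    planted = [genes[i] for i in planted_idx]
    n_hidden = int(round(spec.hidden_fraction * spec.n_planted))
    hidden = set(planted[:n_hidden])
    visible = set(planted) - hidden
    planted_set = set(planted)

    # planted features cycle through the three edge relations: an enriched
    # annotation term, an interaction-hub gene, a co-associated disease
    hub_pool = [g for g in genes if g not in planted_set]
    features: list[tuple[str, EdgeType]] = []
    n_hubs = 0
    for i in range(spec.n_planted_features):
        kind = i % 3
        if kind == 0:
            features.append((annotation_node(f"GO:PLT{i:05d}"), EdgeType.ANNOTATED_WITH))
        elif kind == 1:
            features.append((hub_pool[n_hubs], EdgeType.INTERACTS_WITH))
            n_hubs += 1
        else:
            features.append((disease_node(f"CPLT{i:04d}"), EdgeType.ASSOCIATED_WITH))

    edges: dict[tuple[str, str, str], EdgeRecord] = {}

    def add(a: str, b: str, t: EdgeType) -> None:
        try:
            e = EdgeRecord(a, b, t, provenance="synthetic").normalized()
        except ValueError:
            return  # self-edge (a hub drawn against itself)
        edges.setdefault(e.key, e)

    # planted features: carried by planted genes w.p. p_in, others w.p. p_out
    for feat, t in features:
        draws = rng.random(spec.n_genes)
        for g, u in zip(genes, draws):
            p = spec.p_in if g in planted_set else spec.p_out
            if u < p and g != feat:
                add(g, feat, t)

    # background noise: annotations, interactions, other-disease associations
    for ann in noise_ann:
        draws = rng.random(spec.n_genes)
        for g, u in zip(genes, draws):
            if u < spec.background_density:
                add(g, ann, EdgeType.ANNOTATED_WITH)
    pair_draws = rng.random((spec.n_genes, spec.n_genes))
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            if pair_draws[i, j] < spec.background_density:
                add(genes[i], genes[j], EdgeType.INTERACTS_WITH)
    for dis in other_dis:
        draws = rng.random(spec.n_genes)
        for g, u in zip(genes, draws):
            if u < spec.background_density:
                add(g, dis, EdgeType.ASSOCIATED_WITH)

    # visible planted genes keep their link to the target disease
    for g in sorted(visible):
        add(g, spec.disease_node, EdgeType.ASSOCIATED_WITH)

    # every gene needs at least one edge so the universe survives format
    # round trips; park stragglers on a noise annotation term
    linked = {e.a for e in edges.values()} | {e.b for e in edges.values()}
    for i, g in enumerate(genes):
        if g not in linked:
            add(g, noise_ann[i % spec.n_annotations], EdgeType.ANNOTATED_WITH)

    graph = build_graph(edges.values())
    truth = SyntheticTruth(
        disease=spec.disease_node,
        planted_visible=frozenset(visible),
        planted_hidden=frozenset(hidden),
        planted_features=tuple(f for f, _ in features),
    )
    return graph, truth


def _sym(node_id: str) -> str:
    return node_id.split(":", 1)[1]


def write_fixture_suite(
    graph: KnowledgeGraph,
    truth: SyntheticTruth,
    out_dir: str | Path,
    seed: int = 0,
    hidden_p: float = 1e-8,
) -> dict[str, Path]:
    """Write the graph and ground truth as a full set of source-format files.

    Emits MITAB (+ interactor sidecar map), GAF, DisGeNet-style TSV, the
    visible gene list, a MAGMA ``.genes.out`` table (hidden planted genes at
    ``hidden_p``, background genes uniform above 0.05), and a JSON truth
    record.  Reading the first three back through the kg_io readers and
    :func:`~kgprior.graph.build_graph` reproduces the graph exactly;
    deterministic given ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mitab": out / "interactions.mitab",
        "mapping": out / "interactor_map.tsv",
        "gaf": out / "annotations.gaf",
        "disgenet": out / "associations.tsv",
        "gene_list": out / "genes_visible.txt",
        "magma": out / "gwas.genes.out",
        "truth": out / "truth.json",
    }

    inter, annot, assoc = [], [], []
    for e in sorted(graph.edges(), key=lambda e: e.key):
        if e.edge_type is EdgeType.INTERACTS_WITH:
            inter.append(e)
        elif e.edge_type is EdgeType.ANNOTATED_WITH:
            annot.append(e)
        else:
            assoc.append(e)

    def acc(gene_id: str) -> str:
        return f"uniprotkb:P-{_sym(gene_id)}"

    gene_ids = sorted(graph.gene_universe)
    with open(paths["mapping"], "w", encoding="utf-8") as fh:
        for g in gene_ids:
            fh.write(f"{acc(g)}\t{_sym(g)}\n")
    with open(paths["mitab"], "w", encoding="utf-8") as fh:
        filler = ["-"] * 13
        for e in inter:
            fh.write("\t".join([acc(e.a), acc(e.b), *filler]) + "\n")
    with open(paths["gaf"], "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for e in annot:
            go_id = _sym(e.b)
            row = ["SYN", _sym(e.a), _sym(e.a), "", go_id, "SYN:0001", "IEA", "", "P",
                   "", "", "protein", "taxon:9606", "20200101", "SYN", "", ""]
            fh.write("\t".join(row) + "\n")
    with open(paths["disgenet"], "w", encoding="utf-8") as fh:
        fh.write("geneSymbol\tdiseaseId\tscore\n")
        for e in assoc:
            fh.write(f"{_sym(e.a)}\t{_sym(e.b)}\t1.0\n")

    visible = sorted(_sym(g) for g in truth.planted_visible)
    with open(paths["gene_list"], "w", encoding="utf-8") as fh:
        fh.write("# synthetic visible disease genes\n")
        fh.write("\n".join(visible) + "\n")

    # MAGMA fixture: GWAS signal only at the hidden planted genes
    rng = np.random.default_rng(seed)
    hidden = sorted(_sym(g) for g in truth.planted_hidden)
    with open(paths["magma"], "w", encoding="utf-8") as fh:
        fh.write("GENE CHR START STOP NSNPS NPARAM N ZSTAT P\n")
        for i, g in enumerate(gene_ids):
            sym = _sym(g)
            p = hidden_p if sym in hidden else float(0.05 + 0.95 * rng.random())
            z = float(norm.isf(p))
            fh.write(
                f"{sym} 1 {1000 * (i + 1)} {1000 * (i + 1) + 900} 10 5 1000 "
                f"{z:.4f} {p:.6g}\n"
            )

    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "disease": truth.disease,
                "planted_visible": sorted(truth.planted_visible),
                "planted_hidden": sorted(truth.planted_hidden),
                "planted_features": list(truth.planted_features),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
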