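"""Readers and writers for the source formats feeding the knowledge graph.

Supported inputs:

* PSI-MITAB 2.5 protein–protein interaction tables (15+ tab-separated
  columns), with an explicit two-column interactor→gene-symbol sidecar table;
* GAF 2.x gene-function annotation files;
* DisGeNet-style disease–gene TSV (``geneSymbol``, ``diseaseId``, ``score``);
* plain-text gene lists (one symbol per line, ``#`` comments);
* GMT / two-column TSV gene-set collections;
* a generic graph dialect: TSV with columns ``a``, ``b``, ``edge_type``,
  ``provenance``.

All readers are idempotent (re-reading a file yields the same edge set) and
normalise gene symbols by a single upper-casing pass at load time.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .graph import (
    DiseaseDefinition,
    EdgeRecord,
    EdgeType,
    KnowledgeGraph,
    annotation_node,
    disease_node,
    gene_node,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_mapping_table",
    "read_mitab",
    "read_gaf",
    "read_disgenet",
    "collapse_disease_subtypes",
    "load_gene_list",
    "read_gene_sets",
    "GeneSetCollection",
    "write_graph_tsv",
    "read_graph_tsv",
]


class FormatError(ValueError):
    """A source file does not follow its declared format."""


def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping interactor identifiers to gene symbols."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"mapping row needs two columns: {line!r}")
            mapping[parts[0]] = parts[1].upper()
    return mapping


def read_mitab(
    path: str | Path,
    mapping: Mapping[str, str] | str | Path,
    strict: bool = True,
) -> list[EdgeRecord]:
    """Read a PSI-MITAB 2.5 file into ``interacts_with`` edge records.

    The interaction is placed between the genes encoding each interactor, via
    the explicit ``mapping`` (interactor id → gene symbol; a dict or a path to
    a two-column TSV).  Self-interactions are dropped, (A,B)/(B,A) duplicates
    collapse to one undirected edge, and interactors absent from the mapping
    are skipped with a logged count.

    In strict mode a row with fewer than 15 columns raises
    :class:`FormatError`; lenient mode skips it with a warning.
    """
    if not isinstance(mapping, Mapping):
        mapping = read_mapping_table(mapping)
    edges: dict[tuple[str, str, str], EdgeRecord] = {}
    n_unmapped = n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                msg = f"{path}:{lineno}: MITAB row has {len(cols)} columns (<15)"
                if strict:
                    raise FormatError(msg)
                logger.warning("%s; skipped", msg)
                continue
            ga, gb = mapping.get(cols[0]), mapping.get(cols[1])
            if ga is None or gb is None:
                n_unmapped += 1
                continue
            if ga == gb:
                n_self += 1
                continue
            e = EdgeRecord(
                gene_node(ga),
                gene_node(gb),
                EdgeType.INTERACTS_WITH,
                provenance=f"mitab:{Path(path).name}",
            ).normalized()
            edges.setdefault(e.key, e)
    if n_unmapped:
        logger.info("read_mitab: %d rows skipped (unmapped interactor)", n_unmapped)
    if n_self:
        logger.info("read_mitab: %d self-interactions dropped", n_self)
    return list(edges.values())


def read_gaf(path: str | Path) -> list[EdgeRecord]:
    """Read a GAF 2.x annotation file into ``annotated_with`` edge records.

    Column 3 is the gene symbol, column 4 the qualifier, column 5 the GO id.
    Rows whose qualifier contains ``NOT`` are excluded (they assert the
    absence of a function); comment lines (leading ``!``) are ignored, rows
    without a GO id are skipped with a warning, duplicates collapse.
    """
    edges: dict[tuple[str, str, str], EdgeRecord] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                logger.warning("%s:%d: GAF row has <5 columns; skipped", path, lineno)
                continue
            symbol, qualifier, go_id = cols[2], cols[3], cols[4]
            if not go_id:
                logger.warning("%s:%d: missing GO id; skipped", path, lineno)
                continue
            if "NOT" in qualifier.split("|"):
                continue
            aspect = cols[8] if len(cols) > 8 else ""
            e = EdgeRecord(
                gene_node(symbol),
                annotation_node(go_id),
                EdgeType.ANNOTATED_WITH,
                provenance=f"gaf:{aspect}" if aspect else "gaf",
            ).normalized()
            edges.setdefault(e.key, e)
    return list(edges.values())


_DISGENET_REQUIRED = ("geneSymbol", "diseaseId", "score")


def read_disgenet(
    path: str | Path,
    min_score: float = 0.0,
    subtype_map: Mapping[str, str] | None = None,
) -> list[EdgeRecord]:
    """Read a DisGeNet-style TSV into ``associated_with`` edge records.

    Rows with ``score < min_score`` are dropped (default keeps all), and
    disease identifiers are remapped through ``subtype_map`` *before*
    deduplication, so several subtype rows of one disease collapse to a
    single association edge.
    """
    edges: dict[tuple[str, str, str], EdgeRecord] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _DISGENET_REQUIRED if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for row in reader:
            if float(row["score"]) < min_score:
                continue
            did = row["diseaseId"]
            if subtype_map:
                did = subtype_map.get(did, did)
            e = EdgeRecord(
                gene_node(row["geneSymbol"]),
                disease_node(did),
                EdgeType.ASSOCIATED_WITH,
                provenance=f"disgenet:{Path(path).name}",
            ).normalized()
            edges.setdefault(e.key, e)
    return list(edges.values())


def collapse_disease_subtypes(
    edges: Iterable[EdgeRecord], subtype_map: Mapping[str, str]
) -> list[EdgeRecord]:
    """Re-point association edges from disease subtypes to canonical ids.

    Merging near-identical disease subtypes prevents those parallel links from
    making the learning task artificially easy.  The map is many-to-one over
    bare disease ids; mapping a disease onto a different subtype key (a chain)
    is a configuration error.  Non-disease edges pass through untouched.
    """
    for src, dst in subtype_map.items():
        if dst in subtype_map and subtype_map[dst] != dst:
            raise ValueError(f"subtype_map chains {src!r} -> {dst!r} -> {subtype_map[dst]!r}")
    out: dict[tuple[str, str, str], EdgeRecord] = {}
    for e in edges:
        e = e.normalized()
        if e.edge_type is EdgeType.ASSOCIATED_WITH:
            did = e.b.split(":", 1)[1]
            canonical = subtype_map.get(did, did)
            e = EdgeRecord(e.a, disease_node(canonical), e.edge_type, e.provenance)
        out.setdefault(e.key, e)
    return list(out.values())


def load_gene_list(
    path: str | Path,
    name: str | None = None,
    disease: str = "disease:ALS",
) -> DiseaseDefinition:
    """Load a one-symbol-per-line gene list as a disease definition.

    Lines starting with ``#`` are comments; an empty list is an error.
    """
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    if not genes:
        raise FormatError(f"{path}: gene list is empty")
    return DiseaseDefinition(
        name=name or Path(path).stem, disease_node=disease, genes=tuple(genes)
    )


@dataclass
class GeneSetCollection:
    """A named collection of gene sets, e.g. GO terms or disease gene sets."""

    name: str
    sets: dict[str, tuple[str, frozenset[str]]]  # term id -> (term name, genes)

    def __len__(self) -> int:
        return len(self.sets)


def read_gene_sets(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a gene-set collection from GMT or two-column TSV.

    GMT rows are ``term<TAB>description<TAB>gene...``; the two-column dialect
    is ``term<TAB>gene`` with one gene per row.  ``.gmt`` extension selects
    GMT, anything else the two-column dialect.  Symbols are upper-cased.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    if path.suffix.lower() == ".gmt":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                term, desc, genes = parts[0], parts[1], parts[2:]
                sets[term] = (desc or term, frozenset(g.upper() for g in genes if g))
    else:
        grouped: dict[str, set[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{path}: gene-set row needs two columns: {line!r}")
                grouped.setdefault(parts[0], set()).add(parts[1].upper())
        sets = {t: (t, frozenset(g)) for t, g in grouped.items()}
    sets = {t: v for t, v in sets.items() if v[1]}
    return GeneSetCollection(name=name or path.stem, sets=sets)


_GRAPH_COLUMNS = ("a", "b", "edge_type", "provenance")


def write_graph_tsv(graph: KnowledgeGraph, path: str | Path) -> None:
    """Write a graph in the generic edge-list dialect (deterministic order)."""
    rows = sorted(
        (e.a, e.b, e.edge_type.value, e.provenance) for e in graph.edges()
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_GRAPH_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_graph_tsv(path: str | Path) -> KnowledgeGraph:
    g = KnowledgeGraph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:3]) != _GRAPH_COLUMNS[:3]:
            raise FormatError(f"{path}: expected header {'	'.join(_GRAPH_COLUMNS)}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            prov = parts[3] if len(parts) > 3 else ""
            g.add_edge(EdgeRecord(parts[0], parts[1], EdgeType(parts[2]), prov))
    return g
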