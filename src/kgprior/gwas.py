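"""Validation of candidate gene sets against gene-based GWAS statistics.

The candidate-gene strategy: instead of the genome-wide multiple-testing
burden, a predicted gene set of effective size N is tested at the lenient
Bonferroni threshold 0.05/N against per-gene association p-values (MAGMA
``.genes.out`` tables).  Adjacent genes whose SNPs are in strong linkage
disequilibrium can be merged into a single locus (e.g. the ZFP91-CNTF
read-through transcript) so the signal is counted once.  A by-chance test
asks how surprising the number of validated candidates is, modelled as a
hypergeometric draw of the mapped candidates from all genes tested
genome-wide, with success = passing the same list-specific threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import FormatError
from .stats import hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = [
    "GwasGeneStat",
    "GwasValidationReport",
    "read_magma_genes",
    "read_merge_map",
    "merge_loci",
    "validate_candidates",
    "chance_significance",
]


@dataclass(frozen=True)
class GwasGeneStat:
    """Per-gene association statistic from a gene-based GWAS analysis."""

    gene: str
    p: float
    n_snps: int | None = None
    chrom: str | None = None
    start: int | None = None
    stop: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.gene}: p={self.p} outside (0, 1]")


@dataclass
class GwasValidationReport:
    """Candidate-list validation at the 0.05/N rule."""

    list_name: str
    n_predicted: int
    n_mapped: int
    threshold: float
    validated: list[tuple[str, float]]
    n_validated: int
    p_chance: float | None = None
    unmapped: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)


def read_magma_genes(path: str | Path) -> list[GwasGeneStat]:
    """Read a MAGMA ``.genes.out`` whitespace-delimited table.

    The header must include GENE and P; duplicate gene symbols are an error
    (each gene must carry exactly one statistic).
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if "GENE" not in df.columns or "P" not in df.columns:
        raise FormatError(f"{path}: header must include GENE and P columns")
    if df.empty:
        return []
    genes = df["GENE"].astype(str).str.upper()
    dups = sorted(genes[genes.duplicated()].unique())
    if dups:
        raise FormatError(f"{path}: duplicated GENE entries: {dups}")
    out = []
    for _, row in df.iterrows():
        out.append(
            GwasGeneStat(
                gene=str(row["GENE"]).upper(),
                p=float(row["P"]),
                n_snps=int(row["NSNPS"]) if "NSNPS" in df.columns else None,
                chrom=str(row["CHR"]) if "CHR" in df.columns else None,
                start=int(row["START"]) if "START" in df.columns else None,
                stop=int(row["STOP"]) if "STOP" in df.columns else None,
            )
        )
    return out


def read_merge_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: member gene -> merged locus name."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: merge-map row needs two columns: {line!r}")
            out[parts[0].upper()] = parts[1].upper()
    return out


def merge_loci(
    stats: Sequence[GwasGeneStat],
    candidates: Sequence[str],
    merge_map: Mapping[str, str],
) -> tuple[list[GwasGeneStat], list[str]]:
    """Replace member candidates by their merged locus, counted once.

    The merged locus takes its p-value from the stats record bearing the
    merged name; if no such record exists, the members are dropped from the
    mappable set with a warning.  Stats are returned unchanged — the merged
    record must already be present (the gene-based analysis is run on the
    merged annotation).
    """
    merge_map = {k.upper(): v.upper() for k, v in merge_map.items()}
    by_gene = {s.gene for s in stats}
    out: list[str] = []
    seen: set[str] = set()
    for c in candidates:
        c = c.upper()
        locus = merge_map.get(c, c)
        if locus != c and locus not in by_gene:
            logger.warning(
                "merge_loci: merged locus %s absent from stats; dropping member %s",
                locus,
                c,
            )
            continue
        if locus not in seen:
            seen.add(locus)
            out.append(locus)
    return list(stats), out


def validate_candidates(
    stats: Sequence[GwasGeneStat],
    candidates: Sequence[str],
    list_name: str = "",
    with_chance: bool = True,
) -> GwasValidationReport:
    """Test each mapped candidate at the list-specific 0.05/N threshold.

    N is the number of candidates effectively tested (present in the stats
    table after symbol matching); validation requires strictly p < 0.05/N.
    Validated genes are returned sorted by ascending p.  When
    ``with_chance`` is set, the by-chance probability of at least as many
    validated genes under a random draw of N candidates is attached.
    """
    by_gene = {s.gene: s.p for s in stats}
    cand_unique = list(dict.fromkeys(c.upper() for c in candidates))
    mapped = [c for c in cand_unique if c in by_gene]
    unmapped = [c for c in cand_unique if c not in by_gene]
    if unmapped:
        logger.info(
            "validate_candidates(%s): %d candidates not in the GWAS table",
            list_name,
            len(unmapped),
        )
    if not mapped:
        raise ValueError(f"{list_name}: no candidate maps to the GWAS gene table")
    threshold = 0.05 / len(mapped)
    validated = sorted(
        ((g, by_gene[g]) for g in mapped if by_gene[g] < threshold),
        key=lambda gp: (gp[1], gp[0]),
    )
    p_chance = None
    if with_chance:
        n_pass = sum(1 for p in by_gene.values() if p < threshold)
        p_chance = chance_significance(
            n_validated=len(validated),
            n_mapped=len(mapped),
            n_pass_genomewide=n_pass,
            n_total_genes=len(by_gene),
        )
    return GwasValidationReport(
        list_name=list_name,
        n_predicted=len(cand_unique),
        n_mapped=len(mapped),
        threshold=threshold,
        validated=validated,
        n_validated=len(validated),
        p_chance=p_chance,
        unmapped=unmapped,
    )


def chance_significance(
    n_validated: int, n_mapped: int, n_pass_genomewide: int, n_total_genes: int
) -> float:
    """How likely is the validation count under random candidate selection?

    Hypergeometric draw of ``n_mapped`` genes from the ``n_total_genes``
    tested genome-wide, where success means passing the candidate list's own
    0.05/N threshold (``n_pass_genomewide`` such genes exist); returns
    P(at least ``n_validated`` successes).
    """
    return hypergeom_tail(
        k=n_validated, K=n_pass_genomewide, n=n_mapped, N=n_total_genes
    )
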