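"""Packaged reference tables distributed with the package.

Two small published reference tables for the ALS gene-prioritisation
analysis, shipped verbatim as TSV with checksum verification:

* the 45 genes predicted by the model trained on the manually curated ALS
  list, with hg19 coordinates and membership/prediction flags for the other
  list definitions;
* the per-list GWAS validation summary (candidate counts, 0.05/N validated
  genes with their gene-based p-values, by-chance and gene-set p-values).

These are the only non-synthetic data in the repository.  A known internal
inconsistency of the source is preserved, not repaired: the ALSoD
membership column of the 45-gene table flags 11 genes, while its
accompanying text says 12.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "load_manual_predictions",
    "load_gwas_validation_reference",
    "parse_validated_genes",
]

_CHECKSUMS = {
    "manual_model_predictions.tsv": (
        "4d8693ec9d811f9fdee9089e1297ce3d0360363febcee7adfe5ad460ff932e3f"
    ),
    "gwas_validation_reference.tsv": (
        "247339be7e410d94c771bd1624f45575878763e01e8255d935769fc6a25b774c"
    ),
}

_FLAG_COLUMNS = (
    "clinvar_genes",
    "clinvar_predictions",
    "disgenet_genes",
    "disgenet_predictions",
    "alsod_genes",
    "alsod_predictions",
)


class PackagingError(RuntimeError):
    """A packaged data file fails its checksum."""


def _data_path(name: str) -> Path:
    path = resources.files("kgprior") / "data" / name
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise PackagingError(f"{name}: checksum mismatch ({digest})")
    return Path(str(path))


def load_manual_predictions() -> pd.DataFrame:
    """The 45-gene prediction table of the manually-curated-list model.

    One row per predicted gene: symbol, Ensembl gene/transcript ids, hg19
    coordinates of the longest transcript, strand, and six boolean columns
    stating membership in, or prediction by, the ClinVar / DisGeNet / ALSoD
    definitions.  A gene present in a list cannot also be predicted by that
    list's model.
    """
    df = pd.read_csv(_data_path("manual_model_predictions.tsv"), sep="\t")
    for col in _FLAG_COLUMNS:
        df[col] = df[col].map({"TRUE": True, "FALSE": False, True: True, False: False})
    return df


def load_gwas_validation_reference() -> pd.DataFrame:
    """Per-list GWAS candidate-validation summary.

    Columns: list name, by-chance p (and its value when the merged
    ZFP91-CNTF locus is not counted, where reported), predicted / mapped /
    validated gene counts, the validated genes with their gene-based
    p-values (``gene:p`` pairs, ``;``-separated), and the gene-set analysis
    p-value.
    """
    return pd.read_csv(_data_path("gwas_validation_reference.tsv"), sep="\t")


def parse_validated_genes(cell: str) -> list[tuple[str, float]]:
    """Parse a ``gene:p;gene:p`` cell of the validation reference table."""
    out = []
    for part in str(cell).split(";"):
        gene, _, p = part.strip().rpartition(":")
        out.append((gene, float(p)))
    return out
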