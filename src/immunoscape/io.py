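"""Plain-text readers/writers: expression TSV, GMT gene sets, clinical and MAF tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .signature_builder import GeneSignature

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_maf",
    "write_maf",
    "read_scores",
    "write_scores",
    "read_gene_list",
]

CLINICAL_COLUMNS = ["sample_id", "cancer_type", "age", "stage", "os_days", "os_event"]
MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Variant_Classification",
    "Protein_Change",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix from TSV (first column = gene IDs, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>gene...``."""
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            signatures.append(GeneSignature(name=name, genes=tuple(genes), description=desc))
    return signatures


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.description or "na", *sig.genes]) + "\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df.set_index("sample_id")


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


def read_maf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MAF_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    return df


def write_maf(mutations: pd.DataFrame, path: str | Path) -> None:
    mutations.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Samples x signatures score matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    return df


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
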