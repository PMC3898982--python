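"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and clinical tables travel as TSV, gene sets as GMT or
newline-delimited lists, probe-to-gene maps as two-column TSV.  Expression
readers tolerate GEO series-matrix style comment lines beginning with '!'.
"""
from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

#: float format used by every writer so that reruns are byte-identical
FLOAT_FMT = "%.10g"


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a features x samples TSV (first column = feature IDs).

    Lines starting with '!' (GEO series-matrix headers) are skipped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="!")
    df.index = df.index.astype(str)
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_gene_map(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV: feature_id <tab> gene_symbol. No header required."""
    df = pd.read_csv(path, sep="\t", header=None, comment="!", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("gene map must have two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_gene_map(gene_map: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for feat, gene in gene_map.items():
            fh.write(f"{feat}\t{gene}\n")


def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, ...]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..., one set per line."""
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = tuple(dict.fromkeys(g for g in parts[2:] if g))
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | os.PathLike,
              description: str = "ccpmeta") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gene_list(path: str | os.PathLike) -> tuple[str, ...]:
    """Newline-delimited gene symbols; blank lines and '#' comments ignored."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return tuple(dict.fromkeys(genes))


def read_clinical_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Clinical TSV with a sample_id column (index) and endpoint/covariates."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("clinical table needs a sample_id column")
    return df.set_index("sample_id")


def write_clinical_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FMT)


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    """Generic result-table writer with the package-wide float format."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
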