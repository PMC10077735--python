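"""Readers and writers for the pipeline's on-disk formats.

Counts travel as Matrix Market triplets (genes x cells) with ``genes.tsv``
and ``barcodes.tsv`` side files (10x-style layout); gene sets as GMT;
everything tabular as TSV.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import GeneExpressionMatrix


def _dedupe(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def read_counts(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    cell_meta_path: str | Path | None = None,
) -> GeneExpressionMatrix:
    """Load a genes x cells sparse count matrix with label side files.

    Matrix Market triplet indices are 1-based per the format convention;
    duplicate gene symbols are disambiguated by suffixing.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - reported with file name
        raise ValueError(f"cannot parse Matrix Market file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if mat.shape[0] != len(genes):
        raise ValueError(
            f"{genes_path}: {len(genes)} genes but matrix has {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has {mat.shape[1]} columns"
        )
    if len(set(genes)) != len(genes):
        warnings.warn("duplicate gene symbols disambiguated by suffixing")
        genes = _dedupe(genes)
    meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    if cell_meta_path is not None:
        meta = pd.read_csv(cell_meta_path, sep="\t", index_col=0)
        meta = meta.loc[barcodes]
    return GeneExpressionMatrix(mat, np.array(genes, dtype=object),
                                np.array(barcodes, dtype=object), meta)


def write_counts(
    gem: GeneExpressionMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(gem.counts), field="integer")
    pd.Series(gem.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(gem.cell_ids).to_csv(barcodes_path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: tab-separated lines of (set name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                warnings.warn(f"gene set {name!r} is empty; dropped")
                continue
            if len(set(members)) != len(members):
                warnings.warn(f"gene set {name!r} has duplicate members; deduplicated")
            sets[name] = set(members)
    return sets


def write_gmt(gene_sets: dict[str, set[str] | list[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *sorted(set(members))]) + "\n")


def read_regulator_list(path: str | Path) -> list[str]:
    """Plain-text regulator list, one symbol per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
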