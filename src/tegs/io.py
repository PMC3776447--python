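"""Readers and writers for the standard gene-set-analysis file formats.

GCT v1.2 (expression, genes as rows on disk; transposed to samples-as-rows
in memory), CLS (categorical two-class or ``#numeric`` dialect), GMT
(gene-set definitions), plus plain-TSV fallbacks and a result-table writer.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import (
    CovarianceMatrix,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    Phenotype,
)

logger = logging.getLogger("tegs")

__all__ = [
    "read_gct",
    "write_gct",
    "read_cls",
    "write_cls",
    "read_gmt",
    "write_gmt",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_phenotype_tsv",
    "align_and_filter",
    "write_results_tsv",
    "write_covariance_tsv",
    "read_covariance_tsv",
]

DEFAULT_MIN_SET_SIZE = 4


# ---------------------------------------------------------------------------
# GCT

def read_gct(path: str | Path) -> ExpressionMatrix:
    """Read a GCT v1.2 expression file (genes as rows) into samples-as-rows form."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GCT file")
    if lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: expected GCT version line '#1.2', got {lines[0]!r}")
    dims = lines[1].split()
    if len(dims) != 2:
        raise FormatError(f"{path}: malformed GCT dimension line {lines[1]!r}")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except ValueError:
        raise FormatError(f"{path}: non-integer GCT dimensions {lines[1]!r}") from None
    header = lines[2].split("\t")
    if len(header) != n_samples + 2:
        raise FormatError(
            f"{path}: header declares {len(header) - 2} samples, expected {n_samples}"
        )
    sample_ids = header[2:]
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_genes:
        raise FormatError(f"{path}: body has {len(body)} genes, header declares {n_genes}")
    gene_ids: list[str] = []
    values = np.empty((n_genes, n_samples), dtype=float)
    for i, ln in enumerate(body):
        fields = ln.split("\t")
        if len(fields) != n_samples + 2:
            raise FormatError(f"{path}: line {i + 4} has {len(fields) - 2} values, expected {n_samples}")
        gene_ids.append(fields[0])
        for j, tok in enumerate(fields[2:]):
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {tok!r} at row {i + 4}, column {j + 3}"
                ) from None
    if len(set(gene_ids)) != n_genes:
        raise FormatError(f"{path}: duplicate gene ids")
    return ExpressionMatrix(values.T, gene_ids, sample_ids)


def write_gct(expr: ExpressionMatrix, path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(expr.sample_ids) + "\n")
        for j, gene in enumerate(expr.gene_ids):
            desc = descriptions.get(gene, "na")
            row = "\t".join(repr(float(v)) for v in expr.values[:, j])
            fh.write(f"{gene}\t{desc}\t{row}\n")


# ---------------------------------------------------------------------------
# CLS

def read_cls(path: str | Path) -> Phenotype:
    """Read a CLS phenotype file (two-class categorical, or '#numeric')."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty CLS file")
    if lines[0].startswith("#numeric"):
        if len(lines) < 3:
            raise FormatError(f"{path}: truncated numeric CLS file")
        try:
            x = np.array([float(t) for t in lines[2].split()])
        except ValueError:
            raise FormatError(f"{path}: non-numeric value in numeric CLS body") from None
        return Phenotype(x, kind="numeric")
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated CLS file")
    head = lines[0].split()
    if len(head) != 3:
        raise FormatError(f"{path}: malformed CLS header {lines[0]!r}")
    n, k = int(head[0]), int(head[1])
    if k != 2:
        raise FormatError(f"{path}: {k}-class CLS files are not supported (need 2 classes)")
    tokens = lines[2].split()
    if len(tokens) != n:
        raise FormatError(f"{path}: header declares {n} samples but body has {len(tokens)} tokens")
    # first-listed class maps to 0, the second to 1
    order: list[str] = []
    for t in tokens:
        if t not in order:
            order.append(t)
    if len(order) != 2:
        raise FormatError(f"{path}: body has {len(order)} distinct classes, expected 2")
    x = np.array([float(order.index(t)) for t in tokens])
    return Phenotype(x, kind="binary")


def write_cls(pheno: Phenotype, path: str | Path, labels: tuple[str, str] = ("CTL", "CASE")) -> None:
    with open(path, "w") as fh:
        if pheno.kind == "numeric":
            fh.write("#numeric\n#score\n")
            fh.write(" ".join(repr(float(v)) for v in pheno.x) + "\n")
        else:
            fh.write(f"{pheno.n} 2 1\n")
            fh.write(f"# {labels[0]} {labels[1]}\n")
            fh.write(" ".join(labels[int(v)] for v in pheno.x) + "\n")


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, then gene ids)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}: line {lineno} redefines gene set {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            dups = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                logger.warning("gene set %s: dropped %d duplicate gene ids", name, dups)
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets:
            desc = sets.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# TSV fallbacks

def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a plain TSV expression table: rows samples, columns genes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns], [str(i) for i in df.index])


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.gene_ids).to_csv(path, sep="\t")


def read_phenotype_tsv(path: str | Path, kind: str | None = None) -> Phenotype:
    """Read a phenotype TSV: either one value per line or sample<TAB>value rows."""
    df = pd.read_csv(path, sep="\t", header=None)
    x = df.iloc[:, -1].to_numpy(dtype=float)
    if kind is None:
        kind = "binary" if np.all(np.isin(x, (0.0, 1.0))) else "numeric"
    return Phenotype(x, kind=kind)


# ---------------------------------------------------------------------------
# Alignment / filtering

def align_and_filter(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> tuple[GeneSetCollection, dict[str, int]]:
    """Restrict each set to genes present in ``expr`` and drop small sets.

    Returns the filtered collection and a report mapping removed set names
    to their post-alignment sizes. Sets below ``min_set_size`` present genes
    are removed (the default of 4 mirrors the usual exclusion of tiny sets).
    """
    present = set(expr.gene_ids)
    kept: dict[str, list[str]] = {}
    removed: dict[str, int] = {}
    n_dropped_genes = 0
    for name, genes in sets:
        matched = [g for g in genes if g in present]
        n_dropped_genes += len(genes) - len(matched)
        if len(matched) >= min_set_size:
            kept[name] = matched
        else:
            removed[name] = len(matched)
    if n_dropped_genes:
        logger.info("align_and_filter: dropped %d set genes absent from the matrix", n_dropped_genes)
    if not kept:
        logger.warning("align_and_filter: no gene sets remain after filtering")
    descriptions = {k: v for k, v in sets.descriptions.items() if k in kept}
    return GeneSetCollection(kept, descriptions), removed


# ---------------------------------------------------------------------------
# Results and covariance audit dumps

RESULT_COLUMNS = ["set", "p_genes", "Q", "p_perm", "p_satt", "p_mix", "kappa", "nu", "q_value"]


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    results.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_covariance_tsv(cov: CovarianceMatrix, gene_ids: list[str], path: str | Path) -> None:
    pd.DataFrame(cov.matrix, index=gene_ids, columns=gene_ids).to_csv(path, sep="\t")


def read_covariance_tsv(path: str | Path, kind: str = "supplied") -> CovarianceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CovarianceMatrix(df.to_numpy(dtype=float), kind=kind)
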