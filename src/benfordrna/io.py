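"""Readers and writers for expression matrices and annotation tables.

Two matrix layouts are supported:

* dense delimited text — first column gene ids, header row sample ids;
  tab- or comma-separated, auto-detected from the ``.tsv``/``.csv``
  extension;
* MatrixMarket sparse triplets (``.mtx``, genes in rows) with sidecar
  identifier files — one id per line — following the Drop-seq single-cell
  distribution convention. Sidecars default to ``<stem>.genes.txt`` and
  ``<stem>.samples.txt`` next to the matrix.

Annotation tables are plain two-column TSVs: gene id + category for labels,
gene id + length in base pairs for gene lengths.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .expression import ExpressionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_lengths",
]


def _sidecar_paths(mtx_path: Path, gene_file, sample_file) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    genes = Path(gene_file) if gene_file else stem.with_suffix(".genes.txt")
    samples = Path(sample_file) if sample_file else stem.with_suffix(".samples.txt")
    return genes, samples


def _read_ids(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"identifier sidecar not found: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def read_matrix(
    path,
    metric: str = "raw",
    fmt: str | None = None,
    gene_file=None,
    sample_file=None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or MatrixMarket format.

    ``fmt`` (one of ``tsv``, ``csv``, ``mtx``) overrides extension-based
    detection. ``metric`` tags what the stored values are (raw counts, CPM,
    RPKM, TPM or log2); the file itself carries no metric information.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        genes_path, samples_path = _sidecar_paths(path, gene_file, sample_file)
        matrix = spio.mmread(path)
        if sparse.issparse(matrix):
            matrix = matrix.toarray()
        genes = _read_ids(genes_path)
        samples = _read_ids(samples_path)
        return ExpressionMatrix(
            values=np.asarray(matrix, dtype=float),
            gene_ids=tuple(genes),
            sample_ids=tuple(samples),
            metric=metric,
        )
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # surface file context with the parser error
            raise ValueError(f"malformed matrix file {path}: {exc}") from exc
        return ExpressionMatrix.from_dataframe(frame, metric=metric)
    raise ValueError(f"unsupported matrix format {fmt!r} (use tsv, csv or mtx)")


def write_matrix(m: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write a matrix as TSV/CSV (dense) or MatrixMarket + id sidecars."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        genes_path, samples_path = _sidecar_paths(path, None, None)
        spio.mmwrite(path, sparse.coo_matrix(m.values))
        genes_path.write_text("".join(f"{g}\n" for g in m.gene_ids))
        samples_path.write_text("".join(f"{s}\n" for s in m.sample_ids))
        return
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        m.to_dataframe().to_csv(path, sep=sep, index_label="gene_id")
        return
    raise ValueError(f"unsupported matrix format {fmt!r} (use tsv, csv or mtx)")


def read_labels(path) -> dict[str, str]:
    """Read a two-column (gene id, category) TSV into a mapping."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"])
    labels = dict(zip(frame["gene_id"].astype(str), frame["category"].astype(str)))
    if len(labels) != len(frame):
        raise ValueError(f"duplicate gene ids in label file {path}")
    return labels


def write_labels(labels: Mapping[str, str], path) -> None:
    with open(path, "w") as handle:
        for gene, category in labels.items():
            handle.write(f"{gene}\t{category}\n")


def read_lengths(path) -> dict[str, int]:
    """Read a two-column (gene id, length in bp) TSV into a mapping."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"])
    lengths = dict(zip(frame["gene_id"].astype(str), frame["length"].astype(int)))
    if len(lengths) != len(frame):
        raise ValueError(f"duplicate gene ids in length file {path}")
    return lengths
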