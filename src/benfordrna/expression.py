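"""Expression-matrix container and normalisation metrics.

Holds gene x sample non-negative expression values together with identifier
lists and a metric tag, and implements the standard per-sample normalisations:

* CPM  — counts per million mapped reads,
* RPKM — reads per kilobase of transcript per million mapped reads,
* TPM  — transcripts per million (length-rate renormalised to 1e6/sample),
* log2 — log2(value + offset), which destroys the lognormal structure that
  Benford conformity depends on; scored matrices therefore carry a metric
  tag so digit-based scoring can refuse log-scale input outright.

Also provides the expressed-gene filter: keep genes whose mean CPM across
all samples lies in the top fraction (default 40%) of per-gene means —
unexpressed genes inherently deviate from Benford's law and must be removed
before ranking genes by conformity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "METRICS",
    "ExpressionMatrix",
    "cpm",
    "rpkm",
    "tpm",
    "log2_transform",
    "expressed_gene_filter",
]

METRICS = ("raw", "cpm", "rpkm", "tpm", "log2")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A gene x sample matrix of non-negative expression values.

    Parameters
    ----------
    values
        2-D float array, genes in rows, samples in columns.
    gene_ids, sample_ids
        Ordered unique identifiers matching the matrix dimensions.
    metric
        One of ``raw``, ``cpm``, ``rpkm``, ``tpm``, ``log2``. Only the
        ``log2`` metric may contain values below zero (log of sub-unity
        offsets); every other metric must be non-negative throughout.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    metric: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        if v.ndim != 2:
            raise ValueError("expression values must be a 2-D gene x sample grid")
        if v.shape != (len(genes), len(samples)):
            raise ValueError(
                f"value grid {v.shape} does not match {len(genes)} genes x "
                f"{len(samples)} samples"
            )
        if len(set(genes)) != len(genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(samples)) != len(samples):
            raise ValueError("sample identifiers must be unique")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must be finite")
        if self.metric != "log2" and np.any(v < 0):
            raise ValueError("expression values must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, metric: str = "raw") -> "ExpressionMatrix":
        """Build from a genes-in-rows DataFrame (index = gene ids)."""
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=tuple(map(str, frame.index)),
            sample_ids=tuple(map(str, frame.columns)),
            metric=metric,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to the given genes, preserving their requested order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[str(g)] for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not present in matrix") from None
        return ExpressionMatrix(
            values=self.values[rows, :],
            gene_ids=tuple(str(g) for g in gene_ids),
            sample_ids=self.sample_ids,
            metric=self.metric,
        )


def _library_sizes(m: ExpressionMatrix) -> np.ndarray:
    totals = m.values.sum(axis=0)
    empty = np.flatnonzero(totals <= 0)
    if empty.size:
        names = ", ".join(m.sample_ids[i] for i in empty[:5])
        raise ValueError(f"sample(s) with zero library size: {names}")
    return totals


def _check_lengths(m: ExpressionMatrix, lengths: Mapping[str, float]) -> np.ndarray:
    out = np.empty(m.n_genes, dtype=float)
    for i, g in enumerate(m.gene_ids):
        if g not in lengths:
            raise KeyError(f"no length for gene {g!r}")
        length = float(lengths[g])
        if not length > 0:
            raise ValueError(f"non-positive length for gene {g!r}: {length}")
        out[i] = length
    return out


def cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: value / library size x 1e6, per sample."""
    if m.metric != "raw":
        raise ValueError(f"cpm expects raw counts, got metric {m.metric!r}")
    totals = _library_sizes(m)
    return replace(m, values=m.values / totals * 1e6, metric="cpm")


def rpkm(m: ExpressionMatrix, lengths: Mapping[str, float]) -> ExpressionMatrix:
    """Reads per kilobase per million: value x 1e9 / (length x library size)."""
    if m.metric != "raw":
        raise ValueError(f"rpkm expects raw counts, got metric {m.metric!r}")
    totals = _library_sizes(m)
    bp = _check_lengths(m, lengths)
    values = m.values * 1e9 / (bp[:, None] * totals[None, :])
    return replace(m, values=values, metric="rpkm")


def tpm(m: ExpressionMatrix, lengths: Mapping[str, float]) -> ExpressionMatrix:
    """Transcripts per million: per-kilobase rates renormalised to 1e6/sample."""
    if m.metric != "raw":
        raise ValueError(f"tpm expects raw counts, got metric {m.metric!r}")
    _library_sizes(m)  # reject zero-library samples with a named error
    bp = _check_lengths(m, lengths)
    rates = m.values / bp[:, None]
    rate_totals = rates.sum(axis=0)
    empty = np.flatnonzero(rate_totals <= 0)
    if empty.size:
        names = ", ".join(m.sample_ids[i] for i in empty[:5])
        raise ValueError(f"sample(s) with zero length-rate total: {names}")
    return replace(m, values=rates / rate_totals * 1e6, metric="tpm")


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset); tags the result so scoring can refuse it.

    Log transformation removes the lognormal spread across orders of
    magnitude that underlies Benford adherence, so any matrix tagged
    ``log2`` is rejected by the digit-scoring operations.
    """
    if m.metric == "log2":
        raise ValueError("matrix is already log2-transformed")
    if not offset > 0:
        raise ValueError(f"offset must be positive, got {offset}")
    return replace(m, values=np.log2(m.values + offset), metric="log2")


def expressed_gene_filter(
    m: ExpressionMatrix, top_fraction: float = 0.4
) -> list[str]:
    """Genes whose mean CPM across all samples is in the top fraction.

    The threshold is the k-th largest per-gene mean with
    ``k = ceil(top_fraction * n_genes)``; genes whose mean equals the
    threshold are all included, so ties at the boundary can return more than
    ``k`` genes. Returns gene ids in matrix order.
    """
    if m.metric != "cpm":
        raise ValueError(
            f"expressed-gene filter is defined on CPM values, got {m.metric!r}"
        )
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if m.n_genes == 0 or m.n_samples == 0:
        raise ValueError("cannot filter an empty matrix")
    means = m.values.mean(axis=1)
    k = int(np.ceil(top_fraction * m.n_genes))
    threshold = np.sort(means)[::-1][k - 1]
    keep = means >= threshold
    return [g for g, ok in zip(m.gene_ids, keep) if ok]
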