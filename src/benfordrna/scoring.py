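"""Per-gene and per-sample Benford conformity scoring.

Two calculation modes, mirroring how a conformity score can be attached to
either axis of an expression matrix:

* gene-centric — one MAE per gene, from the digit distribution of that
  gene's values across all samples (or cells). Meaningful when there are
  enough samples for a single gene to exhibit a digit distribution at all;
  roughly a thousand samples is recommended before per-gene scores become
  stable.
* individual-centric — one MAE per (sample, gene category) pair, pooling a
  category's values within a single sample. Works with few samples because
  each pool spans hundreds of genes.

Also ranking (top/bottom conformers) and threshold-based gene selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .benford import (
    BenfordReference,
    expected_frequencies,
    first_significant_digits,
)
from .expression import ExpressionMatrix

__all__ = [
    "MAETable",
    "gene_centric_mae",
    "individual_centric_mae",
    "rank_and_select",
    "threshold_select",
    "write_mae_table",
    "read_mae_table",
]

FREQ_COLUMNS = [f"d{d}" for d in range(1, 10)]

# Per-gene digit counts below this are flagged as noisy: the MAE of a digit
# distribution estimated from a handful of values is dominated by sampling
# error, and per-gene Benford analysis is recommended at ~1000 samples.
SMALL_SAMPLE_WARNING = 50


def _reject_log2(m: ExpressionMatrix) -> None:
    if m.metric == "log2":
        raise ValueError(
            "Benford scoring is undefined on log2-transformed values: the log "
            "transform removes the spread across orders of magnitude that the "
            "first-digit law reflects. Score the untransformed matrix instead."
        )


def _digit_codes(values: np.ndarray, exclude_below_one: bool) -> np.ndarray:
    """First-digit codes for a 2-D grid; excluded cells are coded 0."""
    usable = values > 0
    if exclude_below_one:
        usable &= values >= 1
    codes = np.zeros(values.shape, dtype=np.int64)
    if usable.any():
        codes[usable] = first_significant_digits(values[usable])
    return codes


def _digit_counts_by_row(codes: np.ndarray) -> np.ndarray:
    """Rows x 9 digit counts from a grid of digit codes (0 = excluded)."""
    counts = np.empty((codes.shape[0], 9), dtype=np.int64)
    for d in range(1, 10):
        counts[:, d - 1] = (codes == d).sum(axis=1)
    return counts


@dataclass(frozen=True)
class MAETable:
    """Conformity scores with their underlying digit frequencies.

    ``table`` holds one row per gene (gene-centric) or per (sample, category)
    pair (individual-centric) with the MAE, the number of values that
    contributed a digit (``n_used``), and the nine observed digit
    frequencies ``d1..d9``. Gene-centric tables also carry the per-gene mean
    expression on the scored matrix's metric scale, plus a log2(CPM+1)-style
    convenience column when the caller provides one. Rows with no usable
    values appear with NaN frequencies and ``defined == False`` in the
    individual-centric mode and are omitted (and listed) in the gene-centric
    mode.
    """

    mode: str
    table: pd.DataFrame
    omitted: tuple[str, ...] = ()
    metric: str = "raw"

    def __post_init__(self) -> None:
        if self.mode not in ("gene_centric", "individual_centric"):
            raise ValueError(f"unknown MAE table mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.table)


def gene_centric_mae(
    m: ExpressionMatrix,
    exclude_below_one: bool = False,
    min_used: int = 1,
    reference: BenfordReference | None = None,
) -> MAETable:
    """One MAE per gene, across that gene's values over all samples.

    Genes with fewer than ``min_used`` usable (non-excluded) values are
    omitted from the table and recorded in ``MAETable.omitted``; with the
    default ``min_used=1`` only genes with no digits at all are dropped,
    matching a workflow that filters genes by expression level rather than
    by digit count. A warning is emitted when scored genes rest on fewer
    than 50 digits, since such MAE estimates are noisy.
    """
    _reject_log2(m)
    if m.n_samples < 1:
        raise ValueError("gene-centric scoring needs at least one sample")
    if min_used < 1:
        raise ValueError(f"min_used must be >= 1, got {min_used}")
    if reference is None:
        reference = expected_frequencies()

    codes = _digit_codes(m.values, exclude_below_one)
    counts = _digit_counts_by_row(codes)
    n_used = counts.sum(axis=1)
    keep = n_used >= min_used
    omitted = tuple(g for g, ok in zip(m.gene_ids, keep) if not ok)

    with np.errstate(invalid="ignore"):
        freqs = counts[keep] / n_used[keep, None]
    maes = np.abs(freqs - reference.probabilities).mean(axis=1)
    if np.any(n_used[keep] < SMALL_SAMPLE_WARNING):
        warnings.warn(
            f"{int((n_used[keep] < SMALL_SAMPLE_WARNING).sum())} gene(s) scored "
            f"on fewer than {SMALL_SAMPLE_WARNING} digits; per-gene MAE is "
            "noisy at small sample counts",
            stacklevel=2,
        )

    table = pd.DataFrame(
        {
            "gene_id": [g for g, ok in zip(m.gene_ids, keep) if ok],
            "mae": maes,
            "n_used": n_used[keep],
            "mean_expression": m.values[keep].mean(axis=1),
        }
    )
    table[FREQ_COLUMNS] = freqs
    return MAETable(mode="gene_centric", table=table, omitted=omitted, metric=m.metric)


def individual_centric_mae(
    m: ExpressionMatrix,
    labels: Mapping[str, str],
    exclude_below_one: bool = False,
    reference: BenfordReference | None = None,
) -> MAETable:
    """One MAE per (sample, category), pooling the category within the sample.

    Every category must overlap the matrix's genes. A category with zero
    usable values in some sample yields a row flagged ``defined == False``
    with NaN score rather than being dropped silently.
    """
    _reject_log2(m)
    if reference is None:
        reference = expected_frequencies()
    categories = sorted(set(labels.values()))
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    members = {
        c: [gene_index[g] for g, cat in labels.items() if cat == c and g in gene_index]
        for c in categories
    }
    empty = [c for c, rows in members.items() if not rows]
    if empty:
        raise ValueError(
            f"categories with no genes in the matrix: {', '.join(empty)}"
        )

    records = []
    for category in categories:
        sub = m.values[members[category], :]
        codes = _digit_codes(sub, exclude_below_one)
        counts = _digit_counts_by_row(codes.T)  # samples x 9
        n_used = counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            freqs = np.where(n_used[:, None] > 0, counts / n_used[:, None], np.nan)
        maes = np.abs(freqs - reference.probabilities).mean(axis=1)
        for j, sample in enumerate(m.sample_ids):
            records.append(
                {
                    "sample_id": sample,
                    "category": category,
                    "mae": maes[j],
                    "n_used": int(n_used[j]),
                    "defined": bool(n_used[j] > 0),
                    **{col: freqs[j, i] for i, col in enumerate(FREQ_COLUMNS)},
                }
            )
    table = pd.DataFrame.from_records(records)
    # one row per (sample, category), samples varying fastest within category
    return MAETable(mode="individual_centric", table=table, metric=m.metric)


def rank_and_select(
    t: MAETable, n_top: int = 300, n_bottom: int = 300
) -> tuple[list[str], list[str]]:
    """Lowest- and highest-MAE gene lists from a gene-centric table.

    Sorting is deterministic: MAE, then gene id ascending for the low end;
    MAE descending with gene id ascending for the high end — so when scores
    tie exactly at the cut the lexicographically smaller id is selected.
    Returns up to ``n_top`` best conformers and up to ``n_bottom`` worst; a
    warning is attached when the table is smaller than ``n_top + n_bottom``
    and the two lists must overlap.
    """
    if t.mode != "gene_centric":
        raise ValueError("ranking requires a gene-centric MAE table")
    if len(t) == 0:
        raise ValueError("cannot rank an empty MAE table")
    if n_top <= 0 or n_bottom <= 0:
        raise ValueError("n_top and n_bottom must be positive")
    frame = t.table
    ascending = frame.sort_values(["mae", "gene_id"], kind="mergesort")
    descending = frame.sort_values(
        ["mae", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    lowest = ascending["gene_id"].head(n_top).tolist()
    highest = descending["gene_id"].head(n_bottom).tolist()
    if len(frame) < n_top + n_bottom:
        warnings.warn(
            f"table has {len(frame)} genes but {n_top}+{n_bottom} were "
            "requested; the low- and high-MAE selections overlap",
            stacklevel=2,
        )
    return lowest, highest


def threshold_select(
    t: MAETable,
    mae_below: float | None = None,
    mae_above: float | None = None,
    mean_expr_below: float | None = None,
    mean_expr_above: float | None = None,
    expression_column: str = "mean_expression",
) -> list[str]:
    """Genes passing all supplied strict-inequality filters, conjunctively.

    ``mae_below=0.065`` keeps genes with MAE strictly under 0.065;
    ``mae_above`` the converse; likewise for mean expression on
    ``expression_column`` (by default the table's native metric scale, but a
    log2(CPM+1) column can be targeted for log-scale cutoffs). Bounds that
    leave an empty admissible interval raise a parameter error.
    """
    if t.mode != "gene_centric":
        raise ValueError("threshold selection requires a gene-centric MAE table")
    supplied = [mae_below, mae_above, mean_expr_below, mean_expr_above]
    if all(v is None for v in supplied):
        raise ValueError("at least one threshold must be supplied")
    if mae_above is not None and mae_below is not None and mae_above >= mae_below:
        raise ValueError(f"contradictory MAE bounds: ({mae_above}, {mae_below})")
    if (
        mean_expr_above is not None
        and mean_expr_below is not None
        and mean_expr_above >= mean_expr_below
    ):
        raise ValueError(
            f"contradictory expression bounds: ({mean_expr_above}, {mean_expr_below})"
        )
    frame = t.table
    mask = np.ones(len(frame), dtype=bool)
    if mae_below is not None:
        mask &= frame["mae"].to_numpy() < mae_below
    if mae_above is not None:
        mask &= frame["mae"].to_numpy() > mae_above
    if mean_expr_below is not None or mean_expr_above is not None:
        if expression_column not in frame.columns:
            raise KeyError(f"no column {expression_column!r} in the MAE table")
        expr = frame[expression_column].to_numpy()
        if mean_expr_below is not None:
            mask &= expr < mean_expr_below
        if mean_expr_above is not None:
            mask &= expr > mean_expr_above
    return frame.loc[mask, "gene_id"].tolist()


def write_mae_table(t: MAETable, path) -> None:
    """Serialise an MAE table as tab-separated text."""
    t.table.to_csv(Path(path), sep="\t", index=False)


def read_mae_table(path, mode: str = "gene_centric", metric: str = "raw") -> MAETable:
    """Read back a tab-separated MAE table written by :func:`write_mae_table`."""
    frame = pd.read_csv(Path(path), sep="\t")
    frame["gene_id" if mode == "gene_centric" else "sample_id"] = frame[
        "gene_id" if mode == "gene_centric" else "sample_id"
    ].astype(str)
    return MAETable(mode=mode, table=frame, metric=metric)
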