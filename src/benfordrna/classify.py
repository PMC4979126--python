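"""Predicting tissue specificity from Benford conformity features.

Each gene is summarised by a 10-dimensional feature vector: its nine
observed first-digit frequencies A_1..A_9 plus its gene-centric MAE. Genes
with a wide expression dynamic range (tissue-specific) sit near the Benford
point in this space, while narrow-range (housekeeping) genes scatter across
near-point-mass digit distributions — so a simple geometric classifier
separates the two classes.

Provides classical (Torgerson) metric MDS for visualising the feature
space, a reproducible stratified train/test split, a k-nearest-neighbour
classifier with a deterministic distance tie rule, and confusion-matrix
metrics with tissue-specific as the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from .scoring import FREQ_COLUMNS, MAETable

__all__ = [
    "HOUSEKEEPING",
    "TISSUE_SPECIFIC",
    "FeatureTable",
    "ClassifierReport",
    "build_features",
    "mds_embed",
    "split_train_test",
    "knn_classify",
    "confusion_metrics",
]

HOUSEKEEPING = "housekeeping"
TISSUE_SPECIFIC = "tissue_specific"
CLASSES = (HOUSEKEEPING, TISSUE_SPECIFIC)

FEATURE_COLUMNS = FREQ_COLUMNS + ["mae"]


@dataclass(frozen=True)
class FeatureTable:
    """Per-gene Benford feature vectors (A_1..A_9, MAE) with optional labels.

    ``frame`` is indexed by gene id with columns ``d1..d9``, ``mae`` and
    ``label`` (None where unlabeled). The nine frequency components of every
    row sum to 1.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        sums = self.frame[FREQ_COLUMNS].to_numpy().sum(axis=1)
        if len(self.frame) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("digit-frequency components must sum to 1 per gene")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    def matrix(self) -> np.ndarray:
        """The n_genes x 10 feature array (frequencies then MAE)."""
        return self.frame[FEATURE_COLUMNS].to_numpy(dtype=float)

    def subset(self, gene_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.frame.loc[list(gene_ids)])


@dataclass(frozen=True)
class ClassifierReport:
    """KNN predictions plus 2x2 confusion metrics.

    Confusion grid rows are actual, columns predicted, both ordered
    (housekeeping, tissue_specific). Sensitivity = TP/(TP+FN) and
    specificity = TN/(TN+FP) with tissue_specific as the positive class.
    Metrics are None when the test genes were unlabeled.
    """

    predictions: dict[str, str]
    confusion: np.ndarray | None
    sensitivity: float | None
    specificity: float | None
    k: int
    split_seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "split_seed": self.split_seed,
            "confusion": None if self.confusion is None else self.confusion.tolist(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "predictions": self.predictions,
        }


def build_features(
    t: MAETable, labels: Mapping[str, str] | None = None
) -> FeatureTable:
    """Assemble per-gene feature vectors from a gene-centric MAE table.

    Genes with undefined digit frequencies (NaN rows) are excluded with a
    warning naming how many were dropped; labels are attached where the
    mapping provides one, other genes stay unlabeled.
    """
    if t.mode != "gene_centric":
        raise ValueError("features are built from a gene-centric MAE table")
    frame = t.table.set_index("gene_id")[FEATURE_COLUMNS].astype(float)
    bad = frame.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"excluded {int(bad.sum())} gene(s) with undefined digit frequencies",
            stacklevel=2,
        )
        frame = frame[~bad]
    frame = frame.copy()
    if labels is None:
        frame["label"] = None
    else:
        frame["label"] = [labels.get(g) for g in frame.index]
    return FeatureTable(frame)


def mds_embed(f: FeatureTable, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of the feature vectors.

    Double-centers the squared Euclidean distance matrix and takes the top
    ``dims`` eigenvectors scaled by the square roots of their eigenvalues.
    Coordinates are centered (column means 0) and deterministic up to sign,
    which is fixed by orienting each axis so its largest-magnitude loading
    is positive. Distances, not coordinates, are the meaningful output.
    """
    if dims < 1:
        raise ValueError(f"dims must be >= 1, got {dims}")
    if len(f) < dims + 1:
        raise ValueError(f"need at least {dims + 1} genes to embed in {dims}-D")
    x = f.matrix()
    d2 = cdist(x, x, metric="sqeuclidean")
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:dims]
    lams = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lams)
    for axis in range(coords.shape[1]):  # deterministic sign convention
        pivot = np.argmax(np.abs(coords[:, axis]))
        if coords[pivot, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return pd.DataFrame(
        coords, index=f.frame.index, columns=[f"mds{i + 1}" for i in range(dims)]
    )


def split_train_test(
    f: FeatureTable,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[FeatureTable, FeatureTable]:
    """Reproducible train/test split of a fully labeled feature table."""
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    labels = f.labels
    if labels.isna().any() or (labels == None).any():  # noqa: E711
        raise ValueError("all genes must be labeled before splitting")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"class(es) with fewer than 2 members cannot be split: "
            f"{', '.join(small.index)}"
        )
    train_idx, test_idx = train_test_split(
        np.arange(len(f)),
        train_size=train_fraction,
        random_state=seed,
        stratify=labels.to_numpy() if stratified else None,
        shuffle=True,
    )
    genes = np.asarray(f.gene_ids)
    return f.subset(genes[np.sort(train_idx)]), f.subset(genes[np.sort(test_idx)])


def _vote(neighbour_labels: Sequence[str], k: int) -> str:
    ts = sum(1 for lab in neighbour_labels if lab == TISSUE_SPECIFIC)
    hk = len(neighbour_labels) - ts
    if ts == hk:  # only possible for even k; break toward the positive class
        return TISSUE_SPECIFIC
    return TISSUE_SPECIFIC if ts > hk else HOUSEKEEPING


def knn_classify(
    train: FeatureTable, test: FeatureTable, k: int = 7, split_seed: int | None = None
) -> ClassifierReport:
    """Majority vote among the k nearest training genes (Euclidean distance).

    Neighbour order is fully deterministic: candidates are ranked by
    (distance, gene id), so exact distance ties at the k-th neighbour resolve
    toward the lexicographically smaller training gene id. With two classes
    and odd ``k`` vote ties cannot occur; an even ``k`` triggers a warning
    and breaks vote ties toward tissue_specific. Confusion metrics are
    computed only when every test gene carries a label.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(train):
        raise ValueError(f"k={k} exceeds the training set size {len(train)}")
    train_labels = train.labels
    present = set(train_labels.dropna())
    if not present <= set(CLASSES):
        raise ValueError(f"unknown training labels: {present - set(CLASSES)}")
    if len(present) < 2:
        raise ValueError("training set must contain both classes")
    if k % 2 == 0:
        warnings.warn(
            "even k allows vote ties; ties are broken toward tissue_specific",
            stacklevel=2,
        )

    dists = cdist(test.matrix(), train.matrix())
    train_ids = np.asarray(train.gene_ids)
    id_rank = np.argsort(train_ids, kind="mergesort")  # lexicographic tie order
    labels_arr = train_labels.to_numpy()

    predictions: dict[str, str] = {}
    for i, gene in enumerate(test.gene_ids):
        row = dists[i, id_rank]
        nearest = id_rank[np.argsort(row, kind="mergesort")[:k]]
        predictions[gene] = _vote(labels_arr[nearest].tolist(), k)

    actual = test.labels
    if actual.isna().any() or (actual == None).any():  # noqa: E711
        return ClassifierReport(
            predictions=predictions,
            confusion=None,
            sensitivity=None,
            specificity=None,
            k=k,
            split_seed=split_seed,
        )
    grid, sens, spec = confusion_metrics(
        actual.tolist(), [predictions[g] for g in test.gene_ids]
    )
    return ClassifierReport(
        predictions=predictions,
        confusion=grid,
        sensitivity=sens,
        specificity=spec,
        k=k,
        split_seed=split_seed,
    )


def confusion_metrics(
    actual: Sequence[str], predicted: Sequence[str]
) -> tuple[np.ndarray, float, float]:
    """2x2 confusion grid with sensitivity and specificity.

    Rows are actual, columns predicted, both ordered (housekeeping,
    tissue_specific). With tissue_specific as the positive class:
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
    """
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted label sequences differ in length")
    stray = set(actual) | set(predicted)
    if not stray <= set(CLASSES):
        raise ValueError(f"labels outside the two classes: {stray - set(CLASSES)}")
    grid = _sk_confusion(actual, predicted, labels=list(CLASSES))
    tn, fp = grid[0]
    fn, tp = grid[1]
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return grid, float(sensitivity), float(specificity)
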