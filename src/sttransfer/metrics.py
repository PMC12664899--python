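"""Evaluation of predicted annotations against ground truth.

Accuracy and support-weighted F1 follow the scikit-learn definitions; the
profile correlation compares mean log1p counts-per-10k pseudobulk profiles
of predicted groups against reference types by Spearman rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import accuracy_score
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score

from .io import ExpressionDataset

logger = logging.getLogger(__name__)


def _clean(labels) -> np.ndarray:
    arr = np.asarray([str(x).strip() for x in np.asarray(labels)], dtype=object)
    if arr.size == 0:
        raise ValueError("empty label vector")
    return arr


@dataclass
class EvaluationReport:
    accuracy: float
    weighted_f1: float
    classes: list[str]
    confusion: np.ndarray
    per_class_f1: dict[str, float]
    profile_spearman: pd.DataFrame | None = None
    n_cells: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "weighted_f1": self.weighted_f1,
            "n_cells": self.n_cells,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "per_class_f1": self.per_class_f1,
        }
        if self.profile_spearman is not None:
            out["profile_spearman"] = self.profile_spearman.to_dict()
        out.update(self.extras)
        return out


def accuracy(truth, pred) -> float:
    """Fraction of cells whose predicted type equals the ground truth."""
    t, p = _clean(truth), _clean(pred)
    if len(t) != len(p):
        raise ValueError("truth and prediction lengths differ")
    return float(accuracy_score(t, p))


def weighted_f1(truth, pred) -> float:
    """Support-weighted mean of per-class F1 scores."""
    t, p = _clean(truth), _clean(pred)
    return float(f1_score(t, p, average="weighted", zero_division=0))


def confusion_matrix(truth, pred, classes: list[str] | None = None) -> np.ndarray:
    """Counts matrix: rows are true types, columns predicted types."""
    t, p = _clean(truth), _clean(pred)
    if classes is None:
        classes = sorted(set(t) | set(p))
    return _sk_confusion(t, p, labels=list(classes))


def evaluate(truth, pred, spatial: ExpressionDataset | None = None,
             reference: ExpressionDataset | None = None) -> EvaluationReport:
    """Full report: accuracy, weighted F1, confusion and per-class F1;
    optionally the predicted-vs-reference profile correlation matrix."""
    t, p = _clean(truth), _clean(pred)
    classes = sorted(set(t) | set(p))
    per_class = f1_score(t, p, average=None, labels=classes, zero_division=0)
    spear = None
    if spatial is not None and reference is not None:
        spear = profile_spearman(spatial, p, reference)
    return EvaluationReport(
        accuracy=accuracy(t, p),
        weighted_f1=weighted_f1(t, p),
        classes=classes,
        confusion=confusion_matrix(t, p, classes),
        per_class_f1=dict(zip(classes, map(float, per_class))),
        profile_spearman=spear,
        n_cells=len(t),
    )


def _group_profiles(counts: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Mean log1p counts-per-10k profile per label group."""
    depth = np.maximum(counts.sum(axis=1, keepdims=True), 1.0)
    logcp10k = np.log1p(counts / depth * 1e4)
    groups = {}
    for g in np.unique(labels):
        groups[g] = logcp10k[labels == g].mean(axis=0)
    return pd.DataFrame(groups).T


def profile_spearman(spatial: ExpressionDataset, pred,
                     reference: ExpressionDataset) -> pd.DataFrame:
    """Spearman correlation between predicted-group and reference-type
    pseudobulk profiles over the shared gene set (rows: predicted groups,
    columns: reference types). Degenerate constant profiles yield NaN."""
    if reference.labels is None:
        raise ValueError("reference must carry labels")
    shared = [g for g in reference.gene_ids if g in set(spatial.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between spatial and reference data")
    sp_prof = _group_profiles(spatial.subset_genes(shared).counts.astype(float), _clean(pred))
    ref_prof = _group_profiles(reference.subset_genes(shared).counts.astype(float),
                               _clean(reference.labels))
    out = pd.DataFrame(index=sp_prof.index, columns=ref_prof.index, dtype=float)
    for i in sp_prof.index:
        for j in ref_prof.index:
            if np.ptp(sp_prof.loc[i]) == 0 or np.ptp(ref_prof.loc[j]) == 0:
                logger.warning("constant profile for %r vs %r: correlation undefined", i, j)
                out.loc[i, j] = np.nan
                continue
            out.loc[i, j] = spearmanr(sp_prof.loc[i], ref_prof.loc[j]).statistic
    return out


def neighbor_label_agreement(labels, adjacency) -> float:
    """Mean over cells of the fraction of graph neighbors sharing the
    cell's label — the spatial-coherence score used to quantify smoothing."""
    arr = _clean(labels)
    a = adjacency.tocsr()
    agree = []
    for i in range(a.shape[0]):
        nbrs = a.indices[a.indptr[i]:a.indptr[i + 1]]
        if len(nbrs):
            agree.append(float((arr[nbrs] == arr[i]).mean()))
    return float(np.mean(agree))
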