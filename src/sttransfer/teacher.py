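"""Boosted-tree teacher: reference-trained classifier emitting per-cell
cell-type probability distributions over the spatial data.

The teacher is an XGBoost ensemble (DART booster, so the regularizing
"dropout" acts at the tree level) trained on the annotated reference
embedding. Its per-class softmax probabilities on the spatial embedding
form the teacher distribution D that the graph annotator distills.
A linear-softmax backend is provided as an alternative teacher.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .vae import LatentEmbedding

logger = logging.getLogger(__name__)

DEFAULT_K_N_FOLD = 5


@dataclass
class TeacherDistribution:
    """Row-stochastic cells x classes probability matrix (the distribution D)."""

    probs: np.ndarray
    classes: list[str]
    cell_ids: list[str]

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        n, c = self.probs.shape
        if len(self.classes) != c:
            raise ValueError("class list length does not match probability columns")
        if len(self.cell_ids) != n:
            raise ValueError("cell id list length does not match probability rows")
        if (self.probs < 0).any() or (self.probs > 1).any():
            raise ValueError("probabilities outside [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows do not sum to 1")

    def argmax_labels(self) -> np.ndarray:
        # np.argmax takes the lowest index on ties, the documented tie-break
        return np.asarray(self.classes, dtype=object)[self.probs.argmax(axis=1)]


class TeacherModel:
    """Trained ensemble plus its fixed, persisted class order."""

    def __init__(self, booster: xgb.Booster, classes: list[str],
                 k_n_fold: int, n_features: int, cv_accuracy: float | None = None):
        self.booster = booster
        self.classes = list(classes)
        self.k_n_fold = k_n_fold
        self.n_features = n_features
        self.cv_accuracy = cv_accuracy

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(path / "teacher.json"))
        manifest = {"classes": self.classes, "k_n_fold": self.k_n_fold,
                    "n_features": self.n_features, "cv_accuracy": self.cv_accuracy}
        (path / "classes.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TeacherModel":
        path = Path(path)
        manifest = json.loads((path / "classes.json").read_text())
        booster = xgb.Booster()
        booster.load_model(str(path / "teacher.json"))
        return cls(booster, manifest["classes"], manifest["k_n_fold"],
                   manifest["n_features"], manifest.get("cv_accuracy"))


def _xgb_params(n_classes: int, seed: int, drop_rate: float) -> dict:
    return {
        "objective": "multi:softprob",
        "num_class": n_classes,
        "booster": "dart",
        "rate_drop": drop_rate,
        "max_depth": 6,
        "eta": 0.3,
        # exact split finding: histogram quantization places cuts at a class
        # edge inside empty margins, which misassigns borderline cells
        "tree_method": "exact",
        "nthread": 1,
        "seed": int(seed),
    }


def train_teacher(ssi: LatentEmbedding, labels, k_n_fold: int = DEFAULT_K_N_FOLD,
                  seed: int = 0, drop_rate: float = 0.1,
                  num_boost_round: int = 100) -> TeacherModel:
    """Fit the boosted-tree teacher on the annotated reference embedding.

    The boosting-round count is selected by stratified k_n_fold
    cross-validation (early stopping on the held-out softmax loss), then
    the final ensemble is refit on all reference cells with that count.
    Cross-validated accuracy is recorded on the model and in the logs.
    """
    labels = pd.Categorical(labels)
    if len(labels) != ssi.n_cells:
        raise ValueError("labels length does not match embedding rows")
    classes = list(labels.categories)
    if len(classes) < 2:
        raise ValueError("need at least 2 cell-type classes to train a teacher")
    counts = labels.value_counts()
    small = [c for c in classes if counts[c] < k_n_fold]
    if small:
        raise ValueError(
            f"classes {small} have fewer than k_n_fold={k_n_fold} cells; "
            "merge them into a broader type or drop those cells")

    y = labels.codes.astype(int)
    x = ssi.values
    params = _xgb_params(len(classes), seed, drop_rate)

    skf = StratifiedKFold(n_splits=k_n_fold, shuffle=True, random_state=seed)
    best_rounds: list[int] = []
    correct = 0
    for train_idx, test_idx in skf.split(x, y):
        dtrain = xgb.DMatrix(x[train_idx], label=y[train_idx])
        dtest = xgb.DMatrix(x[test_idx], label=y[test_idx])
        booster = xgb.train(params, dtrain, num_boost_round=num_boost_round,
                            evals=[(dtest, "held_out")],
                            early_stopping_rounds=10, verbose_eval=False)
        best_rounds.append(booster.best_iteration + 1)
        # DART predictions are valid only over the full ensemble (tree-drop
        # weights are not truncation-consistent), so score without a range
        pred = booster.predict(dtest)
        correct += int((pred.argmax(axis=1) == y[test_idx]).sum())
    cv_accuracy = correct / len(y)
    rounds = int(round(np.mean(best_rounds)))
    logger.info("teacher CV accuracy %.4f (k_n_fold=%d), refit with %d rounds",
                cv_accuracy, k_n_fold, rounds)

    dall = xgb.DMatrix(x, label=y)
    booster = xgb.train(params, dall, num_boost_round=rounds)
    return TeacherModel(booster, classes, k_n_fold, x.shape[1], cv_accuracy)


def predict_distribution(model: TeacherModel, tti: LatentEmbedding) -> TeacherDistribution:
    """Teacher probabilities for each spatial cell (the distribution D)."""
    if tti.values.shape[1] != model.n_features:
        raise ValueError(
            f"embedding has {tti.values.shape[1]} dims, teacher expects {model.n_features}")
    probs = model.booster.predict(xgb.DMatrix(tti.values)).astype(np.float64)
    probs /= probs.sum(axis=1, keepdims=True)
    return TeacherDistribution(probs=probs, classes=model.classes,
                               cell_ids=list(tti.cell_ids))


class LinearTeacher:
    """Multinomial-logistic alternative teacher: D = softmax(TTI W + b)."""

    def __init__(self, classes: list[str], clf):
        self.classes = list(classes)
        self._clf = clf
        self.n_features = clf.coef_.shape[1]


def train_linear_teacher(ssi: LatentEmbedding, labels, seed: int = 0) -> LinearTeacher:
    from sklearn.linear_model import LogisticRegression

    labels = pd.Categorical(labels)
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(ssi.values, labels.codes)
    classes = [str(labels.categories[i]) for i in clf.classes_]
    return LinearTeacher(classes, clf)


def predict_linear_distribution(model: LinearTeacher, tti: LatentEmbedding) -> TeacherDistribution:
    probs = model._clf.predict_proba(tti.values)
    return TeacherDistribution(probs=probs, classes=model.classes,
                               cell_ids=list(tti.cell_ids))
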