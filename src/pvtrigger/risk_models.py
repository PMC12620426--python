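"""Structure-based risk models with sklearn-style estimator interfaces.

Three classifiers score molecules for adverse-event risk:

* :class:`SvmRiskClassifier` — RBF-kernel SVM on descriptor or fingerprint
  matrices (z-scored on the training data, probability-calibrated);
* :class:`GcnRiskClassifier` — graph convolutional network over molecular
  graphs (neighbour-mean aggregation, residual connections, mean-pool
  readout, MLP predictor);
* :class:`DmpnnRiskClassifier` — directed message-passing network whose
  hidden states live on directed bonds (excluding reverse-bond back-flow),
  optionally augmented with molecule-level descriptor/fingerprint vectors
  concatenated to the graph readout.

All three expose fit / predict_proba / predict, get_params / set_params and
``_``-suffixed fitted attributes so they compose with sklearn model
selection. Dataset handling follows the evaluation protocol: an 8:1:1
train/validation/test split, 5-fold cross-validation, AUC via the
Mann-Whitney rank statistic, and a consensus rule that a drug is high-risk
only when all three models score it above a threshold (default 0.60).
Hyperparameters are chosen by seeded random search against the validation
split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._graphnn import DMPNNNet, GCNNet, GraphBatch, predict_net, train_net
from .mol_features import ATOM_FDIM, BOND_FDIM, MolGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetSplit",
    "split_dataset",
    "kfold_indices",
    "compute_auc",
    "SvmRiskClassifier",
    "GcnRiskClassifier",
    "DmpnnRiskClassifier",
    "train_svm",
    "train_gcn",
    "train_dmpnn",
    "consensus",
    "cross_validate_auc",
]


@dataclass(frozen=True)
class DatasetSplit:
    """8:1:1 train/validation/test index partition."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int


def split_dataset(n: int, seed: int = 0) -> DatasetSplit:
    """Seeded uniform shuffle sliced 8:1:1 (floor(0.8n) / floor(0.1n) / rest)."""
    if n < 10:
        raise ValueError("need n >= 10 to split 8:1:1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train, n_val = int(np.floor(0.8 * n)), int(np.floor(0.1 * n))
    return DatasetSplit(train=perm[:n_train],
                        val=perm[n_train:n_train + n_val],
                        test=perm[n_train + n_val:], seed=seed)


def kfold_indices(n: int, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint, exhaustive k-fold (train, held-out) index pairs."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    return [(np.concatenate(folds[:i] + folds[i + 1:]), folds[i])
            for i in range(k)]


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank formulation (ties count 0.5)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return y


class SvmRiskClassifier(BaseEstimator, ClassifierMixin):
    """RBF-SVM on standardized feature matrices, probability-calibrated."""

    def __init__(self, C: float = 1.0, gamma: str | float = "scale",
                 class_weight: str | dict = "balanced", random_state: int = 0):
        self.C = C
        self.gamma = gamma
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _check_labels(y)
        svc = SVC(C=self.C, gamma=self.gamma, kernel="rbf",
                  class_weight=self.class_weight,
                  random_state=self.random_state)
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(svc, method="sigmoid", cv=3,
                                   ensemble=False))
        self.pipeline_.fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.pipeline_.predict(np.asarray(X, dtype=float))

    def score_drugs(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


class _GraphClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared plumbing: graph validation, probability API."""

    @staticmethod
    def _check_graphs(graphs: list[MolGraph]) -> list[MolGraph]:
        ok = [g for g in graphs if g.n_atoms > 0]
        if len(ok) < len(graphs):
            logger.warning("skipping %d empty graphs", len(graphs) - len(ok))
        if not ok:
            raise ValueError("no non-empty graphs to train on")
        return ok

    def predict(self, X):
        return (self.score_drugs(X) >= 0.5).astype(int)

    def predict_proba(self, X):
        p = self.score_drugs(X)
        return np.column_stack([1 - p, p])


class GcnRiskClassifier(_GraphClassifierBase):
    """Graph convolutional network classifier over molecular graphs."""

    def __init__(self, hidden: int = 32, n_layers: int = 2,
                 mlp_hidden: int = 16, dropout: float = 0.0,
                 residual: bool = True, epochs: int = 300, lr: float = 5e-3,
                 random_state: int = 0):
        self.hidden = hidden
        self.n_layers = n_layers
        self.mlp_hidden = mlp_hidden
        self.dropout = dropout
        self.residual = residual
        self.epochs = epochs
        self.lr = lr
        self.random_state = random_state

    def fit(self, X: list[MolGraph], y):
        graphs = self._check_graphs(X)
        y = _check_labels(y)
        self.net_ = GCNNet(d_atom=ATOM_FDIM, hidden=self.hidden,
                           n_layers=self.n_layers, mlp_hidden=self.mlp_hidden,
                           dropout=self.dropout, residual=self.residual,
                           seed=self.random_state)
        self.loss_trace_ = train_net(self.net_, GraphBatch(graphs), y,
                                     epochs=self.epochs, lr=self.lr,
                                     seed=self.random_state)
        self.classes_ = np.array([0, 1])
        return self

    def score_drugs(self, X: list[MolGraph]) -> np.ndarray:
        return predict_net(self.net_, GraphBatch(X))


class DmpnnRiskClassifier(_GraphClassifierBase):
    """Directed message-passing classifier, optionally descriptor-augmented.

    When ``extra`` feature matrices are passed to fit/score, they are z-scored
    with training statistics and concatenated to the graph readout before the
    feed-forward predictor (the "-Des" / "-ECFP4" variants).
    """

    def __init__(self, hidden: int = 32, depth: int = 3, ffn_hidden: int = 16,
                 ffn_layers: int = 1, dropout: float = 0.0, epochs: int = 300,
                 lr: float = 5e-3, random_state: int = 0):
        self.hidden = hidden
        self.depth = depth
        self.ffn_hidden = ffn_hidden
        self.ffn_layers = ffn_layers
        self.dropout = dropout
        self.epochs = epochs
        self.lr = lr
        self.random_state = random_state

    def fit(self, X: list[MolGraph], y, extra: np.ndarray | None = None):
        graphs = self._check_graphs(X)
        y = _check_labels(y)
        if extra is not None:
            extra = np.asarray(extra, dtype=float)
            self.extra_scaler_ = StandardScaler().fit(extra)
            extra = self.extra_scaler_.transform(extra)
            extra = np.nan_to_num(extra)
        else:
            self.extra_scaler_ = None
        self.net_ = DMPNNNet(d_atom=ATOM_FDIM, d_bond=BOND_FDIM,
                             hidden=self.hidden, depth=self.depth,
                             ffn_hidden=self.ffn_hidden,
                             ffn_layers=self.ffn_layers, dropout=self.dropout,
                             d_extra=0 if extra is None else extra.shape[1],
                             seed=self.random_state)
        self.loss_trace_ = train_net(self.net_, GraphBatch(graphs), y,
                                     extra=extra, epochs=self.epochs,
                                     lr=self.lr, seed=self.random_state)
        self.classes_ = np.array([0, 1])
        return self

    def score_drugs(self, X: list[MolGraph],
                    extra: np.ndarray | None = None) -> np.ndarray:
        if (extra is None) != (self.extra_scaler_ is None):
            raise ValueError("extra features must match fit-time usage")
        if extra is not None:
            extra = np.nan_to_num(self.extra_scaler_.transform(
                np.asarray(extra, dtype=float)))
        return predict_net(self.net_, GraphBatch(X), extra=extra)

    def predict(self, X, extra=None):
        return (self.score_drugs(X, extra=extra) >= 0.5).astype(int)


def _random_search(build, score, param_space: dict, budget: int, seed: int):
    rng = np.random.default_rng(seed)
    best, best_auc, best_params = None, -np.inf, None
    for _ in range(budget):
        params = {k: v[rng.integers(len(v))] for k, v in param_space.items()}
        model = build(params)
        auc = score(model)
        if auc > best_auc:
            best, best_auc, best_params = model, auc, params
    return best, best_auc, best_params


def train_svm(X_train, y_train, X_val, y_val, budget: int = 8,
              seed: int = 0) -> tuple[SvmRiskClassifier, float]:
    """Seeded random search over (C, gamma) scored by validation AUC."""
    space = {"C": [0.1, 1.0, 10.0, 100.0],
             "gamma": ["scale", 0.01, 0.1, 1.0]}

    def build(p):
        return SvmRiskClassifier(random_state=seed, **p).fit(X_train, y_train)

    def score(m):
        return compute_auc(m.score_drugs(X_val), y_val)

    model, auc, params = _random_search(build, score, space, budget, seed)
    logger.info("SVM search: val AUC %.3f with %s", auc, params)
    return model, auc


def train_gcn(graphs_train, y_train, graphs_val, y_val, budget: int = 4,
              epochs: int = 300, seed: int = 0) -> tuple[GcnRiskClassifier, float]:
    """Seeded random search over (layers, hidden, dropout)."""
    space = {"n_layers": [2, 3], "hidden": [16, 32], "dropout": [0.0, 0.1]}

    def build(p):
        return GcnRiskClassifier(epochs=epochs, random_state=seed, **p).fit(
            graphs_train, y_train)

    def score(m):
        return compute_auc(m.score_drugs(graphs_val), y_val)

    model, auc, params = _random_search(build, score, space, budget, seed)
    logger.info("GCN search: val AUC %.3f with %s", auc, params)
    return model, auc


def train_dmpnn(graphs_train, y_train, graphs_val, y_val,
                extra_train: np.ndarray | None = None,
                extra_val: np.ndarray | None = None, budget: int = 4,
                epochs: int = 300, seed: int = 0
                ) -> tuple[DmpnnRiskClassifier, float]:
    """Seeded random search over (depth, hidden, ffn, dropout)."""
    space = {"depth": [2, 3], "hidden": [16, 32], "ffn_layers": [1, 2],
             "dropout": [0.0, 0.1]}

    def build(p):
        return DmpnnRiskClassifier(epochs=epochs, random_state=seed, **p).fit(
            graphs_train, y_train, extra=extra_train)

    def score(m):
        return compute_auc(m.score_drugs(graphs_val, extra=extra_val), y_val)

    model, auc, params = _random_search(build, score, space, budget, seed)
    logger.info("DMPNN search: val AUC %.3f with %s", auc, params)
    return model, auc


def consensus(scores: pd.DataFrame, threshold: float = 0.60) -> pd.Series:
    """Consensus high-risk flag: every model's score above the threshold.

    ``scores`` has one column per model, one row per drug; a drug is flagged
    only when it sits in the positive set of all models simultaneously.
    """
    return (scores > threshold).all(axis=1)


def cross_validate_auc(fit_score, n: int, y: np.ndarray, k: int = 5,
                       seed: int = 0) -> list[float]:
    """5-fold CV AUCs for a generic ``fit_score(train_idx, test_idx)`` callable."""
    aucs = []
    for train_idx, test_idx in kfold_indices(n, k=k, seed=seed):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            continue
        s = fit_score(train_idx, test_idx)
        aucs.append(compute_auc(s, y[test_idx]))
    return aucs
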