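"""5-fold cross-validation with merged-ROC, per-label AUC and top-k accuracy.

Drugs are split once into K folds; each method trains on K-1 folds (its
normalizers and model never see test rows) and scores the held-out drugs.
Scores for all drug x side-effect pairs are pooled over folds into one
global ROC/AUC per method; AUC is also reported per side-effect, and the
top-k accuracy per drug measures how many of a drug's k highest-scoring
side-effects are recorded ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import rankdata

from .baselines import NNParams, SVMParams, nn_scores, random_scores, svm_scores
from .cca import CCAModel, SCCAParams, canonical_correlation, occa_fit, \
    cross_product, scca_fit
from .predict import predict_matrix
from .profiles import BinaryProfileMatrix, apply_normalizer, fit_normalizer

__all__ = [
    "FoldAssignment",
    "EvaluationReport",
    "kfold_split",
    "roc_auc",
    "global_auc",
    "per_label_auc",
    "topk_accuracy",
    "fit_method",
    "run_cv_experiment",
]


@dataclass
class FoldAssignment:
    fold_of: dict[str, int]  # drug id -> fold index, 1..K
    K: int

    def test_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f != fold]


@dataclass
class EvaluationReport:
    method_name: str
    params: dict[str, Any]
    pooled_scores: np.ndarray  # n x q, in the row order of the input matrices
    pooled_labels: np.ndarray
    global_auc: float
    per_label_auc: np.ndarray
    topk_accuracy: dict[int, np.ndarray] = field(default_factory=dict)

    def mean_per_label_auc(self) -> float:
        vals = self.per_label_auc[~np.isnan(self.per_label_auc)]
        return float(vals.mean()) if vals.size else float("nan")


def kfold_split(ids: list[str], K: int, seed: int = 0) -> FoldAssignment:
    """Deal a seeded random permutation of ids round-robin into K folds."""
    if K < 2 or K > len(ids):
        raise ValueError(f"K={K} invalid for {len(ids)} ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_of = {ids[j]: (pos % K) + 1 for pos, j in enumerate(perm)}
    return FoldAssignment(fold_of=fold_of, K=K)


def roc_auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) statistic; tied pairs count 1/2.

    Returns NaN when labels contain a single class.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)  # average ranks give the half-credit tie convention
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def global_auc(scores, labels) -> float:
    """AUC on all drug x side-effect pairs flattened together."""
    return roc_auc(np.asarray(scores).ravel(), np.asarray(labels).ravel())


def per_label_auc(scores, labels) -> np.ndarray:
    """Column-wise AUC; single-class columns are NaN (excluded from means)."""
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    L = np.atleast_2d(np.asarray(labels))
    return np.array([roc_auc(S[:, j], L[:, j]) for j in range(S.shape[1])])


def topk_accuracy(scores, labels, k: int) -> float:
    """Fraction of the k top-scoring side-effects that are true for one drug.

    Ties are broken by ascending label index via a stable sort, so the
    result is deterministic.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if not 1 <= k <= s.size:
        raise ValueError(f"k={k} invalid for {s.size} labels")
    top = np.argsort(-s, kind="stable")[:k]
    return float(y[top].sum() / k)


def fit_method(
    method: str,
    train_X: np.ndarray,
    train_Y: np.ndarray,
    test_X: np.ndarray,
    params: dict[str, Any],
    seed: int = 0,
) -> np.ndarray:
    """Train one predictor on the training rows and score the test rows.

    method is one of "random", "nn", "svm", "occa", "scca".  CCA methods
    fit normalizers on training rows only; prediction uses the weighted
    canonical score by default ("predict" param switches to "pinv").
    """
    if method == "random":
        return random_scores(
            train_Y, [str(i) for i in range(test_X.shape[0])],
            seed=seed, mode=params.get("mode", "binary"),
        )
    if method == "nn":
        return nn_scores(train_X, train_Y, test_X, NNParams(**params))
    if method == "svm":
        return svm_scores(train_X, train_Y, test_X, SVMParams(**params))
    if method in ("occa", "scca"):
        xn = fit_normalizer(train_X)
        yn = fit_normalizer(train_Y)
        Xn = apply_normalizer(xn, train_X)
        Yn = apply_normalizer(yn, train_Y)
        predict_how = params.pop("predict", "weighted") if "predict" in params else "weighted"
        if method == "occa":
            m = params.get("m", 1)
            A, B, d = occa_fit(cross_product(Xn, Yn), m)
            rho = np.array(
                [canonical_correlation(Xn, Yn, A[:, j], B[:, j]) for j in range(m)]
            )
            model = CCAModel(A=A, B=B, d=d, rho=rho, x_norm=xn, y_norm=yn)
        else:
            sp = SCCAParams(**{**params, "seed": params.get("seed", seed)})
            model = scca_fit(Xn, Yn, sp, x_norm=xn, y_norm=yn)
        return predict_matrix(model, test_X.astype(float), method=predict_how)
    raise ValueError(f"unknown method {method!r}")


def run_cv_experiment(
    X: BinaryProfileMatrix,
    Y: BinaryProfileMatrix,
    method: str,
    params: dict[str, Any] | None = None,
    K: int = 5,
    seed: int = 0,
    topk: tuple[int, ...] = (10,),
    folds: FoldAssignment | None = None,
) -> EvaluationReport:
    """Cross-validate one method on aligned profile matrices.

    The fold assignment may be passed in so several methods share identical
    train/test splits; otherwise it is derived from ``seed``.  Pooled score
    and label matrices preserve the input row order, so results do not
    depend on fold processing order.
    """
    if X.row_ids != Y.row_ids:
        raise ValueError("X and Y must be aligned on the same drug ids (align_by_ids)")
    params = dict(params or {})
    if folds is None:
        folds = kfold_split(X.row_ids, K, seed=seed)
    row_of = {i: r for r, i in enumerate(X.row_ids)}
    n, q = Y.n, Y.f
    pooled_scores = np.zeros((n, q))
    pooled_labels = Y.values.astype(np.int8)

    for fold in range(1, folds.K + 1):
        te = sorted(folds.test_ids(fold), key=lambda i: row_of[i])
        tr = sorted(folds.train_ids(fold), key=lambda i: row_of[i])
        te_rows = [row_of[i] for i in te]
        tr_rows = [row_of[i] for i in tr]
        scores = fit_method(
            method,
            X.values[tr_rows],
            Y.values[tr_rows],
            X.values[te_rows],
            dict(params),
            seed=seed + fold,
        )
        pooled_scores[te_rows] = scores

    report = EvaluationReport(
        method_name=method,
        params=params,
        pooled_scores=pooled_scores,
        pooled_labels=pooled_labels,
        global_auc=global_auc(pooled_scores, pooled_labels),
        per_label_auc=per_label_auc(pooled_scores, pooled_labels),
    )
    for k in topk:
        kk = min(k, q)
        report.topk_accuracy[k] = np.array(
            [topk_accuracy(pooled_scores[i], pooled_labels[i], kk) for i in range(n)]
        )
    return report
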