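"""Baseline side-effect predictors: random assignment, k-NN, per-label SVM."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .profiles import BinaryProfileMatrix

logger = logging.getLogger("fragside")

__all__ = ["NNParams", "SVMParams", "random_scores", "nn_scores", "svm_scores"]


@dataclass
class NNParams:
    k: int = 10
    similarity: str = "jaccard"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.similarity not in ("jaccard", "cosine", "dot"):
            raise ValueError(f"unknown similarity {self.similarity!r}")


@dataclass
class SVMParams:
    kernel: str = "rbf"
    sigma: float = 0.2
    C: float = 1.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear", "poly"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.sigma <= 0 or self.C <= 0:
            raise ValueError("sigma and C must be positive")


def _values(M) -> np.ndarray:
    return M.values if isinstance(M, BinaryProfileMatrix) else np.asarray(M)


def random_scores(
    train_Y, test_ids: list[str], seed: int = 0, mode: str = "binary"
) -> np.ndarray:
    """Assign labels at random by training prevalence.

    For side-effect j with training prevalence f_j, each test drug gets a
    hard 1 with probability f_j (mode="binary"); mode="prevalence" emits
    f_j itself for every test drug, a deterministic diagnostic variant.
    """
    Y = _values(train_Y)
    if Y.size == 0:
        raise ValueError("empty training labels")
    freq = Y.mean(axis=0, dtype=float)
    n_test = len(test_ids)
    if mode == "prevalence":
        return np.tile(freq, (n_test, 1))
    if mode != "binary":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    return (rng.random((n_test, freq.size)) < freq).astype(float)


def _similarity(test_X: np.ndarray, train_X: np.ndarray, kind: str) -> np.ndarray:
    """Pairwise similarity, test rows x train rows, on binary fingerprints."""
    A = test_X.astype(float)
    B = train_X.astype(float)
    inter = A @ B.T
    if kind == "dot":
        return inter
    if kind == "cosine":
        na = np.sqrt((A * A).sum(axis=1))[:, None]
        nb = np.sqrt((B * B).sum(axis=1))[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = inter / (na * nb)
        return np.nan_to_num(sim)
    # Tanimoto/Jaccard: |A & B| / |A | B|
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = inter / union
    return np.nan_to_num(sim)


def nn_scores(train_X, train_Y, test_X, params: NNParams) -> np.ndarray:
    """k-nearest-neighbor prevalence score: k'/k neighbors carrying the label.

    Neighbors are the k training drugs with the highest fingerprint
    similarity; ties at the k-boundary are resolved by ascending training
    row order (i.e. drug-id order when rows are id-sorted).
    """
    Xtr, Ytr, Xte = _values(train_X), _values(train_Y), _values(test_X)
    if params.k > Xtr.shape[0]:
        raise ValueError(f"k={params.k} exceeds training size {Xtr.shape[0]}")
    sim = _similarity(Xte, Xtr, params.similarity)
    # stable argsort on -sim: equal similarities keep ascending train index
    order = np.argsort(-sim, axis=1, kind="stable")[:, : params.k]
    scores = Ytr[order].mean(axis=1, dtype=float)
    return scores


def svm_scores(train_X, train_Y, test_X, params: SVMParams) -> np.ndarray:
    """One SVM per side-effect; scores are signed decision values.

    RBF kernel k(x, x') = exp(-||x - x'||^2 / (2 sigma^2)).  A label with a
    single class in training cannot be fit; its column is the constant
    value of that class (0 or 1) and the event is logged.
    """
    Xtr, Ytr, Xte = (
        _values(train_X).astype(float),
        _values(train_Y),
        _values(test_X).astype(float),
    )
    q = Ytr.shape[1]
    out = np.zeros((Xte.shape[0], q))
    kernel_kw: dict = {"kernel": params.kernel, "C": params.C, "tol": 1e-7}
    if params.kernel == "rbf":
        kernel_kw["gamma"] = 1.0 / (2.0 * params.sigma**2)
    elif params.kernel == "poly":
        kernel_kw["degree"] = params.degree
    n_single = 0
    for j in range(q):
        y = Ytr[:, j]
        classes = np.unique(y)
        if classes.size < 2:
            out[:, j] = float(classes[0])
            n_single += 1
            continue
        clf = SVC(**kernel_kw)
        clf.fit(Xtr, y)
        out[:, j] = clf.decision_function(Xte)
    if n_single:
        logger.info("svm_scores: %d single-class labels given constant scores", n_single)
    return out
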