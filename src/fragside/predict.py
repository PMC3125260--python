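"""Side-effect prediction for query fingerprints and component extraction.

Two predictors are derived from a fitted model.  The profile estimate maps
a query's canonical components u = A^T x~ back to side-effect space through
the pseudo-inverse of B^T and de-normalizes with the training statistics.
The weighted score s(x) = B Lambda A^T x~ sums the canonical components
weighted by their canonical correlations; it is used for ranking only and
is deliberately left on the canonical scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cca import CCAModel
from .profiles import BinaryProfileMatrix, apply_normalizer, denormalize

__all__ = [
    "PredictionResult",
    "ComponentSet",
    "predict_profile_pinv",
    "predict_score_weighted",
    "predict_matrix",
    "extract_component_sets",
]

# relative cutoff below which singular values of B^T are treated as zero;
# B can be rank-deficient under strong sparsity
_PINV_RCOND = 1e-10


@dataclass
class PredictionResult:
    drug_id: str
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite prediction scores")


@dataclass
class ComponentSet:
    component_index: int  # 1-based
    substructures: list[tuple[str, float]]
    side_effects: list[tuple[str, float]]
    rho: float
    pvalue: float | None = None


def _query_array(x, p: int) -> tuple[np.ndarray, bool]:
    V = x.values if isinstance(x, BinaryProfileMatrix) else np.asarray(x, dtype=float)
    squeeze = V.ndim == 1
    V = np.atleast_2d(V)
    if V.shape[1] != p:
        raise ValueError(f"query has {V.shape[1]} features, model expects {p}")
    return V, squeeze


def predict_matrix(model: CCAModel, X, method: str = "weighted") -> np.ndarray:
    """Score a batch of query fingerprints; rows are drugs, columns side-effects."""
    V, squeeze = _query_array(X, model.p)
    Xt = apply_normalizer(model.x_norm, V) if model.x_norm is not None else V
    U = Xt @ model.A  # n x m canonical components
    if method == "pinv":
        P = np.linalg.pinv(model.B.T, rcond=_PINV_RCOND)  # q x m
        Yn_hat = U @ P.T
        out = denormalize(model.y_norm, Yn_hat) if model.y_norm is not None else Yn_hat
    elif method == "weighted":
        out = U @ np.diag(model.rho) @ model.B.T
    else:
        raise ValueError(f"unknown prediction method {method!r}")
    return out[0] if squeeze else out


def predict_profile_pinv(model: CCAModel, x, drug_id: str = "query") -> PredictionResult:
    """De-normalized profile estimate y^ = pinv(B^T) A^T x~ for one query."""
    scores = predict_matrix(model, np.asarray(x, dtype=float), method="pinv")
    return PredictionResult(drug_id=drug_id, scores=scores, method="pinv")


def predict_score_weighted(
    model: CCAModel, x, drug_id: str = "query"
) -> PredictionResult:
    """Correlation-weighted ranking score s(x) = B Lambda A^T x~ for one query."""
    scores = predict_matrix(model, np.asarray(x, dtype=float), method="weighted")
    return PredictionResult(drug_id=drug_id, scores=scores, method="weighted")


def extract_component_sets(
    model: CCAModel, min_abs_weight: float = 0.0
) -> list[ComponentSet]:
    """Per component, the features with |weight| above the cutoff.

    Lists are sorted by |weight| descending; this is the interpretable
    output of the method — each component pairs a small set of chemical
    substructures with the side-effects they co-vary with.
    """
    x_names = model.x_names or [f"x{j}" for j in range(model.p)]
    y_names = model.y_names or [f"y{j}" for j in range(model.q)]
    sets = []
    for k in range(model.m):

        def top(weights, names):
            idx = np.where(np.abs(weights) > min_abs_weight)[0]
            idx = idx[np.argsort(-np.abs(weights[idx]), kind="stable")]
            return [(names[j], float(weights[j])) for j in idx]

        sets.append(
            ComponentSet(
                component_index=k + 1,
                substructures=top(model.A[:, k], x_names),
                side_effects=top(model.B[:, k], y_names),
                rho=float(model.rho[k]),
            )
        )
    return sets
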