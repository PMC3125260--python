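"""Canonical correlation of substructure and side-effect profiles.

Two fits are provided for the cross-product matrix Z = Xn^T Yn of the
column-normalized profiles:

* OCCA — ordinary CCA under the diagonal-covariance approximation, which
  replaces the within-set covariances X^T X and Y^T Y with identity and so
  reduces to the truncated SVD of Z.
* SCCA — sparse CCA, maximizing alpha^T Z beta subject to unit Euclidean
  norm and L1 bounds ||alpha||_1 <= c1*sqrt(p), ||beta||_1 <= c2*sqrt(q)
  (c1, c2 in (0, 1], the fraction convention of the PMA package).  Each
  component is a rank-1 penalized matrix decomposition found by alternating
  soft-thresholded power updates; subsequent components are extracted by
  deflation Z^(k+1) = Z^(k) - d_k * alpha_k beta_k^T.

Weight signs are adjusted so the largest-|.| entry of each alpha_k is
positive, flipping (alpha_k, beta_k) as a pair to preserve the objective.
Canonical correlations rho_k are the Pearson correlations of the component
scores u = Xn alpha_k and v = Yn beta_k; their significance is assessed by
a row-permutation test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import Normalizer

logger = logging.getLogger("fragside")

# extra axis-aligned starts per rank-1 solve (beyond the primary init)
_N_AXIS_RESTARTS = 8

__all__ = [
    "SCCAParams",
    "CCAModel",
    "cross_product",
    "occa_fit",
    "soft_threshold",
    "l1_bound_search",
    "rank1_pmd",
    "scca_fit",
    "adjust_signs",
    "canonical_correlation",
    "permutation_pvalue",
    "save_model",
    "load_model",
]


@dataclass
class SCCAParams:
    """Sparsity fractions, component count and solver controls.

    c1 and c2 scale the L1 budgets: a unit-norm dim-vector has L1 norm in
    [1, sqrt(dim)], so the bound c*sqrt(dim) spans "one nonzero" (c near
    1/sqrt(dim)) to "unconstrained" (c = 1).
    """

    c1: float = 1.0
    c2: float = 1.0
    m: int = 1
    tol: float = 1e-7
    max_iter: int = 200
    init: str = "svd"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.c1 <= 1 or not 0 < self.c2 <= 1:
            raise ValueError("c1 and c2 must be in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.init not in ("svd", "random"):
            raise ValueError("init must be 'svd' or 'random'")


@dataclass
class CCAModel:
    """Fitted weight matrices A (p x m), B (q x m), singular values and rho."""

    A: np.ndarray
    B: np.ndarray
    d: np.ndarray
    rho: np.ndarray
    x_norm: Normalizer | None = None
    y_norm: Normalizer | None = None
    params: SCCAParams | None = None
    x_names: list[str] | None = None
    y_names: list[str] | None = None

    @property
    def m(self) -> int:
        return self.A.shape[1]

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def q(self) -> int:
        return self.B.shape[0]


def cross_product(Xn: np.ndarray, Yn: np.ndarray) -> np.ndarray:
    """Z = Xn^T Yn, the p x q cross-product the decomposition acts on."""
    Xn = np.asarray(Xn, dtype=float)
    Yn = np.asarray(Yn, dtype=float)
    if Xn.shape[0] != Yn.shape[0]:
        raise ValueError(f"row mismatch: {Xn.shape[0]} vs {Yn.shape[0]}")
    return Xn.T @ Yn


def occa_fit(Z: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-m singular triples of Z (diagonal-covariance CCA), signs adjusted.

    Returns (A, B, d) with A p x m, B q x m, d the top-m singular values.
    """
    Z = np.asarray(Z, dtype=float)
    if not 1 <= m <= min(Z.shape):
        raise ValueError(f"m={m} out of range 1..{min(Z.shape)}")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    A, B, d = U[:, :m].copy(), Vt[:m].T.copy(), s[:m].copy()
    A, B = adjust_signs(A, B)
    return A, B, d


def soft_threshold(v: np.ndarray, delta: float) -> np.ndarray:
    """sign(v) * max(|v| - delta, 0), the proximal map of the L1 penalty."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - delta, 0.0)


def l1_bound_search(v: np.ndarray, bound: float, tol: float = 1e-10) -> float:
    """Smallest delta >= 0 with ||S(v,delta)/||S(v,delta)||_2||_1 <= bound.

    Bisection on [0, max|v|]; the L1 norm of the renormalized thresholded
    vector decreases monotonically in delta, from ||v||_1/||v||_2 down to 1.
    """
    v = np.asarray(v, dtype=float)
    if not np.any(v):
        raise ValueError("v must be nonzero")
    if bound < 1:
        raise ValueError("bound must be >= 1 (unit-norm vectors have L1 norm >= 1)")

    def l1_at(delta: float) -> float:
        w = soft_threshold(v, delta)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 1.0  # only the top entries survive in the limit
        return float(np.abs(w).sum() / nrm)

    if l1_at(0.0) <= bound:
        return 0.0
    lo, hi = 0.0, float(np.abs(v).max())
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if l1_at(mid) <= bound:
            hi = mid
        else:
            lo = mid
    return hi


def _constrained_unit(v: np.ndarray, bound: float) -> np.ndarray:
    """Soft-threshold v to meet the L1 bound, then renormalize to unit L2."""
    if not np.any(v):
        return np.zeros_like(np.asarray(v, dtype=float))
    delta = l1_bound_search(v, bound)
    w = soft_threshold(v, delta)
    nrm = np.linalg.norm(w)
    if nrm == 0:
        # degenerate: keep only the largest-|.| entry
        w = np.zeros_like(v)
        i = int(np.argmax(np.abs(v)))
        w[i] = np.sign(v[i])
        return w
    return w / nrm


def rank1_pmd(
    Z: np.ndarray, c1: float, c2: float, params: SCCAParams | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """One penalized rank-1 factor of Z by alternating thresholded updates.

    Maximizes alpha^T Z beta over unit-norm alpha, beta with
    ||alpha||_1 <= c1*sqrt(p) and ||beta||_1 <= c2*sqrt(q).  The alternating
    scheme only guarantees a local maximum under active L1 constraints, so
    it is restarted from the leading right singular vector (or a seeded
    Gaussian for init="random") and from axis vectors on the largest
    columns of Z; the start with the best objective wins.  Returns
    (alpha, beta, d) with d = alpha^T Z beta >= 0.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.any(Z):
        raise ValueError("Z must be nonzero")
    if params is None:
        params = SCCAParams(c1=c1, c2=c2)
    p, q = Z.shape
    # a unit-norm vector has L1 norm >= 1, so budgets below 1 clamp to the
    # maximally sparse limit (a single nonzero weight)
    bound1 = max(c1 * np.sqrt(p), 1.0)
    bound2 = max(c2 * np.sqrt(q), 1.0)

    starts: list[np.ndarray] = []
    if params.init == "random":
        rng = np.random.default_rng(params.seed)
        starts.append(rng.standard_normal(q))
    else:
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        starts.append(Vt[0])
    # axis restarts on the heaviest columns guard against local optima
    col_norms = np.linalg.norm(Z, axis=0)
    for j in np.argsort(-col_norms, kind="stable")[: min(q, _N_AXIS_RESTARTS)]:
        if col_norms[j] > 0:
            starts.append(np.eye(q)[j])

    def alternate(beta0: np.ndarray):
        beta_l = beta0 / np.linalg.norm(beta0)
        alpha_l = np.zeros(p)
        for _ in range(params.max_iter):
            alpha_new = _constrained_unit(Z @ beta_l, bound1)
            beta_new = _constrained_unit(Z.T @ alpha_new, bound2)
            change = max(
                np.max(np.abs(alpha_new - alpha_l)),
                np.max(np.abs(beta_new - beta_l)),
            )
            alpha_l, beta_l = alpha_new, beta_new
            if change < params.tol:
                return alpha_l, beta_l, True
        return alpha_l, beta_l, False

    best = None
    for beta0 in starts:
        alpha, beta, converged = alternate(beta0)
        d = float(alpha @ Z @ beta)
        if d < 0:  # flip to keep the factor weight non-negative
            beta, d = -beta, -d
        if best is None or d > best[2] + 1e-12:
            best = (alpha, beta, d, converged)
    alpha, beta, d, converged = best
    if not converged:
        logger.warning(
            "rank1_pmd: best start's change still >= tol=%.1e after %d iterations",
            params.tol,
            params.max_iter,
        )
    return alpha, beta, d


def adjust_signs(
    A: np.ndarray, B: np.ndarray, paired: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-|.| weight positive in each component.

    Keyed on alpha_k: if its maximal-magnitude entry (earliest index on
    ties) is negative, alpha_k and beta_k flip together, preserving
    alpha^T Z beta.  With paired=False, beta_k is additionally flipped on
    its own when its maximal entry remains negative.
    """
    A = np.array(A, dtype=float, copy=True)
    B = np.array(B, dtype=float, copy=True)
    for k in range(A.shape[1]):
        a, b = A[:, k], B[:, k]
        if np.any(a) and a[int(np.argmax(np.abs(a)))] < 0:
            a *= -1
            b *= -1
        if not paired and np.any(b) and b[int(np.argmax(np.abs(b)))] < 0:
            b *= -1
    return A, B


def canonical_correlation(
    Xn: np.ndarray, Yn: np.ndarray, alpha: np.ndarray, beta: np.ndarray
) -> float:
    """Pearson correlation of the component scores u = Xn alpha, v = Yn beta.

    Returns NaN when either score has zero variance.
    """
    u = np.asarray(Xn, dtype=float) @ alpha
    v = np.asarray(Yn, dtype=float) @ beta
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return float("nan")
    return float(((u - u.mean()) * (v - v.mean())).mean() / (su * sv))


def scca_fit(
    Xn: np.ndarray,
    Yn: np.ndarray,
    params: SCCAParams,
    x_norm: Normalizer | None = None,
    y_norm: Normalizer | None = None,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> CCAModel:
    """Extract m sparse canonical components by successive rank-1 PMD.

    After each component, Z is deflated by d_k * alpha_k beta_k^T, so the
    accumulated factors plus the residual reconstruct Z^(1) exactly.  Stops
    early (with a log message) if the residual reaches numerical zero.
    """
    Xn = np.asarray(Xn, dtype=float)
    Yn = np.asarray(Yn, dtype=float)
    Z = cross_product(Xn, Yn)
    p, q = Z.shape
    zero_scale = 1e-12 * max(1.0, float(np.abs(Z).max(initial=0.0)))

    alphas, betas, ds = [], [], []
    Zk = Z.copy()
    for k in range(params.m):
        if np.abs(Zk).max(initial=0.0) <= zero_scale:
            logger.info("scca_fit: residual numerically zero after %d components", k)
            break
        alpha, beta, d = rank1_pmd(Zk, params.c1, params.c2, params)
        alphas.append(alpha)
        betas.append(beta)
        ds.append(d)
        Zk = Zk - d * np.outer(alpha, beta)

    if not alphas:
        raise ValueError("cross-product matrix is numerically zero; nothing to fit")
    A = np.column_stack(alphas)
    B = np.column_stack(betas)
    A, B = adjust_signs(A, B)
    rho = np.array(
        [canonical_correlation(Xn, Yn, A[:, k], B[:, k]) for k in range(A.shape[1])]
    )
    return CCAModel(
        A=A,
        B=B,
        d=np.asarray(ds),
        rho=rho,
        x_norm=x_norm,
        y_norm=y_norm,
        params=params,
        x_names=x_names,
        y_names=y_names,
    )


def permutation_pvalue(
    Xn: np.ndarray,
    Yn: np.ndarray,
    params: SCCAParams,
    component_index: int = 0,
    n_perm: int = 99,
    seed: int = 0,
) -> float:
    """Row-permutation p-value for a component's canonical correlation.

    The rows of Yn are shuffled, the first component refitted, and the
    add-one estimator p = (1 + #{rho* >= rho_obs}) / (1 + n_perm) returned.
    Components beyond the first are reached by deflating the observed
    factors before the test statistic is computed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xn = np.asarray(Xn, dtype=float)
    Yn = np.asarray(Yn, dtype=float)
    fit_params = SCCAParams(
        c1=params.c1, c2=params.c2, m=component_index + 1,
        tol=params.tol, max_iter=params.max_iter, init=params.init, seed=params.seed,
    )
    model = scca_fit(Xn, Yn, fit_params)
    k = min(component_index, model.m - 1)
    rho_obs = model.rho[k]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(Yn.shape[0])
        Yp = Yn[perm]
        alpha, beta, _ = rank1_pmd(cross_product(Xn, Yp), params.c1, params.c2, params)
        rho_star = canonical_correlation(Xn, Yp, alpha, beta)
        if not np.isnan(rho_star) and rho_star >= rho_obs:
            count += 1
    return (1 + count) / (1 + n_perm)


# --- model serialization: a directory of labeled TSV/JSON files ---------------


def save_model(model: CCAModel, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    x_names = model.x_names or [f"x{j}" for j in range(model.p)]
    y_names = model.y_names or [f"y{j}" for j in range(model.q)]
    comp = [f"c{k + 1}" for k in range(model.m)]
    pd.DataFrame(model.A, index=x_names, columns=comp).to_csv(out / "A.tsv", sep="\t")
    pd.DataFrame(model.B, index=y_names, columns=comp).to_csv(out / "B.tsv", sep="\t")
    pd.Series(model.d, index=comp, name="d").to_csv(out / "d.tsv", sep="\t")
    pd.Series(model.rho, index=comp, name="rho").to_csv(out / "rho.tsv", sep="\t")
    norms = {}
    for key, nm in (("x", model.x_norm), ("y", model.y_norm)):
        if nm is not None:
            norms[key] = {
                "means": nm.means.tolist(),
                "sds": nm.sds.tolist(),
                "zero_var_mask": nm.zero_var_mask.astype(int).tolist(),
            }
    (out / "normalizers.json").write_text(json.dumps(norms))
    if model.params is not None:
        (out / "params.json").write_text(json.dumps(vars(model.params)))


def load_model(modeldir: str | Path) -> CCAModel:
    d = Path(modeldir)
    A = pd.read_csv(d / "A.tsv", sep="\t", index_col=0)
    B = pd.read_csv(d / "B.tsv", sep="\t", index_col=0)
    dvals = pd.read_csv(d / "d.tsv", sep="\t", index_col=0)["d"].to_numpy()
    rho = pd.read_csv(d / "rho.tsv", sep="\t", index_col=0)["rho"].to_numpy()
    norms = json.loads((d / "normalizers.json").read_text())

    def mk_norm(entry):
        if entry is None:
            return None
        return Normalizer(
            means=np.array(entry["means"]),
            sds=np.array(entry["sds"]),
            zero_var_mask=np.array(entry["zero_var_mask"], dtype=bool),
        )

    params = None
    pfile = d / "params.json"
    if pfile.exists():
        params = SCCAParams(**json.loads(pfile.read_text()))
    return CCAModel(
        A=A.to_numpy(),
        B=B.to_numpy(),
        d=dvals,
        rho=rho,
        x_norm=mk_norm(norms.get("x")),
        y_norm=mk_norm(norms.get("y")),
        params=params,
        x_names=list(A.index),
        y_names=list(B.index),
    )
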