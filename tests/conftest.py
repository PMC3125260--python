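import numpy as np
import pytest

import fragside as fs


@pytest.fixture(scope="session")
def planted():
    """Planted two-component dataset at the package's study conditions."""
    comps = fs.default_planted_components(p=50, q=40)
    X, Y, truth = fs.generate_planted_dataset(
        n=500, p=50, q=40, components=comps, background_rate=0.05, seed=11
    )
    return X, Y, truth


@pytest.fixture(scope="session")
def planted_model(planted):
    """SCCA fit of the planted dataset (c1=c2=0.3, m=4)."""
    X, Y, _ = planted
    xn, yn = fs.fit_normalizer(X), fs.fit_normalizer(Y)
    model = fs.scca_fit(
        fs.apply_normalizer(xn, X.values),
        fs.apply_normalizer(yn, Y.values),
        fs.SCCAParams(c1=0.3, c2=0.3, m=4),
        x_norm=xn,
        y_norm=yn,
        x_names=X.col_names,
        y_names=Y.col_names,
    )
    return model


def pairwise_auc(scores, labels) -> float:
    """Exhaustive pairwise half-credit AUC oracle (independent of roc_auc)."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for sp in pos:
        total += (sp > neg).sum() + 0.5 * (sp == neg).sum()
    return total / (len(pos) * len(neg))


def feasible_point_oracle(Z, c1, c2, n_samples=100_000, seed=0) -> float:
    """Best alpha^T Z beta over random feasible pairs plus axis candidates.

    Feasible points are random unit vectors sharpened toward sparsity so the
    L1 constraints accept a usable fraction; axis-aligned candidates cover
    the maximally sparse corners exactly.
    """
    Z = np.asarray(Z, dtype=float)
    p, q = Z.shape
    b1, b2 = c1 * np.sqrt(p), c2 * np.sqrt(q)
    rng = np.random.default_rng(seed)

    def sample_feasible(dim, bound, count):
        out = []
        got = 0
        while got < count:
            G = rng.standard_normal((count * 4, dim))
            k = rng.uniform(0.0, 8.0, size=(count * 4, 1))
            W = np.sign(G) * np.abs(G) ** (1.0 + k)
            W /= np.linalg.norm(W, axis=1, keepdims=True)
            ok = np.abs(W).sum(axis=1) <= bound
            W = W[ok]
            out.append(W)
            got += W.shape[0]
        return np.vstack(out)[:count]

    A = sample_feasible(p, b1, n_samples)
    B = sample_feasible(q, b2, n_samples)
    best = float(np.max(np.einsum("ij,jk,ik->i", A, Z, B)))
    best = max(best, float(np.abs(Z).max()))  # all axis-pair candidates
    return best
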