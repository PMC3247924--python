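import numpy as np
import pytest

from rmrcm.alignment import Alignment, decode


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_alignment(rng):
    """Small random alignment over a 4-letter sub-alphabet (levels 1-4)."""
    A = rng.integers(1, 5, size=(40, 5))
    return decode(A)


@pytest.fixture
def coupled_alignment(rng):
    """Two-column alignment where column 2 is a deterministic relabeling of
    column 1 (perfect coupling), 200 sequences."""
    a = rng.integers(1, 6, size=200)
    b = ((a + 2) % 5) + 1  # bijective map of levels
    return decode(np.column_stack([a, b]))


def brute_force_penalized_fit(y, X, classes, lam, alpha, seed=0):
    """Independent oracle: maximize (1/n)*loglik - lam*P_alpha(beta) by
    L-BFGS-B on the split beta = beta+ - beta- formulation (smooth convex
    problem with nonnegativity bounds)."""
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    K = len(classes)
    Y = (y[:, None] == np.asarray(classes)[None, :]).astype(float)
    yidx = np.searchsorted(classes, y)

    def fun(z):
        bp = z[: p * K].reshape(p, K)
        bn = z[p * K : 2 * p * K].reshape(p, K)
        io = z[2 * p * K :]
        B = bp - bn
        eta = io[None, :] + X @ B
        m = eta.max(axis=1, keepdims=True)
        E = np.exp(eta - m)
        lse = m[:, 0] + np.log(E.sum(axis=1))
        ll = (eta[np.arange(n), yidx] - lse).sum()
        pen = (1 - alpha) * 0.5 * (B**2).sum() + alpha * (bp + bn).sum()
        P = E / E.sum(axis=1, keepdims=True)
        G = X.T @ (P - Y) / n
        gb = G + (1 - alpha) * lam * B + alpha * lam
        gn = -G - (1 - alpha) * lam * B + alpha * lam
        gi = (P - Y).sum(axis=0) / n
        return -(ll / n - lam * pen), np.concatenate([gb.ravel(), gn.ravel(), gi])

    res = minimize(
        fun,
        np.zeros(2 * p * K + K),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p * K) + [(None, None)] * K,
        options=dict(maxiter=50000, ftol=1e-15, gtol=1e-12),
    )
    bp = res.x[: p * K].reshape(p, K)
    bn = res.x[p * K : 2 * p * K].reshape(p, K)
    return -res.fun, bp - bn, res.x[2 * p * K :]


def objective_value(y, X, classes, B, io, lam, alpha):
    """(1/n)*loglik - lam*P_alpha on the observed-class parameterization."""
    from scipy.special import logsumexp

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    eta = io[None, :] + X @ B
    yidx = np.searchsorted(classes, np.asarray(y))
    ll = float(np.sum(eta[np.arange(n), yidx] - logsumexp(eta, axis=1)))
    pen = float(((1 - alpha) * 0.5 * B**2 + alpha * np.abs(B)).sum())
    return ll / n - lam * pen
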