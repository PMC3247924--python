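"""Regularized multinomial regression of alignment columns (RMRCM).

Every alignment column in turn is the response ``y`` (a 21-level factor)
and the one-hot indicator columns of all *other* alignment columns form the
predictor matrix ``X``.  For each response a full elastic-net path of
penalized multinomial fits is computed:

    maximize_beta  (1/n) * l(y, X, beta) - lambda * P_alpha(beta)

with ``l`` the multinomial log-likelihood in the symmetric (one linear
predictor per class) parameterization, and

    P_alpha(beta) = sum_j (1 - alpha) * beta_j**2 / 2 + alpha * |beta_j|.

Nonzero coefficients mark predicted links between columns.  Per-column
scores are projected to a symmetric column-column link matrix either from
the minimum-BIC model, from the coefficient sum over the whole path
(the default, ``path_sum``), or from the count of path models containing
the link.

The solver is a coordinate-descent partial-Newton scheme (per-class
quadratic approximation, soft-threshold updates, active sets grown by
KKT checks, warm starts along the path), written against the binary
structure of the indicator predictors so that each coordinate visit only
touches the rows where the indicator is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .alignment import Alignment, N_STATES, encode

logger = logging.getLogger("rmrcm")

__all__ = [
    "FitConfig",
    "CoefficientPath",
    "LinkMatrix",
    "multinomial_loglik",
    "elastic_net_penalty",
    "penalized_objective",
    "fit_column_path",
    "bic_select",
    "project_links",
    "rmrcm",
    "molecule_predictor_mask",
]


@dataclass
class FitConfig:
    """Settings for the per-column elastic-net path.

    alpha is the lasso/ridge mixing weight (0.99: almost pure lasso with a
    whiff of ridge for stability).  The lambda path has ``n_lambda``
    log-spaced values from the smallest all-zero lambda downward;
    ``lambda_min_ratio`` defaults to 0.01 when n_seq < n_predictors and
    0.0001 otherwise.  ``predictor_mask`` optionally restricts, per
    response column, which original columns may serve as predictors
    (inter/intra-molecular analyses).
    """

    alpha: float = 0.99
    n_lambda: int = 100
    lambda_min_ratio: Optional[float] = None
    standardize: bool = True
    predictor_mask: Optional[dict] = None
    tol: float = 1e-7
    max_passes: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be >= 1")


@dataclass
class CoefficientPath:
    """Per-response-column fit path.

    ``coefficients[k]`` is the (n_predictors, n_classes) table at
    ``lambdas[k]`` on the original indicator scale; ``classes`` are the
    observed response levels (subset of 1..21) the table's columns refer
    to.  ``predictor_cols`` gives, for each predictor, the index of the
    indicator column in the full matrix ``M`` it came from.
    """

    response_column: int
    classes: np.ndarray
    predictor_cols: np.ndarray
    lambdas: np.ndarray
    coefficients: list
    intercepts: np.ndarray  # (n_lambda, n_classes)
    loglik: np.ndarray
    n_nonzero: np.ndarray
    degenerate: bool = False


@dataclass
class LinkMatrix:
    """Symmetric column-column link scores (the method's output)."""

    scores: np.ndarray
    scoring_mode: str
    column_labels: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = self.scores.shape[0]
        if self.column_labels is None:
            self.column_labels = np.arange(1, n + 1)
        self.column_labels = np.asarray(self.column_labels)

    @property
    def n_col(self) -> int:
        return self.scores.shape[0]

    def pairs(self):
        """Yield (label_i, label_j, score) over unordered pairs, descending
        score; ties broken by ascending pair index."""
        n = self.n_col
        iu = np.triu_indices(n, k=1)
        s = self.scores[iu]
        order = np.lexsort((iu[1], iu[0], -s))
        for k in order:
            yield (
                int(self.column_labels[iu[0][k]]),
                int(self.column_labels[iu[1][k]]),
                float(s[k]),
            )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("col_i\tcol_j\tscore\tscoring_mode\n")
            for i, j, s in self.pairs():
                fh.write(f"{i}\t{j}\t{s:.8g}\t{self.scoring_mode}\n")


# ---------------------------------------------------------------------------
# likelihood and penalty primitives


def multinomial_loglik(y, X, beta, intercepts) -> float:
    """Symmetric-form multinomial log-likelihood sum_i [eta_{i,y_i} -
    log sum_c exp(eta_{i,c})] with eta = intercepts + X @ beta.

    ``y`` holds 1-based class levels indexing the columns of ``beta``.
    """
    y = np.asarray(y)
    beta = np.asarray(beta, dtype=float)
    intercepts = np.asarray(intercepts, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(intercepts))):
        raise ValueError("non-finite coefficients")
    eta = intercepts[None, :] + np.asarray(X, dtype=float) @ beta
    lse = logsumexp(eta, axis=1)
    rows = np.arange(eta.shape[0])
    return float(np.sum(eta[rows, y - 1] - lse))


def elastic_net_penalty(beta, alpha: float) -> float:
    """P_alpha(beta) = sum_j (1-alpha)*beta_j^2/2 + alpha*|beta_j| over all
    non-intercept coefficients."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    b = np.asarray(beta, dtype=float).ravel()
    return float(np.sum((1.0 - alpha) * 0.5 * b**2 + alpha * np.abs(b)))


def penalized_objective(y, X, beta, intercepts, lam: float, alpha: float) -> float:
    """The maximized quantity: (1/n)*loglik - lambda*P_alpha(beta)."""
    n = len(np.asarray(y))
    return multinomial_loglik(y, X, beta, intercepts) / n - lam * elastic_net_penalty(
        beta, alpha
    )


# ---------------------------------------------------------------------------
# coordinate-descent solver


@njit(cache=True)
def _cd_kernel(
    ones_idx,
    ones_ptr,
    mean,
    scale,
    Y,
    B,
    io,
    E,
    eshift,
    active,
    lam_l1,
    lam_l2,
    inner_tol,
    max_cycles,
):
    """Partial-Newton coordinate descent on the active set.

    State: B (std-scale coefficients), io (std-scale intercepts), and the
    linear predictor eta decomposed as E[i,c] + eshift[c] where E collects
    the sparse (indicator==1) contributions and eshift the dense mean
    corrections -- so eshift is also the original-scale intercept and
    B[j,c]/scale[j] the original-scale coefficient.
    """
    n, K = Y.shape
    p = mean.shape[0]
    P = np.empty((n, K))
    w = np.empty(n)
    R = np.empty(n)
    for _cycle in range(max_cycles):
        cyc_max = 0.0
        for c in range(K):
            # fresh class probabilities (partial Newton re-linearization)
            for i in range(n):
                mx = E[i, 0] + eshift[0]
                for k2 in range(1, K):
                    v = E[i, k2] + eshift[k2]
                    if v > mx:
                        mx = v
                tot = 0.0
                for k2 in range(K):
                    P[i, k2] = np.exp(E[i, k2] + eshift[k2] - mx)
                    tot += P[i, k2]
                for k2 in range(K):
                    P[i, k2] /= tot
            Sw = 0.0
            SR = 0.0
            for i in range(n):
                pc = P[i, c]
                wv = pc * (1.0 - pc)
                if wv < 1e-5:
                    wv = 1e-5
                w[i] = wv / n
                R[i] = (Y[i, c] - pc) / n
                Sw += w[i]
                SR += R[i]
            kappa = 0.0  # actual residual_i = R[i] + kappa * w[i]
            first_dmax = 0.0
            for _inner in range(100):
                dmax = 0.0
                d0 = (SR + kappa * Sw) / Sw
                if d0 != 0.0:
                    io[c] += d0
                    eshift[c] += d0
                    kappa -= d0
                    chg = Sw * d0 * d0
                    if chg > dmax:
                        dmax = chg
                for j in range(p):
                    if not active[j, c]:
                        continue
                    s = scale[j]
                    mj = mean[j]
                    swo = 0.0
                    sro = 0.0
                    for t in range(ones_ptr[j], ones_ptr[j + 1]):
                        i = ones_idx[t]
                        swo += w[i]
                        sro += R[i]
                    srtot = SR + kappa * Sw
                    sxr = (sro + kappa * swo - mj * srtot) / s
                    swx = (swo * (1.0 - 2.0 * mj) + mj * mj * Sw) / (s * s)
                    bj = B[j, c]
                    z = sxr + swx * bj
                    if z > lam_l1:
                        bn = (z - lam_l1) / (swx + lam_l2)
                    elif z < -lam_l1:
                        bn = (z + lam_l1) / (swx + lam_l2)
                    else:
                        bn = 0.0
                    d = bn - bj
                    if d != 0.0:
                        B[j, c] = bn
                        ds = d / s
                        for t in range(ones_ptr[j], ones_ptr[j + 1]):
                            i = ones_idx[t]
                            R[i] -= w[i] * ds
                            E[i, c] += ds
                        SR -= ds * swo
                        kappa += mj * ds
                        eshift[c] -= mj * ds
                        chg = swx * d * d
                        if chg > dmax:
                            dmax = chg
                if _inner == 0:
                    first_dmax = dmax
                if dmax < inner_tol:
                    break
            # progress made right after re-linearizing this class's
            # quadratic; drives the outer (partial-Newton) convergence
            if first_dmax > cyc_max:
                cyc_max = first_dmax
        if cyc_max < inner_tol:
            return


def _softmax(eta: np.ndarray) -> np.ndarray:
    m = eta.max(axis=1, keepdims=True)
    e = np.exp(eta - m)
    return e / e.sum(axis=1, keepdims=True)


def fit_column_path(y, X, config: FitConfig, response_column: int = 0) -> CoefficientPath:
    """Fit the elastic-net multinomial path for one response column.

    ``y`` holds 1-based levels (1..21); ``X`` is the binary indicator
    predictor matrix with the response column's own indicators (and any
    masked columns) already removed.  ``predictor_cols`` in the result is
    set by :func:`rmrcm`; standalone calls get 0..p-1.
    """
    y = np.asarray(y, dtype=np.int64)
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if n < 1:
        raise ValueError("empty response")
    if X.size and not np.all((X == 0.0) | (X == 1.0)):
        raise ValueError("X must be a binary indicator matrix")
    classes = np.unique(y)
    K = classes.size
    lmr = config.lambda_min_ratio
    if lmr is None:
        lmr = 0.01 if n < p else 1e-4
    pred_cols = np.arange(p)

    if K < 2:
        lambdas = np.geomspace(1.0, lmr, config.n_lambda)
        zero = np.zeros((p, K))
        logger.warning("response column %d is fully conserved; degenerate path",
                       response_column)
        return CoefficientPath(
            response_column=response_column,
            classes=classes,
            predictor_cols=pred_cols,
            lambdas=lambdas,
            coefficients=[zero.copy() for _ in range(config.n_lambda)],
            intercepts=np.zeros((config.n_lambda, K)),
            loglik=np.zeros(config.n_lambda),
            n_nonzero=np.zeros(config.n_lambda, dtype=int),
            degenerate=True,
        )

    Y = (y[:, None] == classes[None, :]).astype(np.float64)
    freq = Y.mean(axis=0)

    counts = X.sum(axis=0)
    mean = counts / n
    var = mean * (1.0 - mean)
    valid = var > 0
    scale = np.where(valid, np.sqrt(np.maximum(var, 1e-300)), 1.0)
    if not config.standardize:
        scale = np.ones(p)

    # CSC-like lists of rows where each indicator is 1
    ones_lists = [np.flatnonzero(X[:, j]).astype(np.int64) for j in range(p)]
    ones_ptr = np.zeros(p + 1, dtype=np.int64)
    for j in range(p):
        ones_ptr[j + 1] = ones_ptr[j] + ones_lists[j].size
    ones_idx = (
        np.concatenate(ones_lists) if p else np.zeros(0, dtype=np.int64)
    ).astype(np.int64)

    # dense standardized predictors (p, n) for BLAS gradient/KKT checks
    Xs = ((X - mean[None, :]) / scale[None, :]).T.copy()
    Xs[~valid, :] = 0.0

    io = np.log(np.maximum(freq, 1e-12))
    io -= io.mean()
    B = np.zeros((p, K))
    E = np.zeros((n, K))
    eshift = io.copy()

    G = Xs @ (np.tile(freq, (n, 1)) - Y) / n
    alpha_eff = max(config.alpha, 1e-3)
    lam_max = np.abs(G[valid]).max() / alpha_eff if valid.any() else 1.0
    if lam_max <= 0:
        lam_max = 1.0
    lambdas = np.geomspace(lam_max, lam_max * lmr, config.n_lambda)

    coefficients = []
    intercepts = np.empty((config.n_lambda, K))
    loglik = np.empty(config.n_lambda)
    n_nonzero = np.empty(config.n_lambda, dtype=int)
    active = np.zeros((p, K), dtype=np.bool_)
    lam_prev = lam_max
    max_cycles = min(50, max(1, config.max_passes // max(1, K)))
    # intercept-only (null) log-likelihood for deviance-based path stopping
    ll_null = float(n * np.sum(freq * np.log(np.maximum(freq, 1e-300))))
    dev_ratio_prev = 0.0
    n_kept = config.n_lambda

    for li, lam in enumerate(lambdas):
        lam_l1 = lam * config.alpha
        lam_l2 = lam * (1.0 - config.alpha)
        # sequential strong rule screening + ever-active warm start
        strong = np.abs(G) > config.alpha * (2.0 * lam - lam_prev)
        active |= strong & valid[:, None]
        active |= B != 0.0
        for _ in range(100):
            _cd_kernel(
                ones_idx,
                ones_ptr,
                mean,
                scale,
                Y,
                B,
                io,
                E,
                eshift,
                active,
                lam_l1,
                lam_l2,
                config.tol,
                max_cycles,
            )
            eta = E + eshift[None, :]
            P = _softmax(eta)
            G = Xs @ (P - Y) / n
            viol = (~active) & valid[:, None] & (np.abs(G) > lam_l1 + 1e-9)
            if viol.any():
                active |= viol
            else:
                break
        lam_prev = lam
        b_orig = B / scale[:, None]
        coefficients.append(b_orig.copy())
        intercepts[li] = eshift
        rows = np.arange(n)
        loglik[li] = float(
            np.sum(eta[rows, np.searchsorted(classes, y)] - logsumexp(eta, axis=1))
        )
        n_nonzero[li] = int(np.count_nonzero(B))
        # stop the path early once the fit saturates (deviance explained
        # > 99.9%) or stops improving, as path solvers conventionally do;
        # beyond this point solutions are noise and convergence crawls
        dev_ratio = 1.0 - loglik[li] / ll_null if ll_null < 0 else 0.0
        if li > 0 and (
            dev_ratio > 0.999
            or (dev_ratio - dev_ratio_prev) < 1e-5 * max(dev_ratio, 1e-12)
        ):
            n_kept = li + 1
            break
        dev_ratio_prev = dev_ratio

    return CoefficientPath(
        response_column=response_column,
        classes=classes,
        predictor_cols=pred_cols,
        lambdas=lambdas[:n_kept],
        coefficients=coefficients[:n_kept],
        intercepts=intercepts[:n_kept],
        loglik=loglik[:n_kept],
        n_nonzero=n_nonzero[:n_kept],
    )


def bic_select(path: CoefficientPath, n: int):
    """Pick the path entry minimizing BIC = -2*loglik + k*ln(n).

    Ties go to the sparser (larger-lambda) entry.  Returns
    ``(index, coefficients, intercepts)``.
    """
    if len(path.coefficients) == 0:
        raise ValueError("empty path")
    bic = -2.0 * path.loglik + path.n_nonzero * np.log(n)
    idx = int(np.argmin(bic))  # first occurrence = largest lambda
    return idx, path.coefficients[idx], path.intercepts[idx]


def _block_scores(coef: np.ndarray, predictor_cols: np.ndarray, n_col: int) -> np.ndarray:
    """Sum |beta| over response classes and over the 21 indicators of each
    original predictor column."""
    scores = np.zeros(n_col)
    col_of = predictor_cols // N_STATES
    np.add.at(scores, col_of, np.abs(coef).sum(axis=1))
    return scores


def project_links(path: CoefficientPath, n_col: int, mode: str = "path_sum",
                  n_seq: Optional[int] = None) -> np.ndarray:
    """Project a fitted path onto per-column link scores.

    ``bic`` scores come from the minimum-BIC fit alone; ``path_sum`` adds
    the |beta| sums over every lambda on the path; ``model_count`` counts
    the path models in which a column's block has any nonzero coefficient.
    """
    if mode == "bic":
        if n_seq is None:
            raise ValueError("mode='bic' needs n_seq")
        _, coef, _ = bic_select(path, n_seq)
        return _block_scores(coef, path.predictor_cols, n_col)
    if mode == "path_sum":
        out = np.zeros(n_col)
        for coef in path.coefficients:
            out += _block_scores(coef, path.predictor_cols, n_col)
        return out
    if mode == "model_count":
        out = np.zeros(n_col)
        for coef in path.coefficients:
            out += _block_scores(coef, path.predictor_cols, n_col) > 0
        return out
    raise ValueError(f"unknown scoring mode: {mode!r}")


def molecule_predictor_mask(molecule_labels: np.ndarray, mode: str) -> dict:
    """Allowed predictor columns per response column for two-molecule data.

    ``intermolecular_only`` keeps only the partner molecule's columns;
    ``inter_and_intra`` keeps every other column (the default behaviour of
    an unmasked fit).
    """
    labels = np.asarray(molecule_labels)
    n_col = labels.size
    mask = {}
    for i in range(n_col):
        if mode == "intermolecular_only":
            allowed = np.flatnonzero(labels != labels[i])
        elif mode == "inter_and_intra":
            allowed = np.flatnonzero(np.arange(n_col) != i)
        else:
            raise ValueError(f"unknown mask mode: {mode!r}")
        mask[i] = allowed
    return mask


def _predictor_columns(i: int, n_col: int, config: FitConfig) -> np.ndarray:
    if config.predictor_mask is not None:
        allowed = np.asarray(config.predictor_mask[i])
        allowed = allowed[allowed != i]
    else:
        allowed = np.array([j for j in range(n_col) if j != i])
    return allowed


def fit_alignment_paths(aln: Alignment, config: FitConfig) -> list[CoefficientPath]:
    """Fit one coefficient path per alignment column."""
    enc = encode(aln)
    n_col = enc.n_col
    paths = []
    for i in range(n_col):
        allowed = _predictor_columns(i, n_col, config)
        ind_cols = enc.column_map[allowed].ravel()
        X = enc.M[:, ind_cols]
        path = fit_column_path(enc.A[:, i], X, config, response_column=i)
        path.predictor_cols = ind_cols
        logger.debug("column %d/%d fitted (%d lambdas)", i + 1, n_col,
                     len(path.lambdas))
        paths.append(path)
    return paths


def rmrcm(aln: Alignment, config: Optional[FitConfig] = None,
          mode: str = "path_sum", column_labels=None) -> LinkMatrix:
    """Full RMRCM: per-column paths, projection, symmetrization.

    The alignment should already be gap-filtered.  Scores are symmetrized
    by averaging score(i -> j) and score(j -> i); the diagonal is zero.
    ``column_labels`` (1-based original column numbers) default to
    1..n_col.
    """
    if config is None:
        config = FitConfig()
    if aln.n_col < 2:
        raise ValueError("need at least 2 columns")
    paths = fit_alignment_paths(aln, config)
    n_col = aln.n_col
    S = np.zeros((n_col, n_col))
    for i, path in enumerate(paths):
        S[i] = project_links(path, n_col, mode=mode, n_seq=aln.n_seq)
        S[i, i] = 0.0
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 0.0)
    return LinkMatrix(scores=S, scoring_mode=mode, column_labels=column_labels)
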