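"""Fast logistic-regression internals.

The association tests reduce to likelihood-ratio chi-square statistics of
binary phenotypes on small score designs.  The supervised-PCA permutation
null re-fits thousands of single-predictor logistic models per dataset, so
the fitters here are written as vectorised Newton iterations rather than
going through a general GLM framework; statsmodels is used as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

_MAX_ABS_ETA = 30.0  # |linear predictor| beyond this flags separation
_RIDGE = 1e-4


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _null_loglik(y: np.ndarray) -> float:
    n = y.size
    ybar = float(y.mean())
    if ybar in (0.0, 1.0):
        return 0.0
    return n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))


def _drop_dependent_columns(X: np.ndarray, tol: float = 1e-9):
    """Indices of a maximal linearly independent, non-constant column subset."""
    n, p = X.shape
    keep: list[int] = []
    basis = np.empty((n, 0))
    for j in range(p):
        col = X[:, j] - X[:, j].mean()
        norm0 = np.linalg.norm(col)
        if norm0 < tol * np.sqrt(n):
            continue  # constant column carries no information
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col
        if np.linalg.norm(resid) > tol * norm0:
            keep.append(j)
            basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
    return keep


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    *,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-10,
):
    """Newton fit of logistic regression with intercept.

    Returns (beta, loglik, converged, separated).  ``X`` must not contain an
    intercept column; one is prepended.  A ridge penalty (not applied to the
    intercept) stabilises separated fits.
    """
    n = y.size
    Xd = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    k = Xd.shape[1]
    beta = np.zeros(k)
    ybar = float(y.mean())
    beta[0] = np.log(ybar / (1 - ybar))
    pen = np.zeros(k)
    pen[1:] = ridge
    converged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        grad = Xd.T @ (y - mu) - pen * beta
        hess = (Xd * w[:, None]).T @ Xd + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # dampen exploding steps (separation)
        stepmax = np.max(np.abs(step))
        if stepmax > 10.0:
            step *= 10.0 / stepmax
        beta = beta + step
        if stepmax < tol:
            converged = True
            break
    eta = Xd @ beta
    separated = bool(np.max(np.abs(eta)) > _MAX_ABS_ETA or not converged)
    return beta, _loglik(eta, y), converged, separated


def logistic_lrt(y, X):
    """Likelihood-ratio chi-square of logistic ``y ~ X`` vs intercept only.

    Rank-deficient and constant columns are dropped with a warning; perfect
    separation triggers a ridge-penalised refit whose statistic is reported
    with a diagnostic flag.  Returns (statistic, df, p_value, diagnostics).

    Raises
    ------
    ValueError : if ``y`` contains a single class.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("phenotype must contain both classes")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    diagnostics: dict = {}
    keep = _drop_dependent_columns(X)
    if len(keep) < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(keep))
        diagnostics["dropped_columns"] = dropped
        if keep:
            warnings.warn(
                f"dropped {len(dropped)} dependent/constant design column(s)",
                stacklevel=2,
            )
    df = len(keep)
    if df == 0:
        return 0.0, 0, 1.0, diagnostics
    Xk = X[:, keep]
    beta, ll, converged, separated = fit_logistic(y, Xk)
    if separated:
        beta, ll, _, _ = fit_logistic(y, Xk, ridge=_RIDGE, max_iter=200)
        diagnostics["separation_fallback"] = True
    stat = max(2.0 * (ll - _null_loglik(y)), 0.0)
    p = float(stats.chi2.sf(stat, df))
    return float(stat), df, p, diagnostics


def lrt_single_batch(x: np.ndarray, Y: np.ndarray, *, max_iter: int = 8):
    """Row-wise logistic LRT statistics: ``Y[m, :] ~ x[m, :]``.

    Vectorised two-parameter Newton iteration (intercept + slope per row),
    started at the intercept-only fit; iteration stops when every row's step
    is below 1e-9 or after ``max_iter`` sweeps.  Rows where the fit diverges
    (separation) are refit with a small ridge penalty.  Arrays are laid out
    (M, n) so the per-fit reductions run over contiguous memory.

    Parameters
    ----------
    x : (M, n) predictor rows.
    Y : (M, n) binary outcome rows.

    Returns
    -------
    (M,) array of 2*(ll_full - ll_null) statistics.
    """
    x = np.ascontiguousarray(x)
    Y = np.ascontiguousarray(Y, dtype=x.dtype)
    M, n = Y.shape
    dt = x.dtype
    step_tol = 1e-9 if dt == np.float64 else 1e-5
    ybar = Y.mean(axis=1, dtype=np.float64)
    a = np.log(ybar / (1.0 - ybar))
    b = np.zeros(M)
    # per-row constants of the score equations
    sum_y = ybar * n
    sum_yx = np.einsum("mn,mn->m", Y, x, dtype=np.float64)
    x2 = x * x
    eta = np.empty_like(x)
    buf = np.empty_like(x)
    for _ in range(max_iter):
        np.multiply(b[:, None].astype(dt), x, out=eta)
        eta += a[:, None].astype(dt)
        np.clip(eta, -35, 35, out=eta)
        np.negative(eta, out=buf)
        np.exp(buf, out=buf)
        buf += dt.type(1)
        mu = np.reciprocal(buf, out=buf)
        g1 = sum_y - mu.sum(axis=1, dtype=np.float64)
        g2 = sum_yx - np.einsum("mn,mn->m", mu, x, dtype=np.float64)
        np.multiply(mu, mu, out=eta)   # eta buffer repurposed: w = mu - mu^2
        w = np.subtract(mu, eta, out=eta)
        h11 = w.sum(axis=1, dtype=np.float64)
        h12 = np.einsum("mn,mn->m", w, x, dtype=np.float64)
        h22 = np.einsum("mn,mn->m", w, x2, dtype=np.float64)
        det = np.maximum(h11 * h22 - h12 * h12, 1e-300)
        da = (h22 * g1 - h12 * g2) / det
        db = (h11 * g2 - h12 * g1) / det
        # cap runaway steps so separated rows stay finite
        scale = np.maximum(1.0, np.maximum(np.abs(da), np.abs(db)) / 10.0)
        a += da / scale
        b += db / scale
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < step_tol:
            break
    np.multiply(b[:, None].astype(dt), x, out=eta)
    eta += a[:, None].astype(dt)
    ll = (
        np.einsum("mn,mn->m", Y, eta, dtype=np.float64)
        - np.logaddexp(dt.type(0), eta).sum(axis=1, dtype=np.float64)
    )
    ll0 = n * (ybar * np.log(ybar) + (1.0 - ybar) * np.log(1.0 - ybar))
    stat = 2.0 * (ll - ll0)
    bad = np.abs(eta).max(axis=1) > _MAX_ABS_ETA
    if np.any(bad):
        for m in np.nonzero(bad)[0]:
            _, llr, _, _ = fit_logistic(
                np.asarray(Y[m], dtype=np.float64),
                np.asarray(x[m], dtype=np.float64)[:, None],
                ridge=_RIDGE,
                max_iter=200,
            )
            stat[m] = 2.0 * (llr - n * (
                ybar[m] * np.log(ybar[m]) + (1 - ybar[m]) * np.log(1 - ybar[m])
            ))
    return np.maximum(stat, 0.0)
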