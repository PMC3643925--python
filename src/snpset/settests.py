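"""SNP-set association tests: PCA, supervised PCA, kernel PCA and SIR.

Each test consumes an additively coded genotype matrix ``G`` (n individuals x
p SNPs) with a binary phenotype ``y`` and returns a :class:`SetTestResult`.

* ``pca_test`` — logistic likelihood-ratio test of the phenotype on the first
  k principal components of the genotype covariance matrix, with k chosen so
  the components explain at least 80% of the variance (configurable).
* ``spca_test`` — supervised PCA: SNPs are screened by their marginal
  association with the phenotype, the first PC of the selected subset is the
  predictor, and the reported statistic is maximised over a grid of screening
  thresholds.  Because the selection step invalidates the usual asymptotics,
  the p-value comes from permutations of the phenotype in which the whole
  procedure (screening, selection, PC extraction, maximisation) is re-run.
* ``kpca_test`` — kernel PCA with an RBF kernel: PCA on the centred kernel
  matrix, components to 80% of kernel-eigenvalue mass, logistic LRT.
* ``sir_test`` — sliced inverse regression with two slices (cases/controls)
  and Li's marginal dimension chi-square test with p*(H-1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import sparse, stats

from . import _glm
from .sim import GenotypeDataset

__all__ = [
    "SetTestResult",
    "TestConfig",
    "pca_components",
    "logistic_lrt",
    "pca_test",
    "screen_snps",
    "spca_test",
    "rbf_kernel",
    "linear_kernel",
    "center_kernel",
    "kpca_test",
    "sir_eigen",
    "sir_test",
    "single_snp_tests",
    "run_set_tests",
]

_KPCA_COMPONENT_CAP = 50
_KPCA_DENSE_N = 800
_SIR_PINV_RTOL = 1e-8


@dataclass
class SetTestResult:
    """Outcome of one SNP-set test.

    ``df`` is None for permutation-calibrated methods.  ``diagnostics`` holds
    method internals (eigenvalues, variance fractions, kernel bandwidth,
    permutation counts, degeneracy flags).
    """

    method: str
    statistic: float
    p_value: float
    df: int | None = None
    n_components: int = 1
    component_loadings: np.ndarray | None = None
    selected_snps: list[int] | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.df is not None and self.statistic < 0:
            raise ValueError("chi-square statistic must be nonnegative")


@dataclass(frozen=True)
class TestConfig:
    """Tuning knobs shared by the four tests (defaults follow common usage).

    variance_threshold : cumulative-variance fraction for component selection
        in PCA and KPCA (default 0.80).
    kernel / kernel_bandwidth : KPCA kernel; ``"auto"`` bandwidth uses the
        mean-pairwise-distance heuristic (see :func:`rbf_kernel`).
    n_permutations : permutation budget B for the SPCA null (>= 100).
    adaptive_permutations : stop permuting once the running p-value is
        decisively above any rejection level (sequential rule, see
        ``early_stop_exceedances``).
    screening_grid : quantiles of the screening statistic used as candidate
        selection thresholds in SPCA.
    fixed_screening_threshold : alternative SPCA mode — a single absolute
        screening-statistic cutoff instead of the quantile grid.
    n_slices : number of SIR slices (binary phenotypes force 2).
    alphas : significance levels carried along for reporting.
    """

    variance_threshold: float = 0.80
    kernel: str = "rbf"
    kernel_bandwidth: float | str = "auto"
    n_permutations: int = 1000
    adaptive_permutations: bool = True
    early_stop_exceedances: int = 10
    screening_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 0.9)
    fixed_screening_threshold: float | None = None
    n_slices: int = 2
    alphas: tuple[float, ...] = (0.05, 0.01)

    __test__ = False  # not a pytest collectable despite the name

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must be in (0, 1]")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")


def _as_matrix(G) -> np.ndarray:
    if isinstance(G, GenotypeDataset):
        return np.asarray(G.genotypes, dtype=float)
    return np.asarray(G, dtype=float)


def _as_phenotype(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size != 2 or not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError("phenotype must contain both classes coded 0/1")
    return y


# ---------------------------------------------------------------------------
# principal components + logistic LRT
# ---------------------------------------------------------------------------


class PCAComponents(NamedTuple):
    k: int
    scores: np.ndarray       # n x k component scores
    loadings: np.ndarray     # p x k orthonormal eigenvectors
    eigenvalues: np.ndarray  # all p eigenvalues, nonincreasing


def pca_components(G, variance_threshold: float = 0.80) -> PCAComponents:
    """Eigendecomposition of the genotype variance-covariance matrix.

    ``k`` is the smallest number of leading components whose cumulative
    eigenvalue fraction reaches ``variance_threshold``.  Loadings carry the
    sign convention that each eigenvector's largest-magnitude entry is
    positive.
    """
    X = _as_matrix(G)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    w, v = np.linalg.eigh(cov)
    w = np.maximum(w[::-1], 0.0)
    v = v[:, ::-1]
    total = w.sum()
    if total <= 0:
        raise ValueError("constant genotype matrix: no principal components")
    frac = np.cumsum(w) / total
    k = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    k = min(k, w.size)
    signs = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    v = v * signs
    return PCAComponents(k, Xc @ v[:, :k], v[:, :k], w)


def logistic_lrt(y, X):
    """Likelihood-ratio chi-square of logistic ``y ~ X`` against intercept only.

    Thin wrapper over the vectorised fitter; see :mod:`snpset._glm`.
    """
    return _glm.logistic_lrt(y, X)


def pca_test(G, y, config: TestConfig = TestConfig()) -> SetTestResult:
    """PCA set test: logistic LRT on the leading principal components."""
    y = _as_phenotype(y)
    comp = pca_components(G, config.variance_threshold)
    stat, df, p, diag = _glm.logistic_lrt(y, comp.scores)
    diag.update(
        eigenvalues=comp.eigenvalues,
        variance_fractions=np.cumsum(comp.eigenvalues) / comp.eigenvalues.sum(),
    )
    return SetTestResult(
        method="PCA",
        statistic=stat,
        p_value=p,
        df=df,
        n_components=comp.k,
        component_loadings=comp.loadings,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# supervised PCA
# ---------------------------------------------------------------------------


class ScreeningResult(NamedTuple):
    statistics: np.ndarray  # per-SNP absolute score statistic
    ranks: np.ndarray       # 0 = strongest; ties broken by SNP index


def screen_snps(G, y) -> ScreeningResult:
    """Marginal per-SNP screening statistic.

    The statistic is the absolute two-group score statistic of the allele
    count (equivalent to |t| up to a variance convention): ``|U_j| /
    sqrt(V_j)`` with ``U_j = sum_i (y_i - ybar) g_ij`` and ``V_j =
    ybar(1-ybar) sum_i (g_ij - gbar_j)^2``.  SNPs identical in cases and
    controls score 0; monomorphic SNPs score 0 by convention.
    """
    X = _as_matrix(G)
    y = _as_phenotype(y)
    ybar = y.mean()
    Xc = X - X.mean(axis=0)
    u = (y - ybar) @ Xc
    v = ybar * (1 - ybar) * np.sum(Xc * Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(u) / np.sqrt(v)
    z = np.where(v > 0, z, 0.0)
    order = np.lexsort((np.arange(z.size), -z))  # stable: index breaks ties
    ranks = np.empty_like(order)
    ranks[order] = np.arange(z.size)
    return ScreeningResult(z, ranks)


def _spca_max_statistic(
    Xc: np.ndarray,
    cov: np.ndarray,
    sqrt_v: np.ndarray,
    Y: np.ndarray,
    grid: Sequence[float],
    dtype=np.float64,
    fixed_threshold: float | None = None,
):
    """Max-over-grid supervised-PCA statistic for each phenotype row.

    ``Y`` is an (M, n) matrix of 0/1 label vectors (the first row is usually
    the observed phenotype; the rest are permutations).  For every row the
    screening statistics, threshold grid, SNP selection, PC1 and logistic
    LRT are recomputed from scratch.  Returns (statistics, per-threshold
    details for row 0).
    """
    n, p = Xc.shape
    M = Y.shape[0]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.abs(Yc @ Xc) / sqrt_v  # M x p screening stats
    Z = np.where(np.isfinite(Z), Z, 0.0)
    if fixed_threshold is not None:
        qs = np.full((1, M), float(fixed_threshold))
    else:
        qs = np.quantile(Z, grid, axis=1)  # T x M
    T = qs.shape[0]
    mask = Z[None, :, :] >= qs[:, :, None] - 1e-12
    small_p = p <= 62
    codes = mask @ (1 << np.arange(p, dtype=np.int64)) if small_p else None
    col_cache: dict = {}
    cols: list[np.ndarray] = []
    col_sets: list[np.ndarray] = []
    colidx = np.empty((T, M), dtype=np.int64)
    fallback = False
    for ti in range(T):
        mrow = mask[ti]
        crow = codes[ti] if small_p else None
        for mcol in range(M):
            key = int(crow[mcol]) if small_p else mrow[mcol].tobytes()
            j = col_cache.get(key)
            if j is None:
                idx = np.nonzero(mrow[mcol])[0]
                if idx.size == 0:  # all screened out: fall back to full set
                    idx = np.arange(p)
                    fallback = True
                sub = cov[np.ix_(idx, idx)]
                _, vecs = np.linalg.eigh(sub)
                lead = vecs[:, -1]
                imax = np.argmax(np.abs(lead))
                if lead[imax] < 0:
                    lead = -lead
                j = len(cols)
                col_cache[key] = j
                cols.append(Xc[:, idx] @ lead)
                col_sets.append(idx)
            colidx[ti, mcol] = j
    # D x n, one PC1 score vector per distinct subset; permutation batches may
    # run in float32 (the LRT is only compared against permutation noise)
    score_rows = np.vstack(cols).astype(dtype, copy=False)
    Yb = Y.astype(dtype, copy=False)
    ncols = len(cols)
    pair_key = np.repeat(np.arange(M, dtype=np.int64), T) * ncols + colidx.T.ravel()
    unique_keys, inverse = np.unique(pair_key, return_inverse=True)
    u_perm = unique_keys // ncols
    u_col = unique_keys % ncols
    stats_u = _glm.lrt_single_batch(score_rows[u_col], Yb[u_perm])
    per_pair = stats_u[inverse].reshape(M, T)
    max_stat = per_pair.max(axis=1)
    best_t = per_pair[0].argmax()
    details = {
        "per_threshold_stats": per_pair[0].copy(),
        "thresholds": qs[:, 0].copy(),
        "selected": col_sets[colidx[best_t, 0]],
        "screening_fallback": fallback,
    }
    return max_stat, details


def _permute_labels(y: np.ndarray, n_perm: int, rng: np.random.Generator):
    """(n_perm, n) matrix of independently permuted label rows."""
    out = np.tile(y, (n_perm, 1))
    return rng.permuted(out, axis=1)


def spca_test(
    G,
    y,
    config: TestConfig = TestConfig(),
    rng: np.random.Generator | None = None,
) -> SetTestResult:
    """Supervised-PCA set test with a full-procedure permutation null.

    The observed statistic is the maximum over the screening-threshold grid of
    the logistic LRT of the phenotype on PC1 of the selected SNP subset.  Its
    p-value is estimated from phenotype permutations in which screening,
    selection, PC extraction and grid maximisation are all re-run, which
    accounts for the selection step.  With ``adaptive_permutations`` the
    sequential rule of Besag & Clifford is used: permuting stops once ``h``
    permuted statistics have reached the observed one, reporting ``p = h/L``
    (else ``p = (c+1)/(B+1)`` after the full budget B).
    """
    if rng is None:
        rng = np.random.default_rng()
    X = _as_matrix(G)
    y = _as_phenotype(y)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    ybar = y.mean()
    sqrt_v = np.sqrt(ybar * (1 - ybar) * np.sum(Xc * Xc, axis=0))
    grid = config.screening_grid
    fixed = config.fixed_screening_threshold
    obs, details = _spca_max_statistic(
        Xc, cov, sqrt_v, y[None, :], grid, fixed_threshold=fixed
    )
    obs = float(obs[0])

    B = config.n_permutations
    h = config.early_stop_exceedances
    exceed = 0
    done = 0
    p_value = None
    schedule = [50, 150, 300, 500]
    while done < B:
        blk = min(schedule.pop(0) if schedule else 400, B - done)
        Yp = _permute_labels(y, blk, rng)
        stats_p, _ = _spca_max_statistic(
            Xc, cov, sqrt_v, Yp, grid, dtype=np.float32, fixed_threshold=fixed
        )
        if config.adaptive_permutations:
            for s in stats_p:
                done += 1
                exceed += s >= obs - 1e-12
                if exceed >= h:
                    p_value = exceed / done
                    break
            if p_value is not None:
                break
        else:
            done += blk
            exceed += int(np.sum(stats_p >= obs - 1e-12))
    if p_value is None:
        p_value = (exceed + 1) / (done + 1)
    details.update(n_permutations=done, n_exceedances=int(exceed))
    return SetTestResult(
        method="SPCA",
        statistic=obs,
        p_value=float(p_value),
        df=None,
        n_components=1,
        selected_snps=details["selected"].tolist(),
        diagnostics=details,
    )


# ---------------------------------------------------------------------------
# kernel PCA
# ---------------------------------------------------------------------------


def rbf_kernel(G, bandwidth: float | str = "auto"):
    """RBF (Gaussian) kernel matrix ``K[i,j] = exp(-|gi-gj|^2 / (2 sigma^2))``.

    ``bandwidth="auto"`` sets ``sigma^2`` to twice the mean off-diagonal
    squared Euclidean distance.  This is the mean-distance variant of the
    usual bandwidth heuristic: on sparse genotype matrices (rare alleles,
    strong LD) the *median* pairwise distance is frequently exactly zero
    because most individuals carry identical genotype vectors, which would
    degenerate the kernel; the mean stays positive and yields a smooth kernel
    whose leading components mirror the LD structure.  Returns (K, sigma).
    """
    X = _as_matrix(G)
    sq_norm = np.sum(X * X, axis=1)
    d2 = sq_norm[:, None] + sq_norm[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    if bandwidth == "auto":
        n = d2.shape[0]
        mean_d2 = float(d2.sum()) / (n * (n - 1)) if n > 1 else 0.0
        if mean_d2 <= 0:
            mean_d2 = 1.0  # all rows identical: any bandwidth gives K = ones
        sigma = np.sqrt(2.0 * mean_d2)
    else:
        sigma = float(bandwidth)
        if sigma <= 0:
            raise ValueError("kernel bandwidth must be positive")
    K = np.exp(-d2 / (2.0 * sigma**2))
    return K, sigma


def linear_kernel(G):
    """Linear kernel ``K = G G^T`` (KPCA with this kernel reduces to PCA)."""
    X = _as_matrix(G)
    return X @ X.T


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double-centre a kernel matrix: ``K - 1K/n - K1/n + 1K1/n^2``."""
    row = K.mean(axis=0)
    grand = row.mean()
    return K - row[None, :] - row[:, None] + grand


def _top_eigen(Kc: np.ndarray, k: int):
    """Leading eigenpairs of a symmetric PSD matrix, descending."""
    n = Kc.shape[0]
    if n <= _KPCA_DENSE_N or k >= n - 1:
        w, v = np.linalg.eigh(Kc)
        return w[::-1][:k], v[:, ::-1][:, :k]
    v0 = np.cos(np.arange(n, dtype=float))  # deterministic start vector
    w, v = sparse.linalg.eigsh(Kc, k=k, which="LA", v0=v0)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def kpca_test(G, y, config: TestConfig = TestConfig()) -> SetTestResult:
    """Kernel-PCA set test.

    PCA on the centred kernel matrix; the smallest number of leading kernel
    components whose eigenvalue sum reaches ``variance_threshold`` of the
    total (the trace) is kept, hard-capped at min(n-2, 50) to bound the
    degrees of freedom; the phenotype is tested on the component scores with
    a logistic LRT.
    """
    y = _as_phenotype(y)
    X = _as_matrix(G)
    n = X.shape[0]
    if config.kernel == "rbf":
        K, sigma = rbf_kernel(X, config.kernel_bandwidth)
    else:
        K, sigma = linear_kernel(X), None
    Kc = center_kernel(K)
    total = float(np.trace(Kc))
    if total <= 0:
        raise ValueError("centred kernel has no variance")
    cap = min(n - 2, _KPCA_COMPONENT_CAP)
    # ask for a few components first; extend only if 80% mass is not reached
    for k_try in (min(n - 1, 16), min(n - 1, cap + 10)):
        w, v = _top_eigen(Kc, k_try)
        w = np.maximum(w, 0.0)
        frac = np.cumsum(w) / total
        reached = np.nonzero(frac >= config.variance_threshold - 1e-12)[0]
        if reached.size or k_try >= min(n - 1, cap + 10):
            break
    capped = reached.size == 0 or reached[0] + 1 > cap
    k = cap if capped else int(reached[0] + 1)
    scores = v[:, :k] * np.sqrt(w[:k])
    stat, df, p, diag = _glm.logistic_lrt(y, scores)
    diag.update(
        kernel=config.kernel,
        kernel_bandwidth=sigma,
        eigenvalues=w,
        eigenvalue_fractions=frac,
        component_cap_hit=bool(capped),
    )
    return SetTestResult(
        method="KPCA",
        statistic=stat,
        p_value=p,
        df=df,
        n_components=k,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# sliced inverse regression
# ---------------------------------------------------------------------------


class SIREigen(NamedTuple):
    eigenvalues: np.ndarray    # descending, in [0, 1]
    directions: np.ndarray     # p x k directions in the original coordinates
    slice_props: np.ndarray
    slice_means: np.ndarray    # H x p' means of the standardised predictors
    rank: int                  # effective rank of the predictor covariance
    pinv_clipped: bool


def _slice_indicator(y: np.ndarray, n_slices: int) -> np.ndarray:
    """Slice labels for the response; binary responses get their two classes."""
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("response is constant: cannot slice")
    if classes.size == 2:
        return (y == classes[1]).astype(int)
    edges = np.quantile(y, np.linspace(0, 1, n_slices + 1)[1:-1])
    return np.searchsorted(edges, y, side="right")


def sir_eigen(G, y, n_slices: int = 2) -> SIREigen:
    """Slice-mean eigendecomposition for sliced inverse regression.

    Predictors are standardised with the sample mean and the inverse square
    root of the sample covariance, computed by eigendecomposition with a
    relative pseudo-inverse tolerance (near-zero variance directions are
    dropped and flagged).  The weighted covariance of the slice means of the
    standardised predictors, ``V = sum_h p_h m_h m_h^T``, has at most
    ``H - 1`` nonzero eigenvalues, all in [0, 1].
    """
    X = _as_matrix(G)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    labels = _slice_indicator(y, n_slices)
    H = labels.max() + 1
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    w, v = np.linalg.eigh(cov)
    keep = w > _SIR_PINV_RTOL * w.max()
    clipped = bool(np.any(~keep))
    w_k, v_k = w[keep], v[:, keep]
    transform = v_k / np.sqrt(w_k)  # p x r, maps x -> standardised coords
    Z = Xc @ transform
    props = np.bincount(labels, minlength=H) / n
    means = np.vstack([Z[labels == h].mean(axis=0) for h in range(H)])
    M = (means * props[:, None]).T @ means
    lam, vecs = np.linalg.eigh(M)
    lam = np.clip(lam[::-1], 0.0, 1.0)
    vecs = vecs[:, ::-1]
    k = min(H - 1, int(keep.sum()))
    directions = transform @ vecs[:, :k]
    return SIREigen(lam, directions, props, means, int(keep.sum()), clipped)


def sir_test(G, y, config: TestConfig = TestConfig()) -> SetTestResult:
    """Marginal dimension test for SIR: no direction is needed.

    Statistic ``T = n * sum_j lambda_j`` compared to chi-square with
    ``p * (H - 1)`` degrees of freedom.  For a binary phenotype (H = 2) this
    is ``T = n * lambda_1``, a Hotelling-type two-group statistic computed
    with the total covariance.
    """
    X = _as_matrix(G)
    y = _as_phenotype(y)
    n, p = X.shape
    eig = sir_eigen(X, y, config.n_slices)
    H = eig.slice_props.size
    stat = float(n * eig.eigenvalues.sum())
    df = p * (H - 1)
    p_value = float(stats.chi2.sf(stat, df))
    return SetTestResult(
        method="SIR",
        statistic=stat,
        p_value=p_value,
        df=df,
        n_components=min(H - 1, eig.rank),
        component_loadings=eig.directions,
        diagnostics={
            "eigenvalues": eig.eigenvalues[: H - 1],
            "slice_props": eig.slice_props,
            "cov_rank": eig.rank,
            "pinv_clipped": eig.pinv_clipped,
        },
    )


# ---------------------------------------------------------------------------
# single-SNP tests and the combined runner
# ---------------------------------------------------------------------------


def single_snp_tests(G, y) -> list[SetTestResult]:
    """Per-SNP 1-df logistic likelihood-ratio tests (additive coding)."""
    X = _as_matrix(G)
    y = _as_phenotype(y)
    n, p = X.shape
    stats_vec = _glm.lrt_single_batch(
        np.ascontiguousarray(X.T), np.tile(y, (p, 1))
    )
    variable = X.std(axis=0) > 0
    results = []
    for j in range(p):
        if variable[j]:
            s = float(stats_vec[j])
            pv = float(stats.chi2.sf(s, 1))
            df = 1
        else:
            s, pv, df = 0.0, 1.0, 0
        results.append(
            SetTestResult(
                method="single-SNP",
                statistic=s,
                p_value=pv,
                df=df,
                n_components=1,
                selected_snps=[j],
                diagnostics={"maf": float(X[:, j].mean() / 2.0)},
            )
        )
    return results


_METHODS = ("pca", "spca", "kpca", "sir")


def run_set_tests(
    G,
    y,
    methods: Sequence[str] = _METHODS,
    config: TestConfig = TestConfig(),
    rng: np.random.Generator | None = None,
) -> dict[str, SetTestResult]:
    """Run the requested set tests on one dataset (shared across methods)."""
    out: dict[str, SetTestResult] = {}
    for m in methods:
        m = m.lower()
        if m == "pca":
            out[m] = pca_test(G, y, config)
        elif m == "spca":
            out[m] = spca_test(G, y, config, rng)
        elif m == "kpca":
            out[m] = kpca_test(G, y, config)
        elif m == "sir":
            out[m] = sir_test(G, y, config)
        else:
            raise ValueError(f"unknown method '{m}'")
    return out
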