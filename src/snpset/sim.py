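"""Case-control genotype simulation with controlled MAF and pairwise LD.

The generator follows the thresholded-Gaussian (Gaussian copula) construction:
each haplotype is obtained by drawing a latent multivariate-normal vector and
setting allele j to 1 when the latent coordinate falls below the standard-normal
quantile of that SNP's minor-allele frequency.  The latent correlation of every
pair is solved numerically so that the *allele indicators* attain a prescribed
Pearson correlation (hence a prescribed R-squared), which makes the realised LD
match its target exactly in expectation rather than being attenuated by
thresholding.

Genotypes are sums of two independent haplotypes (Hardy-Weinberg proportions by
construction).  Disease status follows an additive-per-allele logistic model
whose intercept is calibrated so the population prevalence hits a target value,
and case-control datasets are assembled by rejection sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from scipy import optimize, stats

__all__ = [
    "HaplotypeModel",
    "ScenarioSpec",
    "GenotypeDataset",
    "InfeasibleCorrelationError",
    "SimulationError",
    "binary_corr_to_latent",
    "build_haplotype_model",
    "fit_model_from_haplotypes",
    "draw_haplotypes",
    "draw_genotypes",
    "disease_prob",
    "calibrate_intercept",
    "simulate_case_control",
    "empirical_ld",
]

_REJECTION_CAP = 10_000_000  # max individuals drawn per dataset
_PD_FLOOR = 1e-8
_RHO_LIMIT = 1.0 - 1e-9


class InfeasibleCorrelationError(ValueError):
    """Requested indicator correlation is outside the Fréchet-attainable range."""


class SimulationError(RuntimeError):
    """Rejection sampling or intercept calibration failed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeModel:
    """Latent-Gaussian haplotype model.

    Attributes
    ----------
    mafs : (p,) array of minor-allele frequencies in (0, 0.5].
    latent_corr : (p, p) correlation matrix of the latent Gaussian vector
        (symmetric, unit diagonal, positive definite after repair).
    thresholds : (p,) standard-normal quantiles ``Phi^{-1}(mafs)``; the latent
        coordinate below its threshold codes the minor allele.
    target_r2 : (p, p) matrix of intended pairwise allele R^2 (record keeping).
    repair_distance : Frobenius distance moved by the positive-definite repair
        (0 when no repair was necessary).
    flipped : indices of columns whose allele coding was flipped during fitting
        so that the minor allele is the one being counted.
    """

    mafs: np.ndarray
    latent_corr: np.ndarray
    thresholds: np.ndarray
    target_r2: np.ndarray
    repair_distance: float = 0.0
    flipped: tuple[int, ...] = ()
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mafs = np.asarray(self.mafs, dtype=float)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.target_r2 = np.asarray(self.target_r2, dtype=float)
        p = self.mafs.size
        if self.latent_corr.shape != (p, p):
            raise ValueError("latent_corr shape does not match number of SNPs")
        if np.any(self.mafs <= 0) or np.any(self.mafs > 0.5):
            raise ValueError("MAFs must lie in (0, 0.5]")
        if not np.allclose(self.latent_corr, self.latent_corr.T, atol=1e-12):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(self.latent_corr), 1.0, atol=1e-12):
            raise ValueError("latent_corr must have unit diagonal")

    @property
    def n_snps(self) -> int:
        return self.mafs.size

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor of the latent correlation (cached)."""
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.latent_corr)
        return self._chol


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterisation of one simulation scenario.

    ``r2`` is either a single target applied to every pair or a p x p matrix
    (as nested tuples).  ``causal_indices`` empty means a null scenario.
    """

    scenario_id: str
    n_snps: int
    mafs: tuple[float, ...]
    r2: float | tuple[tuple[float, ...], ...]
    causal_indices: tuple[int, ...] = ()
    grrs: tuple[float, ...] = ()
    n_cases: int = 1000
    n_controls: int = 1000
    baseline_prevalence: float = 0.10

    def __post_init__(self) -> None:
        if len(self.mafs) != self.n_snps:
            raise ValueError("mafs length must equal n_snps")
        if len(self.causal_indices) != len(self.grrs):
            raise ValueError("causal_indices and grrs must have equal length")
        if len(set(self.causal_indices)) != len(self.causal_indices):
            raise ValueError("causal indices must be distinct")
        if any(not 0 <= c < self.n_snps for c in self.causal_indices):
            raise ValueError("causal index out of range")
        if any(g <= 0 for g in self.grrs):
            raise ValueError("genotype relative risks must be positive")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("need at least one case and one control")

    @property
    def is_null(self) -> bool:
        return len(self.causal_indices) == 0

    def r2_matrix(self) -> np.ndarray:
        if np.isscalar(self.r2):
            m = np.full((self.n_snps, self.n_snps), float(self.r2))
            np.fill_diagonal(m, 1.0)
            return m
        return np.asarray(self.r2, dtype=float)


@dataclass
class GenotypeDataset:
    """Additively coded genotypes with a binary phenotype.

    genotypes : (n, p) matrix with entries in {0, 1, 2} (minor-allele counts)
    phenotype : (n,) vector in {0, 1}, 1 = case
    snp_ids : p SNP labels
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.phenotype = np.asarray(self.phenotype)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.genotypes.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length must match genotype columns")
        if self.genotypes.shape[0] != self.phenotype.size:
            raise ValueError("phenotype length must match genotype rows")
        if not np.isin(np.unique(self.genotypes), [0, 1, 2]).all():
            raise ValueError("genotype entries must be 0, 1 or 2")
        if not np.isin(np.unique(self.phenotype), [0, 1]).all():
            raise ValueError("phenotype entries must be 0 or 1")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


# ---------------------------------------------------------------------------
# copula machinery
# ---------------------------------------------------------------------------


def _bvn_cdf(t1: float, t2: float, rho: float) -> float:
    """P(Z1 < t1, Z2 < t2) for standard bivariate normal with correlation rho."""
    return float(
        stats.multivariate_normal.cdf(
            [t1, t2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
            abseps=1e-14, releps=0.0,
        )
    )


def binary_corr_to_latent(p_i: float, p_j: float, r: float) -> float:
    """Latent-normal correlation reproducing a Pearson correlation of indicators.

    Finds rho such that thresholding a standard bivariate normal with
    correlation rho at ``Phi^{-1}(p_i)``, ``Phi^{-1}(p_j)`` yields Bernoulli
    margins with Pearson correlation ``r``.  Solved by monotone root finding on
    the orthant probability.

    Raises
    ------
    InfeasibleCorrelationError
        when ``r`` exceeds the Fréchet bounds for the two margins.
    """
    if not (0 < p_i < 1 and 0 < p_j < 1):
        raise ValueError("margins must lie strictly in (0, 1)")
    if r == 0.0:
        return 0.0
    denom = np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
    r_max = (min(p_i, p_j) - p_i * p_j) / denom
    r_min = (max(p_i + p_j - 1.0, 0.0) - p_i * p_j) / denom
    if not r_min - 1e-12 <= r <= r_max + 1e-12:
        raise InfeasibleCorrelationError(
            f"indicator correlation {r:.6g} infeasible for margins "
            f"({p_i:.4g}, {p_j:.4g}); attainable range is "
            f"[{r_min:.6g}, {r_max:.6g}]"
        )
    t1, t2 = stats.norm.ppf(p_i), stats.norm.ppf(p_j)
    target_p11 = r * denom + p_i * p_j

    def objective(rho: float) -> float:
        return _bvn_cdf(t1, t2, rho) - target_p11

    lo, hi = -_RHO_LIMIT, _RHO_LIMIT
    f_lo, f_hi = objective(lo), objective(hi)
    # targets at/beyond the numerically attainable boundary collapse to +-1
    if f_hi <= 0.0:
        return _RHO_LIMIT
    if f_lo >= 0.0:
        return -_RHO_LIMIT
    try:
        rho = optimize.brentq(objective, lo, hi, xtol=1e-12, rtol=8.9e-16)
    except RuntimeError as exc:  # pragma: no cover - brentq converges here
        raise InfeasibleCorrelationError(
            f"root finding failed for margins ({p_i}, {p_j}), r={r}"
        ) from exc
    achieved = (_bvn_cdf(t1, t2, rho) - p_i * p_j) / denom
    if abs(achieved - r) > 1e-6:
        raise InfeasibleCorrelationError(
            f"copula solution inaccurate: wanted r={r}, achieved {achieved}"
        )
    return float(rho)


def _repair_positive_definite(corr: np.ndarray, floor: float = _PD_FLOOR):
    """Clip eigenvalues at ``floor``, rebuild, rescale to unit diagonal.

    Returns the repaired matrix and the Frobenius distance moved (0 when the
    input already had smallest eigenvalue above the floor).
    """
    w, v = np.linalg.eigh(corr)
    if w.min() > floor:
        return corr, 0.0
    w_clipped = np.maximum(w, floor)
    repaired = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.linalg.norm(repaired - corr, "fro"))


def _latent_corr_from_allele_corr(
    mafs: np.ndarray, allele_corr: np.ndarray
) -> tuple[np.ndarray, float]:
    """Entrywise copula inversion followed by positive-definite repair.

    Solutions are cached per distinct (maf_i, maf_j, r) triple, so
    equicorrelated designs cost a single root find.
    """
    p = mafs.size
    latent = np.eye(p)
    cache: dict[tuple[float, float, float], float] = {}
    for i in range(p):
        for j in range(i + 1, p):
            a, b = sorted((float(mafs[i]), float(mafs[j])))
            key = (a, b, float(allele_corr[i, j]))
            rho = cache.get(key)
            if rho is None:
                try:
                    rho = binary_corr_to_latent(key[0], key[1], key[2])
                except InfeasibleCorrelationError as exc:
                    raise InfeasibleCorrelationError(
                        f"SNP pair ({i}, {j}): {exc}"
                    ) from exc
                cache[key] = rho
            latent[i, j] = latent[j, i] = rho
    if np.any(np.abs(latent[~np.eye(p, dtype=bool)]) >= _RHO_LIMIT):
        warnings.warn(
            "some latent correlations were clipped to +-(1-1e-9); "
            "positive-definite repair will perturb them",
            stacklevel=3,
        )
    return _repair_positive_definite(latent)


def build_haplotype_model(
    mafs, r2, *, negative_ld: bool = False
) -> HaplotypeModel:
    """Build a haplotype model from target MAFs and pairwise R^2.

    The allele-scale correlation target is ``+sqrt(R^2)`` (positive LD) by
    default; pass ``negative_ld=True`` to flip the sign of every off-diagonal
    target (only feasible for small sets, since a common negative correlation
    of many variables is not positive definite).
    """
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    p = mafs.size
    if np.isscalar(r2):
        r2_mat = np.full((p, p), float(r2))
        np.fill_diagonal(r2_mat, 1.0)
    else:
        r2_mat = np.asarray(r2, dtype=float)
        if r2_mat.shape != (p, p):
            raise ValueError("r2 matrix shape must be (p, p)")
    if np.any(r2_mat < 0) or np.any(r2_mat > 1):
        raise ValueError("R^2 entries must lie in [0, 1]")
    sign = -1.0 if negative_ld else 1.0
    allele_corr = sign * np.sqrt(r2_mat)
    latent, dist = _latent_corr_from_allele_corr(mafs, allele_corr)
    return HaplotypeModel(
        mafs=mafs,
        latent_corr=latent,
        thresholds=stats.norm.ppf(mafs),
        target_r2=r2_mat,
        repair_distance=dist,
    )


def fit_model_from_haplotypes(haplotypes) -> HaplotypeModel:
    """Fit a latent-Gaussian model to a phased 0/1 haplotype panel.

    MAFs are column means after flipping any column whose allele frequency
    exceeds 0.5 (flips are recorded).  Pairwise allele correlations are
    estimated from joint frequencies and inverted to latent correlations
    entrywise, followed by positive-definite repair.
    """
    H = np.asarray(haplotypes, dtype=float)
    if H.ndim != 2 or H.shape[1] < 2:
        raise ValueError("need a 2-D panel with at least 2 SNPs")
    if not np.isin(np.unique(H), [0, 1]).all():
        raise ValueError("haplotype entries must be 0 or 1")
    m, p = H.shape
    if m < 30:
        raise ValueError("need at least 30 haplotypes to fit a model")
    freqs = H.mean(axis=0)
    if np.any(freqs == 0) or np.any(freqs == 1):
        bad = np.nonzero((freqs == 0) | (freqs == 1))[0]
        raise ValueError(f"monomorphic column(s) {bad.tolist()} cannot be fitted")
    flipped = tuple(int(j) for j in np.nonzero(freqs > 0.5)[0])
    H = H.copy()
    for j in flipped:
        H[:, j] = 1.0 - H[:, j]
    mafs = H.mean(axis=0)
    allele_corr = np.corrcoef(H, rowvar=False)
    # clamp duplicated-column correlations into the solvable open interval
    np.clip(allele_corr, -_RHO_LIMIT, _RHO_LIMIT, out=allele_corr)
    latent, dist = _latent_corr_from_allele_corr(mafs, allele_corr)
    r2 = allele_corr**2
    np.fill_diagonal(r2, 1.0)
    return HaplotypeModel(
        mafs=mafs,
        latent_corr=latent,
        thresholds=stats.norm.ppf(mafs),
        target_r2=r2,
        repair_distance=dist,
        flipped=flipped,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def draw_haplotypes(
    model: HaplotypeModel, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``m`` haplotypes (rows of 0/1 alleles) from the latent model."""
    if m < 1:
        raise ValueError("m must be at least 1")
    z = rng.standard_normal((m, model.n_snps)) @ model.cholesky().T
    return (z < model.thresholds).astype(np.int8)


def draw_genotypes(
    model: HaplotypeModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` diploid genotypes as sums of two independent haplotypes."""
    h = draw_haplotypes(model, 2 * n, rng)
    return h[:n] + h[n:]


def disease_prob(g, causal_indices, grrs, beta0: float) -> np.ndarray:
    """P(Y=1 | g) under the additive per-allele multiplicative-odds model.

    ``logit P = beta0 + sum_c log(GRR_c) * g[causal_c]``.
    """
    grrs = np.asarray(grrs, dtype=float)
    if np.any(grrs <= 0):
        raise ValueError("genotype relative risks must be positive")
    g = np.asarray(g, dtype=float)
    single = g.ndim == 1
    gmat = np.atleast_2d(g)
    eta = np.full(gmat.shape[0], float(beta0))
    for c, grr in zip(causal_indices, grrs):
        eta += np.log(grr) * gmat[:, c]
    prob = 1.0 / (1.0 + np.exp(-eta))
    return float(prob[0]) if single else prob


def _causal_genotype_pmf(
    model: HaplotypeModel, causal_indices: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint pmf of genotypes at the causal loci.

    The allele-vector pmf follows from lower-orthant probabilities of the
    latent normal via inclusion-exclusion; the genotype pmf is the convolution
    of two independent allele vectors.  Returns (values, probabilities) where
    ``values`` is (K, C) with entries in {0, 1, 2}.
    """
    idx = list(causal_indices)
    C = len(idx)
    thr = model.thresholds[idx]
    corr = model.latent_corr[np.ix_(idx, idx)]

    def orthant(sub: tuple[int, ...]) -> float:
        if not sub:
            return 1.0
        if len(sub) == 1:
            return float(stats.norm.cdf(thr[sub[0]]))
        s = list(sub)
        return float(
            stats.multivariate_normal.cdf(
                thr[s], mean=np.zeros(len(s)), cov=corr[np.ix_(s, s)],
                abseps=1e-12, releps=0.0,
            )
        )

    subsets = list(product((0, 1), repeat=C))
    orth = {s: orthant(tuple(j for j in range(C) if s[j])) for s in subsets}
    allele_pmf = {}
    for a in subsets:
        supp = tuple(j for j in range(C) if a[j])
        total = 0.0
        for w in subsets:  # supersets of a's support
            if all(w[j] for j in supp):
                extra = sum(w) - len(supp)
                total += (-1) ** extra * orth[w]
        allele_pmf[a] = max(total, 0.0)
    geno_pmf: dict[tuple[int, ...], float] = {}
    for a1, p1 in allele_pmf.items():
        for a2, p2 in allele_pmf.items():
            gkey = tuple(x + y for x, y in zip(a1, a2))
            geno_pmf[gkey] = geno_pmf.get(gkey, 0.0) + p1 * p2
    values = np.array(sorted(geno_pmf), dtype=float)
    probs = np.array([geno_pmf[tuple(v)] for v in values.astype(int)])
    return values, probs / probs.sum()


def calibrate_intercept(
    model: HaplotypeModel,
    causal_indices,
    grrs,
    prevalence: float,
    rng: np.random.Generator | None = None,
) -> float:
    """Intercept beta0 such that the population mean of P(Y=1) is ``prevalence``.

    Exact for up to 6 causal loci (joint genotype pmf via orthant
    probabilities); beyond that a 200,000-genotype Monte-Carlo quadrature with
    a fixed internal stream is used.
    """
    causal_indices = tuple(causal_indices)
    grrs = tuple(grrs)
    if not causal_indices:
        return float(np.log(prevalence / (1.0 - prevalence)))
    if len(causal_indices) <= 6:
        values, probs = _causal_genotype_pmf(model, causal_indices)
        eta_g = values @ np.log(np.asarray(grrs))
        weights = probs
    else:  # Monte-Carlo quadrature
        mc_rng = rng or np.random.default_rng(0)
        g = draw_genotypes(model, 200_000, mc_rng)[:, list(causal_indices)]
        eta_g = g @ np.log(np.asarray(grrs))
        weights = np.full(eta_g.size, 1.0 / eta_g.size)

    def mean_prob(b0: float) -> float:
        return float(weights @ (1.0 / (1.0 + np.exp(-(b0 + eta_g))))) - prevalence

    try:
        return float(optimize.brentq(mean_prob, -40.0, 40.0, xtol=1e-12))
    except ValueError as exc:
        raise SimulationError("prevalence calibration failed") from exc


@lru_cache(maxsize=128)
def _scenario_model(spec: ScenarioSpec) -> tuple[HaplotypeModel, float]:
    """Cached (model, intercept) for a scenario; specs are frozen/hashable."""
    model = build_haplotype_model(np.array(spec.mafs), spec.r2_matrix())
    beta0 = calibrate_intercept(
        model, spec.causal_indices, spec.grrs, spec.baseline_prevalence
    )
    return model, beta0


def simulate_case_control(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    model: HaplotypeModel | None = None,
) -> GenotypeDataset:
    """Simulate one case-control dataset under a scenario.

    Under the null (no causal SNP) the phenotype is independent of genotype,
    so exactly ``n_cases + n_controls`` genotypes are drawn and a shuffled
    label vector attached — distributionally identical to rejection sampling.
    With causal SNPs, individuals are drawn from the population model and
    Bernoulli disease outcomes accumulated until both quotas are met
    (capped at 10^7 draws).  Rows are shuffled before return.
    """
    if model is None:
        model, beta0 = _scenario_model(spec)
    else:
        beta0 = calibrate_intercept(
            model, spec.causal_indices, spec.grrs, spec.baseline_prevalence
        )
    n1, n0 = spec.n_cases, spec.n_controls
    n = n1 + n0
    snp_ids = [f"snp{j + 1}" for j in range(spec.n_snps)]
    if spec.is_null:
        genotypes = draw_genotypes(model, n, rng)
        phenotype = np.zeros(n, dtype=np.int8)
        phenotype[:n1] = 1
        order = rng.permutation(n)
        return GenotypeDataset(genotypes[order], phenotype[order], snp_ids)

    log_grr = np.log(np.asarray(spec.grrs))
    cidx = list(spec.causal_indices)
    cases, controls = [], []
    need1, need0 = n1, n0
    drawn = 0
    batch = max(2048, int(1.2 * n1 / spec.baseline_prevalence))
    while need1 > 0 or need0 > 0:
        if drawn >= _REJECTION_CAP:
            raise SimulationError(
                f"case/control quota unmet after {drawn} draws "
                f"(still need {need1} cases, {need0} controls)"
            )
        m = min(batch, _REJECTION_CAP - drawn)
        g = draw_genotypes(model, m, rng)
        drawn += m
        prob = 1.0 / (1.0 + np.exp(-(beta0 + g[:, cidx] @ log_grr)))
        is_case = rng.random(m) < prob
        if need1 > 0:
            take = g[is_case][:need1]
            cases.append(take)
            need1 -= take.shape[0]
        if need0 > 0:
            take = g[~is_case][:need0]
            controls.append(take)
            need0 -= take.shape[0]
    genotypes = np.vstack([np.vstack(cases), np.vstack(controls)])
    phenotype = np.zeros(n, dtype=np.int8)
    phenotype[:n1] = 1
    order = rng.permutation(n)
    return GenotypeDataset(genotypes[order], phenotype[order], snp_ids)


# ---------------------------------------------------------------------------
# validation utilities
# ---------------------------------------------------------------------------


def empirical_ld(matrix) -> np.ndarray:
    """Pairwise R^2 (squared Pearson correlation) between columns.

    Monomorphic columns yield NaN rows/columns with a warning; the diagonal
    is 1 wherever defined.
    """
    X = np.asarray(matrix, dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("monomorphic column(s): R^2 undefined (NaN)", stacklevel=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
    else:
        corr = np.corrcoef(X, rowvar=False)
    return corr**2
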