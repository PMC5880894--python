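"""Latent variable models of clr abundances on environmental covariates.

The model is y_ij = b0_j + x_i . b_j + z_i . l_j + e_ij with Gaussian noise
and standard-normal latent scores. Estimation alternates per-taxon
regression given the latent contribution with factor analysis of the
residuals, to a log-likelihood tolerance. With zero latent variables the
fit reduces exactly to ordinary least squares per taxon.

Niche similarity between two taxa is the Pearson correlation of their
fitted environmental responses X b_j over samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FactorAnalysis

from .compositional import ClrMatrix
from .datamodel import CountTable, DataError, EnvMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_LATENT = 2
DEFAULT_PREVALENCE = 0.70
DEFAULT_N_BOOTSTRAP = 100


@dataclass
class DesignMatrix:
    """Standardized covariates, optionally with squared columns appended."""

    sample_ids: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.columns)):
            raise DataError("design shape inconsistent with ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.columns)


@dataclass
class LVMFit:
    taxon_ids: list[str]
    sample_ids: list[str]
    intercept: np.ndarray  # (D,)
    beta: np.ndarray  # (D, p)
    loadings: np.ndarray  # (D, d)
    sigma2: np.ndarray  # (D,)
    scores: np.ndarray  # (n, d)
    n_latent: int
    design_columns: list[str]
    loglik: float
    converged: bool
    n_iter: int

    def fitted_environmental(self, x: np.ndarray) -> np.ndarray:
        """Samples x taxa matrix of environmental fitted values X b_j."""
        return np.asarray(x) @ self.beta.T


@dataclass
class EnvCorrelation:
    taxon_ids: list[str]
    corr: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    significant: np.ndarray | None = None

    def pairs(self) -> pd.DataFrame:
        rows = []
        d = len(self.taxon_ids)
        for i in range(d):
            for j in range(i + 1, d):
                row = {
                    "taxon_a": self.taxon_ids[i],
                    "taxon_b": self.taxon_ids[j],
                    "r": self.corr[i, j],
                }
                if self.ci_low is not None:
                    row["ci_low"] = self.ci_low[i, j]
                    row["ci_high"] = self.ci_high[i, j]
                    row["significant"] = bool(self.significant[i, j])
                rows.append(row)
        return pd.DataFrame(rows)


def build_design(env: EnvMatrix, include_quadratic: bool = True) -> DesignMatrix:
    """Standardize covariates (mean 0, unit sample sd) and append squares.

    Samples with any missing covariate are dropped (listwise), logged.
    Quadratic columns are elementwise squares of the standardized linear
    columns, not re-standardized.
    """
    complete = ~env.missing_mask.any(axis=1)
    if complete.sum() < len(env.sample_ids):
        logger.info("dropped %d samples with missing covariates", int((~complete).sum()))
    values = env.values[complete, :]
    sample_ids = [s for s, k in zip(env.sample_ids, complete) if k]
    if values.shape[0] < 2:
        raise DataError("need at least 2 complete samples to build a design")
    sd = values.std(axis=0, ddof=1)
    for name, s in zip(env.variables, sd):
        if s == 0:
            raise DataError(f"zero-variance covariate: {name!r}")
    std = (values - values.mean(axis=0)) / sd
    columns = list(env.variables)
    if include_quadratic:
        std = np.hstack([std, std**2])
        columns = columns + [f"{v}^2" for v in env.variables]
    return DesignMatrix(sample_ids, columns, std)


def prevalence_filter(
    clr_matrix: ClrMatrix, ct: CountTable, min_prevalence: float = DEFAULT_PREVALENCE
) -> ClrMatrix:
    """Keep taxa present (count > 0) in at least ``min_prevalence`` of samples.

    Prevalence is computed on the raw counts of the full count table.
    """
    keep = []
    for taxon in clr_matrix.entity_ids:
        i = ct.taxon_ids.index(taxon)
        prevalence = float((ct.counts[i, :] > 0).mean())
        if prevalence >= min_prevalence:
            keep.append(taxon)
        else:
            logger.info("taxon %s below prevalence %.2f (%.3f); dropped", taxon, min_prevalence, prevalence)
    if not keep:
        raise DataError("no taxa pass the prevalence filter")
    idx = [clr_matrix.entity_ids.index(t) for t in keep]
    values = clr_matrix.values[idx, :]
    # re-center columns: dropping rows breaks the zero-sum clr constraint
    values = values - values.mean(axis=0)
    return ClrMatrix(keep, list(clr_matrix.sample_ids), values, clr_matrix.grain)


def _align(y: ClrMatrix | np.ndarray, x: DesignMatrix | np.ndarray):
    """Return (Y n x D, X n x p, sample ids, taxon ids, design columns)."""
    if isinstance(y, ClrMatrix) and isinstance(x, DesignMatrix):
        shared = [s for s in y.sample_ids if s in set(x.sample_ids)]
        if len(shared) < 2:
            raise DataError("fewer than 2 shared samples between response and design")
        yi = [y.sample_ids.index(s) for s in shared]
        xi = [x.sample_ids.index(s) for s in shared]
        return y.values[:, yi].T, x.values[xi, :], shared, list(y.entity_ids), list(x.columns)
    ya = np.asarray(y.values.T if isinstance(y, ClrMatrix) else y, dtype=float)
    xa = np.asarray(x.values if isinstance(x, DesignMatrix) else x, dtype=float)
    if ya.shape[0] != xa.shape[0]:
        raise DataError("response and design have different numbers of samples")
    sample_ids = [f"s{i}" for i in range(ya.shape[0])]
    taxon_ids = (
        list(y.entity_ids) if isinstance(y, ClrMatrix) else [f"t{j}" for j in range(ya.shape[1])]
    )
    columns = list(x.columns) if isinstance(x, DesignMatrix) else [f"x{k}" for k in range(xa.shape[1])]
    return ya, xa, sample_ids, taxon_ids, columns


def _marginal_loglik(resid: np.ndarray, loadings: np.ndarray, sigma2: np.ndarray) -> float:
    """Gaussian log-likelihood of residuals under cov = L L' + diag(sigma2)."""
    n, d_taxa = resid.shape
    cov = loadings @ loadings.T + np.diag(sigma2)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return -np.inf
    inv = np.linalg.inv(cov)
    quad = float(np.einsum("ij,jk,ik->", resid, inv, resid))
    return -0.5 * (n * d_taxa * np.log(2 * np.pi) + n * logdet + quad)


def _identify_loadings(loadings: np.ndarray, scores: np.ndarray):
    """Rotate to a lower-triangular, positive-diagonal leading block."""
    d = loadings.shape[1]
    if d == 0 or loadings.shape[0] < d:
        return loadings, scores
    top = loadings[:d, :]
    q, r = np.linalg.qr(top.T)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    return loadings @ q, scores @ q


def fit_lvm(
    y: ClrMatrix | np.ndarray,
    x: DesignMatrix | np.ndarray,
    n_latent: int = DEFAULT_N_LATENT,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> LVMFit:
    """Fit the latent variable model by alternating maximization.

    Given the latent contribution, coefficients are per-taxon least squares;
    given the coefficients, loadings, noise variances and posterior-mean
    scores come from factor analysis of the residual matrix. Deterministic
    for a given seed.
    """
    ymat, xmat, sample_ids, taxon_ids, columns = _align(y, x)
    n, d_taxa = ymat.shape
    p = xmat.shape[1]
    if n <= p + n_latent:
        raise DataError(f"too few samples (n={n}) for p={p} covariates and d={n_latent} latents")

    design = np.hstack([np.ones((n, 1)), xmat])
    latent_part = np.zeros((n, d_taxa))
    loadings = np.zeros((d_taxa, n_latent))
    scores = np.zeros((n, n_latent))
    sigma2 = np.ones(d_taxa)
    loglik = -np.inf
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        coef, *_ = np.linalg.lstsq(design, ymat - latent_part, rcond=None)
        resid = ymat - design @ coef
        if n_latent == 0:
            sigma2 = np.maximum(resid.var(axis=0, ddof=0), 1e-12)
            loglik = _marginal_loglik(resid, loadings, sigma2)
            converged = True
            break
        fa = FactorAnalysis(
            n_components=n_latent, svd_method="lapack", random_state=seed, max_iter=1000
        )
        fa.fit(resid)
        loadings = fa.components_.T
        sigma2 = np.maximum(fa.noise_variance_, 1e-12)
        scores = fa.transform(resid)
        latent_part = scores @ loadings.T
        new_loglik = _marginal_loglik(resid - resid.mean(axis=0), loadings, sigma2)
        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol * (1 + abs(loglik)):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    if not converged:
        logger.warning("LVM did not converge in %d iterations", max_iter)

    loadings, scores = _identify_loadings(loadings, scores)
    return LVMFit(
        taxon_ids=taxon_ids,
        sample_ids=sample_ids,
        intercept=coef[0, :].copy(),
        beta=coef[1:, :].T.copy(),
        loadings=loadings,
        sigma2=sigma2,
        scores=scores,
        n_latent=n_latent,
        design_columns=columns,
        loglik=float(loglik),
        converged=converged,
        n_iter=it,
    )


def _fitted_correlation(beta: np.ndarray, xmat: np.ndarray) -> np.ndarray:
    """Correlation matrix of fitted environmental responses X b_j."""
    eta = xmat @ beta.T  # n x D
    sd = eta.std(axis=0, ddof=1)
    d_taxa = beta.shape[0]
    corr = np.full((d_taxa, d_taxa), np.nan)
    ok = sd > 1e-12
    if ok.sum() >= 2:
        sub = np.corrcoef(eta[:, ok], rowvar=False)
        idx = np.where(ok)[0]
        corr[np.ix_(idx, idx)] = sub
    corr[np.ix_(np.where(ok)[0], np.where(ok)[0])] = np.clip(
        corr[np.ix_(np.where(ok)[0], np.where(ok)[0])], -1.0, 1.0
    )
    np.fill_diagonal(corr, 1.0)
    if (~ok).any():
        logger.info("%d taxa have constant fitted responses; correlations missing", int((~ok).sum()))
    return corr


def environmental_correlations(
    fit: LVMFit,
    x: DesignMatrix | np.ndarray,
    y: ClrMatrix | np.ndarray | None = None,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    seed: int = 0,
    level: float = 0.95,
    refit_max_iter: int = 40,
) -> EnvCorrelation:
    """Pairwise correlations of fitted environmental responses.

    When ``y`` is given, significance is assessed by a nonparametric
    bootstrap over samples: the model is refit on each resample and a pair
    is significant when the percentile interval at ``level`` excludes 0.
    """
    xmat = x.values if isinstance(x, DesignMatrix) else np.asarray(x)
    corr = _fitted_correlation(fit.beta, xmat)
    if y is None or n_bootstrap <= 0:
        return EnvCorrelation(list(fit.taxon_ids), corr)

    ymat, xmat, *_ = _align(y, x)
    n = ymat.shape[0]
    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, corr.shape[0], corr.shape[1]))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        refit = fit_lvm(
            ymat[idx, :], xmat[idx, :], n_latent=fit.n_latent, seed=seed, max_iter=refit_max_iter
        )
        boots[b] = _fitted_correlation(refit.beta, xmat)
    alpha = 1.0 - level
    lo = np.nanpercentile(boots, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(boots, 100 * (1 - alpha / 2), axis=0)
    significant = (lo > 0) | (hi < 0)
    np.fill_diagonal(significant, False)
    return EnvCorrelation(list(fit.taxon_ids), corr, lo, hi, significant)


def environmental_correlations_per_dimension(
    fit: LVMFit, x: DesignMatrix
) -> dict[str, np.ndarray]:
    """Correlations of fitted responses restricted to one covariate at a time.

    For covariate v, the fitted response uses only the columns belonging to
    v (its linear column and, when present, its square). With only a linear
    column the correlations are degenerate (+/-1 by coefficient sign); the
    quadratic term makes them informative.
    """
    out: dict[str, np.ndarray] = {}
    base_vars = [c for c in x.columns if not c.endswith("^2")]
    for var in base_vars:
        cols = [i for i, c in enumerate(x.columns) if c == var or c == f"{var}^2"]
        out[var] = _fitted_correlation(fit.beta[:, cols], x.values[:, cols])
    return out


def residual_correlations(fit: LVMFit) -> np.ndarray:
    """Residual (latent-factor) correlation matrix.

    rho_jk = l_j . l_k / sqrt((l_j . l_j + s_j^2)(l_k . l_k + s_k^2)),
    with unit diagonal by convention. Zero off-diagonal when d = 0.
    """
    d_taxa = len(fit.taxon_ids)
    if fit.n_latent == 0:
        return np.eye(d_taxa)
    gram = fit.loadings @ fit.loadings.T
    total = np.diag(gram) + fit.sigma2
    rho = gram / np.sqrt(np.outer(total, total))
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass
class PolyFit:
    """A least-squares polynomial fit with AIC-based model comparison."""

    degree: int
    coefficients: np.ndarray  # ascending order: intercept first
    rss: float
    aic: float
    adj_r2: float
    fstat: float
    df: tuple[int, int]
    pvalue: float
    aic_by_degree: dict[int, float] = field(default_factory=dict)


def fit_polynomial(x: np.ndarray, y: np.ndarray, degree: int) -> PolyFit:
    """OLS polynomial fit; AIC = n ln(RSS/n) + 2k with k = degree + 2.

    k counts the intercept, the polynomial coefficients and the error
    variance. RSS = 0 maps to AIC = -inf.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = xa.size
    if n < degree + 2:
        raise DataError(f"need at least {degree + 2} points for degree {degree}")
    if np.ptp(xa) == 0:
        raise DataError("all predictor values identical")
    design = np.vander(xa, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, ya, rcond=None)
    resid = ya - design @ coef
    rss = float(resid @ resid)
    tss = float(((ya - ya.mean()) ** 2).sum())
    k_reg = degree  # number of non-intercept regressors
    df1, df2 = k_reg, n - k_reg - 1
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df2 if df2 > 0 else np.nan
    if rss <= 1e-12 * max(1.0, tss):
        aic = -np.inf
        fstat = np.inf
        pvalue = 0.0
    else:
        aic = n * np.log(rss / n) + 2.0 * (degree + 2)
        fstat = (r2 / df1) / ((1.0 - r2) / df2) if df2 > 0 and r2 < 1 else np.inf
        pvalue = float(stats.f.sf(fstat, df1, df2)) if np.isfinite(fstat) else 0.0
    return PolyFit(degree, coef, rss, aic, adj_r2, float(fstat), (df1, df2), pvalue)


def univariate_best_fit(y: np.ndarray, x: np.ndarray) -> PolyFit:
    """AIC-selected best of degree-1 and degree-2 polynomial fits of y on x.

    A perfect degree-1 fit (RSS = 0, AIC -> -inf) wins by convention.
    """
    ya = np.asarray(y, dtype=float)
    xa = np.asarray(x, dtype=float)
    if ya.size < 5:
        raise DataError("univariate best fit needs n >= 5")
    fit1 = fit_polynomial(xa, ya, 1)
    fit2 = fit_polynomial(xa, ya, 2)
    best = fit1 if fit1.aic <= fit2.aic else fit2
    best.aic_by_degree = {1: fit1.aic, 2: fit2.aic}
    return best
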