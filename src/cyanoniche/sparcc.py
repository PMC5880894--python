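"""Compositional correlation inference (SparCC) with bootstrap significance.

Basis correlations among unobserved absolute abundances are estimated from
log-ratio variances under a sparsity assumption, with iterative exclusion of
strongly correlated pairs. Point estimates are medians over Dirichlet
fraction resamples; significance comes from permutation bootstraps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountTable, DataError

logger = logging.getLogger(__name__)

DEFAULT_N_RESAMPLE = 20
DEFAULT_N_BOOTSTRAP = 500
DEFAULT_EXCLUSION_THRESHOLD = 0.1
DEFAULT_MAX_EXCLUSIONS = 10
DEFAULT_R_THRESHOLD = 0.6
DEFAULT_P_THRESHOLD = 0.01


@dataclass
class CorrelationResult:
    taxon_ids: list[str]
    rho: np.ndarray
    pvals: np.ndarray | None = None
    n_resample: int = 0
    n_bootstrap: int = 0
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.taxon_ids, columns=self.taxon_ids)

    def pval_frame(self) -> pd.DataFrame:
        if self.pvals is None:
            raise ValueError("p-values not computed")
        return pd.DataFrame(self.pvals, index=self.taxon_ids, columns=self.taxon_ids)


def variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """Taxa x taxa matrix of log-ratio variances.

    ``fractions`` is samples x taxa, strictly positive per sample.
    t_ij = Var_samples[ln(f_i / f_j)] with the unbiased (n-1) estimator.
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 2 or f.shape[0] < 2:
        raise DataError("need at least 2 samples of fractions")
    if np.any(f <= 0):
        raise DataError("fractions must be strictly positive")
    logf = np.log(f)
    var = logf.var(axis=0, ddof=1)
    cov = np.cov(logf, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.clip(t, 0.0, None)


def basis_correlations(
    t_matrix: np.ndarray,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    max_exclusions: int = DEFAULT_MAX_EXCLUSIONS,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Solve for basis variances and correlations under sparsity.

    Returns (omega2, rho, excluded index pairs). With no exclusions the
    solution is the closed form omega_i^2 = (t_i - W) / (D - 2) with
    t_i = sum_j t_ij and W = sum_i t_i / (2(D-1)). Each exclusion round
    removes the off-diagonal pair with the largest |rho| above the threshold
    from the linear system and re-solves.

    Non-positive basis variances make the affected taxon's correlations NaN.
    """
    t = np.asarray(t_matrix, dtype=float)
    d = t.shape[0]
    if d < 3:
        raise DataError("basis estimation needs at least 3 taxa")
    include = np.ones((d, d), dtype=bool)
    np.fill_diagonal(include, False)
    excluded: list[tuple[int, int]] = []

    def solve() -> tuple[np.ndarray, np.ndarray]:
        # sum_{j in S_i} t_ij = |S_i| w_i + sum_{j in S_i} w_j  (rho ~ 0 assumption)
        a = include.astype(float)
        system = np.diag(include.sum(axis=1).astype(float)) + a
        rhs = (t * include).sum(axis=1)
        try:
            omega2 = np.linalg.solve(system, rhs)
        except np.linalg.LinAlgError:
            omega2, *_ = np.linalg.lstsq(system, rhs, rcond=None)
        bad = omega2 <= 0
        if bad.any():
            logger.info(
                "non-positive basis variance for %d taxa; correlations set missing", int(bad.sum())
            )
        omega = np.sqrt(np.where(bad, np.nan, omega2))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(omega, omega))
        over = np.nanmax(np.abs(rho)) if np.isfinite(rho).any() else 0.0
        if over > 1.0 + 1e-12:
            logger.debug("clipping correlations to [-1, 1] (max |rho| = %.3f)", over)
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return omega2, rho

    omega2, rho = solve()
    for _ in range(max_exclusions):
        candidate = np.abs(rho.copy())
        np.fill_diagonal(candidate, 0.0)
        candidate[~include] = 0.0
        candidate = np.nan_to_num(candidate, nan=0.0)
        i, j = np.unravel_index(int(np.argmax(candidate)), candidate.shape)
        if candidate[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
        excluded.append((min(i, j), max(i, j)))
        omega2, rho = solve()
    return omega2, rho, excluded


def sparcc_correlation(
    ct: CountTable,
    n_resample: int = DEFAULT_N_RESAMPLE,
    seed: int | np.random.Generator = 0,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    max_exclusions: int = DEFAULT_MAX_EXCLUSIONS,
) -> CorrelationResult:
    """Median basis correlation over Dirichlet fraction resamples.

    For each resample, per-sample fractions are drawn from
    Dirichlet(counts + 1); the point estimate is the elementwise median.
    """
    if len(ct.taxon_ids) < 3:
        raise DataError("SparCC needs at least 3 taxa")
    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = ct.counts.T  # samples x taxa
    rhos = np.empty((n_resample, counts.shape[1], counts.shape[1]))
    excluded_names: list[tuple[str, str]] = []
    for r in range(n_resample):
        fractions = np.vstack([rng.dirichlet(row + 1.0) for row in counts])
        t = variation_matrix(fractions)
        _, rho, excluded = basis_correlations(t, exclusion_threshold, max_exclusions)
        rhos[r] = rho
        if r == 0:
            excluded_names = [(ct.taxon_ids[i], ct.taxon_ids[j]) for i, j in excluded]
    with warnings.catch_warnings():
        # taxa with non-positive basis variance are NaN in every resample
        warnings.simplefilter("ignore", RuntimeWarning)
        rho_med = np.nanmedian(rhos, axis=0)
    rho_med = (rho_med + rho_med.T) / 2.0
    np.fill_diagonal(rho_med, 1.0)
    return CorrelationResult(
        list(ct.taxon_ids), rho_med, n_resample=n_resample, excluded_pairs=excluded_names
    )


def bootstrap_pvalues(
    ct: CountTable,
    rho_obs: np.ndarray,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    seed: int | np.random.Generator = 0,
    n_resample: int = DEFAULT_N_RESAMPLE,
) -> np.ndarray:
    """Two-sided permutation pseudo-p-values for observed correlations.

    Each bootstrap independently permutes every taxon's counts across
    samples (breaking associations, preserving marginals) and recomputes the
    correlation. p_ij = (1 + #{|rho_b| >= |rho_obs|}) / (B + 1).
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = np.abs(np.asarray(rho_obs))
    exceed = np.zeros_like(obs)
    n_samples = len(ct.sample_ids)
    for _ in range(n_bootstrap):
        permuted = np.vstack(
            [row[rng.permutation(n_samples)] for row in ct.counts]
        )
        null_ct = CountTable(list(ct.taxon_ids), list(ct.sample_ids), permuted)
        null = sparcc_correlation(null_ct, n_resample=n_resample, seed=rng)
        exceed += np.abs(null.rho) >= obs
    pvals = (1.0 + exceed) / (n_bootstrap + 1.0)
    np.fill_diagonal(pvals, 1.0)
    return pvals


def build_network(
    res: CorrelationResult,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Edge list of pairs with |rho| > r_threshold and p < p_threshold."""
    if res.pvals is None:
        raise ValueError("p-values required to build a network")
    rows = []
    d = len(res.taxon_ids)
    for i in range(d):
        for j in range(i + 1, d):
            r = res.rho[i, j]
            p = res.pvals[i, j]
            if np.isfinite(r) and abs(r) > r_threshold and p < p_threshold:
                rows.append(
                    {
                        "source": res.taxon_ids[i],
                        "target": res.taxon_ids[j],
                        "rho": r,
                        "p": p,
                        "sign": "positive" if r > 0 else "negative",
                    }
                )
    return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])
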