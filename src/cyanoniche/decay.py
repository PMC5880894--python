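"""Genetic distance and niche-similarity decay regressions.

p-distance is the proportion of aligned sites at which two sequences
differ, excluding sites where either has a gap. Decay analyses regress a
pairwise similarity statistic (co-occurrence r, environmental co-response,
or partner-interaction divergence |dr|) on pairwise genetic distance.

Caveat recorded in output metadata: pairs, not taxa, are the regression
unit; no correction for pair non-independence is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import DataError, SequenceSet
from .lvm import PolyFit, fit_polynomial

logger = logging.getLogger(__name__)

PAIR_CAVEAT = "pairs are the regression unit; no correction for pair non-independence"


@dataclass
class DecayRegression:
    degree: int
    coefficients: np.ndarray
    fstat: float
    df: tuple[int, int]
    pvalue: float
    adj_r2: float
    aic_by_degree: dict[int, float]
    n_pairs: int
    caveat: str = PAIR_CAVEAT

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coefficients": [float(c) for c in self.coefficients],
            "fstat": float(self.fstat),
            "df": list(self.df),
            "pvalue": float(self.pvalue),
            "adj_r2": float(self.adj_r2),
            "aic_by_degree": {str(k): float(v) for k, v in self.aic_by_degree.items()},
            "n_pairs": self.n_pairs,
            "caveat": self.caveat,
        }


def _from_polyfit(fit: PolyFit, aic_by_degree: dict[int, float], n_pairs: int) -> DecayRegression:
    return DecayRegression(
        degree=fit.degree,
        coefficients=fit.coefficients,
        fstat=fit.fstat,
        df=fit.df,
        pvalue=fit.pvalue,
        adj_r2=fit.adj_r2,
        aic_by_degree=aic_by_degree,
        n_pairs=n_pairs,
    )


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites, excluding sites gapped in either sequence."""
    if len(seq_a) != len(seq_b):
        raise DataError("sequences have different lengths")
    compared = 0
    mismatches = 0
    for a, b in zip(seq_a, seq_b):
        if a == "-" or b == "-":
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise DataError("no comparable (gap-free) sites")
    return mismatches / compared


def pairwise_distance_matrix(seqs: SequenceSet) -> pd.DataFrame:
    """Symmetric p-distance matrix over all sequence pairs."""
    ids = seqs.ids()
    if len(ids) < 2:
        raise DataError("need at least 2 sequences")
    d = np.zeros((len(ids), len(ids)))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d[i, j] = d[j, i] = p_distance(seqs[ids[i]], seqs[ids[j]])
    return pd.DataFrame(d, index=ids, columns=ids)


def make_pair_table(
    stat: pd.DataFrame,
    distances: pd.DataFrame,
    pvals: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Tidy one-row-per-unordered-pair table joining a statistic to distances.

    ``stat`` and ``distances`` are symmetric square frames sharing ids.
    When ``pvals`` is given, a ``significant`` column marks p < threshold.
    """
    ids = [t for t in stat.index if t in set(distances.index)]
    if len(ids) < 2:
        raise DataError("fewer than 2 shared taxa between statistic and distances")
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            row = {
                "taxon_a": a,
                "taxon_b": b,
                "distance": float(distances.loc[a, b]),
                "stat": float(stat.loc[a, b]),
            }
            if pvals is not None:
                row["significant"] = bool(pvals.loc[a, b] < p_threshold)
            rows.append(row)
    return pd.DataFrame(rows)


def _regress(distance: np.ndarray, stat: np.ndarray, max_degree: int) -> DecayRegression:
    if np.ptp(distance) == 0:
        raise DataError("all pairwise distances identical; decay regression undefined")
    fits = {deg: fit_polynomial(distance, stat, deg) for deg in range(1, max_degree + 1)}
    aics = {deg: f.aic for deg, f in fits.items()}
    best_degree = min(aics, key=lambda deg: (aics[deg], deg))
    return _from_polyfit(fits[best_degree], aics, len(distance))


def cooccurrence_decay(pairs: pd.DataFrame, only_significant: bool = True) -> DecayRegression:
    """Degree-1 regression of pairwise co-occurrence r on genetic distance."""
    sub = pairs
    if only_significant and "significant" in pairs.columns:
        sub = pairs[pairs["significant"]]
    if len(sub) < 3:
        raise DataError(f"need at least 3 pairs, got {len(sub)}")
    return _regress(sub["distance"].to_numpy(), sub["stat"].to_numpy(), max_degree=1)


def niche_decay(
    pairs: pd.DataFrame, max_degree: int = 2, only_significant: bool = True
) -> DecayRegression:
    """AIC-selected polynomial regression of niche co-response on distance."""
    sub = pairs
    if only_significant and "significant" in pairs.columns:
        sub = pairs[pairs["significant"]]
    if len(sub) < max_degree + 2:
        raise DataError(f"need at least {max_degree + 2} pairs, got {len(sub)}")
    if len(sub) == max_degree + 2:
        logger.warning("fitting at the minimum pair count; residual df is 1")
    return _regress(sub["distance"].to_numpy(), sub["stat"].to_numpy(), max_degree=max_degree)


def partner_divergence(
    partner_corr: pd.DataFrame, distances: pd.DataFrame
) -> Mapping[str, DecayRegression]:
    """Per-partner regressions of |dr| between focal pairs on their distance.

    ``partner_corr`` is focal taxa (rows) x partners (columns) of
    correlations with each partner. For each partner, the response for a
    focal pair (A, B) is |r_AP - r_BP|. Partners with more than half of the
    focal correlations missing are skipped.
    """
    focal = [t for t in partner_corr.index if t in set(distances.index)]
    if len(focal) < 2:
        raise DataError("need at least 2 focal taxa")
    n_pairs = len(focal) * (len(focal) - 1) // 2
    if n_pairs < 3:
        raise DataError("a single focal pair is insufficient for regression")
    results: dict[str, DecayRegression] = {}
    for partner in partner_corr.columns:
        r = partner_corr.loc[focal, partner]
        if r.isna().mean() > 0.5:
            logger.info("partner %s skipped: correlations missing for >half of focal taxa", partner)
            continue
        rows = []
        for i, a in enumerate(focal):
            for b in focal[i + 1:]:
                if pd.isna(r[a]) or pd.isna(r[b]):
                    continue
                rows.append((float(distances.loc[a, b]), abs(float(r[a]) - float(r[b]))))
        if len(rows) < 3:
            logger.info("partner %s skipped: fewer than 3 usable pairs", partner)
            continue
        arr = np.array(rows)
        results[partner] = _regress(arr[:, 0], arr[:, 1], max_degree=1)
    return results
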