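"""Conditionally rare taxa: bimodality-based detection and group enrichment.

A taxon is conditionally rare when its per-sample relative-abundance series
is strongly bimodal (coefficient >= 0.90 by default) and it reaches at least
a minimum relative abundance (0.005) in some sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountTable, DataError

logger = logging.getLogger(__name__)

DEFAULT_B_THRESHOLD = 0.90
DEFAULT_MAXREL_THRESHOLD = 0.005


@dataclass
class CrtResult:
    """Per-taxon conditional-rarity calls plus the thresholds used."""

    table: pd.DataFrame  # index taxon; columns b, max_rel, is_crt, reason
    b_threshold: float
    maxrel_threshold: float

    @property
    def flags(self) -> pd.Series:
        return self.table["is_crt"]


def bimodality_coefficient(x: Sequence[float]) -> float:
    """Sarle's bimodality coefficient from bias-corrected sample moments.

    b = (g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3))) with g1 the sample
    skewness and g2 the sample excess kurtosis.
    """
    arr = np.asarray(x, dtype=float)
    n = arr.size
    if n < 4:
        raise DataError(f"bimodality coefficient needs n >= 4, got {n}")
    if not np.all(np.isfinite(arr)):
        raise DataError("non-finite values in abundance series")
    if np.ptp(arr) == 0:
        raise DataError("zero variance: bimodality coefficient undefined")
    g1 = stats.skew(arr, bias=False)
    g2 = stats.kurtosis(arr, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def detect_crt(
    ct: CountTable,
    b_threshold: float = DEFAULT_B_THRESHOLD,
    maxrel_threshold: float = DEFAULT_MAXREL_THRESHOLD,
) -> CrtResult:
    """Flag taxa whose relative-abundance series is bimodal and peaks high.

    Taxa for which the coefficient is undefined (zero variance, too few
    samples) are marked not-CRT with the reason recorded.
    """
    rel = ct.relative_abundances()
    rows = []
    for i, taxon in enumerate(ct.taxon_ids):
        series = rel[i, :]
        max_rel = float(series.max())
        b = np.nan
        reason = ""
        try:
            b = bimodality_coefficient(series)
        except DataError as exc:
            reason = str(exc)
            logger.info("taxon %s marked not-CRT: %s", taxon, reason)
        is_crt = (not reason) and b >= b_threshold and max_rel >= maxrel_threshold
        rows.append({"taxon": taxon, "b": b, "max_rel": max_rel, "is_crt": is_crt, "reason": reason})
    table = pd.DataFrame(rows).set_index("taxon")
    return CrtResult(table, b_threshold, maxrel_threshold)


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Sums P(X = k) over all k in the support whose probability does not
    exceed that of the observed table (with a small relative tolerance for
    floating-point ties). Degenerate margins give p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    a = t[0, 0]
    row1 = t[0].sum()
    col1 = t[:, 0].sum()
    n = t.sum()
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        logger.info("degenerate 2x2 margins; Fisher p set to 1")
        return 1.0
    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def crt_enrichment_test(
    crt_flags: Sequence[bool], focal_mask: Sequence[bool]
) -> tuple[np.ndarray, float]:
    """2x2 enrichment table and two-sided Fisher exact p for a focal group.

    The background is all taxa excluding the focal group. Table layout:
    [[CRT_focal, nonCRT_focal], [CRT_background, nonCRT_background]].
    """
    flags = np.asarray(crt_flags, dtype=bool)
    focal = np.asarray(focal_mask, dtype=bool)
    if flags.shape != focal.shape:
        raise ValueError("flag and mask lengths differ")
    if not focal.any():
        raise DataError("empty focal group")
    if focal.all():
        raise DataError("empty background group")
    table = np.array(
        [
            [int((flags & focal).sum()), int((~flags & focal).sum())],
            [int((flags & ~focal).sum()), int((~flags & ~focal).sum())],
        ]
    )
    return table, fisher_exact_two_sided(table)


def truncate_proportion(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Proportion truncated (not rounded) toward zero at ``decimals`` places.

    Matches the convention of summary tables that print 1/6 as 0.16.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    scale = 10**decimals
    return math.floor(numerator / denominator * scale) / scale


def crt_summary(result: CrtResult, group_map: Mapping[str, str]) -> pd.DataFrame:
    """Per-group CRT counts, truncated proportions and enrichment p-values.

    Includes a whole-community row (no test) plus one row per group in
    ``group_map`` (taxon -> group), each tested against the rest of the
    community.
    """
    flags = result.flags
    taxa = list(flags.index)
    rows = [
        {
            "group": "whole community",
            "n_crt": int(flags.sum()),
            "n_total": len(taxa),
            "proportion": truncate_proportion(int(flags.sum()), len(taxa)),
            "fisher_p": np.nan,
        }
    ]
    for group in sorted(set(group_map.values())):
        mask = np.array([group_map.get(t) == group for t in taxa])
        _, p = crt_enrichment_test(flags.to_numpy(), mask)
        n_crt = int(flags.to_numpy()[mask].sum())
        n_total = int(mask.sum())
        rows.append(
            {
                "group": group,
                "n_crt": n_crt,
                "n_total": n_total,
                "proportion": truncate_proportion(n_crt, n_total),
                "fisher_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("group")
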