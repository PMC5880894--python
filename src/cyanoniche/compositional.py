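"""Zero replacement and centered log-ratio (clr) transforms.

Two grains are supported: genus totals relative to the whole community
(inter-genus) and strain counts relative to their genus total (intra-genus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CountTable, DataError

logger = logging.getLogger(__name__)

GRAIN_INTER = "inter-genus"
GRAIN_INTRA = "intra-genus"


@dataclass
class ClrMatrix:
    """Entities x samples matrix of clr-transformed relative abundances."""

    entity_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    grain: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.sample_ids)):
            raise DataError("clr values shape inconsistent with ids")
        if not np.all(np.isfinite(self.values)):
            raise DataError("clr matrix contains non-finite entries")
        colsums = self.values.sum(axis=0)
        if np.any(np.abs(colsums) > 1e-9 * max(1.0, np.abs(self.values).max())):
            raise DataError("clr columns do not sum to zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.sample_ids)


def multiplicative_zero_replacement(composition: np.ndarray, delta: float) -> np.ndarray:
    """Replace zeros by ``delta``, shrinking nonzero parts multiplicatively.

    Zeros become delta; each nonzero x_i becomes x_i * (1 - Z*delta) with Z
    the number of zeros, so the output is strictly positive and sums to 1.
    """
    x = np.asarray(composition, dtype=float)
    if np.any(x < 0):
        raise DataError("composition has negative parts")
    if not np.isclose(x.sum(), 1.0, atol=1e-8):
        raise DataError("composition must sum to 1")
    zeros = x == 0
    n_zero = int(zeros.sum())
    if n_zero == x.size:
        raise DataError("all-zero composition")
    if n_zero == 0:
        return x.copy()
    if delta <= 0 or delta >= x[~zeros].min():
        raise DataError("delta must be positive and smaller than the smallest nonzero part")
    if n_zero * delta >= 1.0:
        raise DataError("delta too large: total replaced mass must stay below 1")
    out = x * (1.0 - n_zero * delta)
    out[zeros] = delta
    return out


def clr(composition: np.ndarray) -> np.ndarray:
    """Centered log-ratio: ln(x_i / geometric mean). Requires positive parts."""
    x = np.asarray(composition, dtype=float)
    if np.any(x <= 0):
        raise DataError("clr requires strictly positive parts; apply zero replacement first")
    logs = np.log(x)
    return logs - logs.mean()


def default_delta(relative: np.ndarray) -> float:
    """Half the smallest nonzero relative abundance in the matrix."""
    nz = relative[relative > 0]
    if nz.size == 0:
        raise DataError("matrix has no nonzero entries")
    return 0.5 * float(nz.min())


def _clr_columns(relative: np.ndarray, delta: float | None) -> np.ndarray:
    if delta is None:
        delta = default_delta(relative)
    out = np.empty_like(relative, dtype=float)
    for j in range(relative.shape[1]):
        col = relative[:, j]
        nz = col[col > 0]
        n_zero = int((col == 0).sum())
        # cap so delta stays below the smallest nonzero part and the total
        # replaced mass stays well below 1 even in zero-heavy columns
        d = min(delta, 0.5 * float(nz.min()))
        if n_zero:
            d = min(d, 0.5 / n_zero)
        out[:, j] = clr(multiplicative_zero_replacement(col, d))
    return out


def clr_inter_genus(
    ct: CountTable,
    genus_map: Mapping[str, str],
    delta: float | None = None,
    other_label: str = "other",
) -> ClrMatrix:
    """clr of (genus totals, pooled remainder) compositions per sample.

    Taxa absent from ``genus_map`` are pooled into one ``other`` part.
    """
    genera = sorted(set(genus_map.values()))
    if other_label in genera:
        raise DataError(f"genus name collides with pool label {other_label!r}")
    depths = ct.sample_depths()
    if np.any(depths == 0):
        zero = ct.sample_ids[int(np.argmin(depths))]
        raise DataError(f"sample {zero!r} has zero depth; filter samples first")
    pooled = np.zeros((len(genera) + 1, len(ct.sample_ids)))
    for i, taxon in enumerate(ct.taxon_ids):
        genus = genus_map.get(taxon)
        row = len(genera) if genus is None else genera.index(genus)
        pooled[row, :] += ct.counts[i, :]
    relative = pooled / depths
    values = _clr_columns(relative, delta)
    return ClrMatrix(genera + [other_label], list(ct.sample_ids), values, GRAIN_INTER)


def clr_intra_genus(
    ct: CountTable,
    genus_taxa: Sequence[str],
    delta: float | None = None,
) -> ClrMatrix:
    """clr of strain compositions within one genus, per sample.

    Samples where the genus total is zero are dropped (composition
    undefined there) with a log entry.
    """
    if len(genus_taxa) < 2:
        raise DataError("intra-genus clr requires at least 2 strains")
    sub = ct.select_taxa(genus_taxa)
    totals = sub.counts.sum(axis=0)
    keep = totals > 0
    dropped = [s for s, k in zip(sub.sample_ids, keep) if not k]
    if dropped:
        logger.info(
            "dropped %d samples with zero genus total from intra-genus clr: %s",
            len(dropped),
            ", ".join(dropped),
        )
    if not keep.any():
        raise DataError("genus absent from every sample")
    counts = sub.counts[:, keep]
    relative = counts / counts.sum(axis=0)
    values = _clr_columns(relative, delta)
    kept_samples = [s for s, k in zip(sub.sample_ids, keep) if k]
    return ClrMatrix(list(genus_taxa), kept_samples, values, GRAIN_INTRA)
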