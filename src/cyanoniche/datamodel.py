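"""Core data types, TSV/FASTA readers and writers, and depth filtering.

All tabular files are tab-delimited UTF-8 with a header row. Counts are
taxa x samples with taxon ids in the first column; environmental tables are
samples x variables with sample ids in the first column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SEQUENCE_ALPHABET = frozenset("ACGT-")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """Taxa x samples table of non-negative integer read counts.

    ``sample_meta`` maps sample id to a mapping with optional ``date``
    (ISO-8601 string) and ``site`` keys.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sample_meta: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataError("counts must be a 2-D array")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise DataError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise DataError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise DataError("counts must be non-negative")
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_depths(self) -> np.ndarray:
        """Per-sample column sums."""
        return self.counts.sum(axis=0)

    def relative_abundances(self) -> np.ndarray:
        """Taxa x samples matrix of within-sample proportions."""
        depths = self.sample_depths()
        if np.any(depths == 0):
            raise DataError("cannot compute relative abundances: zero-depth sample")
        return self.counts / depths

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_taxa(self, taxa: Sequence[str]) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return CountTable(list(taxa), list(self.sample_ids), self.counts[idx, :], dict(self.sample_meta))

    def select_samples(self, samples: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in samples]
        return CountTable(
            list(self.taxon_ids),
            list(samples),
            self.counts[:, idx],
            {s: self.sample_meta[s] for s in samples if s in self.sample_meta},
        )


@dataclass
class EnvMatrix:
    """Samples x environmental-variables matrix with a missing-value mask.

    ``units`` maps variable name to its unit string (may be empty).
    """

    sample_ids: list[str]
    variables: list[str]
    values: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variables)):
            raise DataError(
                f"env values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variables)} variables"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.variables, "variable")
        for v in self.variables:
            self.units.setdefault(v, "")

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean samples x variables mask, True where the value is missing."""
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variables)

    def align_to(self, ct: CountTable) -> "EnvMatrix":
        """Restrict to the samples shared with ``ct``, in the table's order."""
        shared = [s for s in ct.sample_ids if s in set(self.sample_ids)]
        if not shared:
            raise DataError("no overlapping sample ids between count table and environmental table")
        idx = [self.sample_ids.index(s) for s in shared]
        return EnvMatrix(shared, list(self.variables), self.values[idx, :], dict(self.units))


@dataclass
class SequenceSet:
    """Identifier -> aligned nucleotide string over {A, C, G, T, -}."""

    sequences: dict[str, str]
    uniform_length: bool = True

    def __post_init__(self) -> None:
        if self.uniform_length and self.sequences:
            lengths = {len(s) for s in self.sequences.values()}
            if len(lengths) > 1:
                raise DataError(f"sequences have ragged lengths: {sorted(lengths)}")
        for name, seq in self.sequences.items():
            bad = set(seq) - SEQUENCE_ALPHABET
            if bad:
                raise DataError(f"sequence {name!r} contains invalid symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]

    def __iter__(self):
        return iter(self.sequences)

    @property
    def length(self) -> int:
        if not self.sequences:
            raise DataError("empty sequence set")
        return len(next(iter(self.sequences.values())))

    def ids(self) -> list[str]:
        return list(self.sequences)


def read_count_table(path: str | Path, meta_path: str | Path | None = None) -> CountTable:
    """Read a taxa x samples TSV of integer counts.

    First column holds taxon ids; the header row holds sample ids. If
    ``meta_path`` is not given, a sidecar ``<stem>.meta.tsv`` next to the
    count file is used when present. Metadata rows whose sample id does not
    occur in the count table are ignored with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise DataError(f"{path}: no taxa")
    if df.shape[1] == 0:
        raise DataError(f"{path}: no samples")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"{path}: duplicate taxon id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise DataError(f"{path}: duplicate sample id {dup!r}")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (taxon, cell) in enumerate(zip(df.index, df[col])):
            try:
                counts[i, j] = int(str(cell).strip())
            except (TypeError, ValueError):
                raise DataError(
                    f"{path}: non-integer count {cell!r} at taxon {taxon!r}, sample {col!r}"
                ) from None

    meta: dict[str, dict[str, str]] = {}
    if meta_path is None:
        candidate = path.with_suffix(".meta.tsv")
        meta_path = candidate if candidate.exists() else None
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
        known = set(df.columns)
        for sid, row in mdf.iterrows():
            if sid not in known:
                logger.warning("metadata sample id %r not in count table; ignored", sid)
                continue
            meta[str(sid)] = {k: str(v) for k, v in row.items() if pd.notna(v)}
    return CountTable(list(df.index.astype(str)), list(df.columns.astype(str)), counts, meta)


def write_count_table(ct: CountTable, path: str | Path) -> None:
    ct.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def read_env_table(path: str | Path, units: Mapping[str, str] | None = None) -> EnvMatrix:
    """Read a samples x variables TSV; blank cells become missing values."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"{path}: duplicated sample id {dup!r}")
    values = df.to_numpy(dtype=float)
    return EnvMatrix(
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
        values,
        dict(units or {}),
    )


def write_env_table(env: EnvMatrix, path: str | Path) -> None:
    env.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_fasta(path: str | Path, uniform_length: bool = True) -> SequenceSet:
    """Read FASTA into a :class:`SequenceSet`; uppercases and maps U to T."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise DataError(f"{path}: duplicate sequence id {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper().replace("U", "T")
    return SequenceSet(sequences, uniform_length=uniform_length)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.sequences.items()]
    SeqIO.write(records, str(path), "fasta-2line")


def filter_low_depth_samples(ct: CountTable, min_reads: int = 1000) -> CountTable:
    """Drop samples with fewer than ``min_reads`` total reads.

    The boundary is strict: a sample with exactly ``min_reads`` is retained.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = ct.sample_depths() >= min_reads
    if not keep.any():
        raise DataError("empty table: all samples below depth threshold")
    dropped = [s for s, k in zip(ct.sample_ids, keep) if not k]
    if dropped:
        logger.info("dropped %d low-depth samples: %s", len(dropped), ", ".join(dropped))
    kept = [s for s, k in zip(ct.sample_ids, keep) if k]
    return ct.select_samples(kept)
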