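"""Entropy-based decomposition of aligned reads into exact sequence variants.

Reads are recursively partitioned at the highest-entropy alignment position
until no position exceeds the entropy threshold. Child partitions whose most
abundant unique sequence falls below the minimum substantive abundance are
discarded as noise; their reads are tallied, never reassigned.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .datamodel import CountTable, DataError, SequenceSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUBSTANTIVE_ABUNDANCE = 500
# Entropy split threshold in nats; the upstream decomposition tool's default.
DEFAULT_ENTROPY_THRESHOLD = 0.0965

_SYMBOLS = "ACGT-"


@dataclass
class MEDNode:
    """A final partition of reads identical at every split position."""

    node_id: str
    representative: str
    read_count: int
    members: dict[str, int]
    split_positions: list[int] = field(default_factory=list)


@dataclass
class MEDResult:
    nodes: list[MEDNode]
    noise_reads: int
    total_reads: int
    entropy_threshold: float
    min_substantive_abundance: int

    def node_of_sequence(self) -> dict[str, str]:
        """Map each retained unique sequence to its node id."""
        return {seq: node.node_id for node in self.nodes for seq in node.members}


def _as_multiset(reads: Mapping[str, int] | SequenceSet) -> dict[str, int]:
    if isinstance(reads, SequenceSet):
        multiset: dict[str, int] = Counter(reads.sequences.values())
        return dict(multiset)
    return {s: int(m) for s, m in reads.items()}


def positional_entropy(reads: Mapping[str, int] | SequenceSet) -> np.ndarray:
    """Shannon entropy (nats) of the symbol distribution at each position.

    ``reads`` maps unique sequence to multiplicity (or is a SequenceSet whose
    records each count once). Gaps are a fifth symbol.
    """
    multiset = _as_multiset(reads)
    if not multiset:
        raise DataError("empty read set")
    for seq, mult in multiset.items():
        if mult < 1:
            raise DataError(f"multiplicity < 1 for sequence {seq!r}")
    lengths = {len(s) for s in multiset}
    if len(lengths) != 1:
        raise DataError(f"reads have ragged lengths: {sorted(lengths)}")
    length = lengths.pop()

    seqs = list(multiset)
    weights = np.array([multiset[s] for s in seqs], dtype=float)
    encoded = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(len(seqs), length)
    total = weights.sum()
    entropy = np.zeros(length)
    for symbol in _SYMBOLS.encode("ascii"):
        freq = ((encoded == symbol) * weights[:, None]).sum(axis=0) / total
        nz = freq > 0
        entropy[nz] -= freq[nz] * np.log(freq[nz])
    return entropy


def decompose(
    reads: Mapping[str, int] | SequenceSet,
    min_substantive_abundance: int = DEFAULT_MIN_SUBSTANTIVE_ABUNDANCE,
    entropy_threshold: float = DEFAULT_ENTROPY_THRESHOLD,
) -> MEDResult:
    """Partition reads into exact-variant nodes.

    Recursion: compute positional entropies of the current member multiset;
    if the maximum exceeds ``entropy_threshold``, split members by their
    symbol at the arg-max position (ties broken toward the lowest index).
    Children whose most abundant unique sequence count is below
    ``min_substantive_abundance`` are discarded and counted as noise. If no
    child survives, the current partition is kept whole as a node.
    """
    if min_substantive_abundance < 1:
        raise ValueError("min_substantive_abundance must be >= 1")
    multiset = _as_multiset(reads)
    if not multiset:
        raise DataError("empty read set")
    total = sum(multiset.values())

    nodes: list[MEDNode] = []
    noise = 0

    if max(multiset.values()) < min_substantive_abundance:
        logger.warning(
            "most abundant unique sequence (%d reads) below -M %d; all %d reads filtered",
            max(multiset.values()),
            min_substantive_abundance,
            total,
        )
        return MEDResult([], total, total, entropy_threshold, min_substantive_abundance)

    def recurse(members: dict[str, int], path: list[int]) -> None:
        nonlocal noise
        entropy = positional_entropy(members)
        pos = int(np.argmax(entropy))  # argmax takes the lowest index on ties
        if entropy[pos] > entropy_threshold:
            children: dict[str, dict[str, int]] = {}
            for seq, mult in members.items():
                children.setdefault(seq[pos], {})[seq] = mult
            surviving = {
                sym: child
                for sym, child in children.items()
                if max(child.values()) >= min_substantive_abundance
            }
            if surviving:
                for sym in sorted(children):
                    child = children[sym]
                    if sym in surviving:
                        recurse(child, path + [pos])
                    else:
                        noise += sum(child.values())
                return
            # no split survives the abundance filter: keep the partition whole
        representative = max(members, key=lambda s: (members[s], s))
        nodes.append(
            MEDNode(
                node_id=f"node{len(nodes) + 1:04d}",
                representative=representative,
                read_count=sum(members.values()),
                members=dict(members),
                split_positions=list(path),
            )
        )

    recurse(multiset, [])
    retained = sum(n.read_count for n in nodes)
    assert retained + noise == total, "read conservation violated"
    return MEDResult(nodes, noise, total, entropy_threshold, min_substantive_abundance)


def node_sample_counts(result: MEDResult, per_sample_reads: Mapping[str, Mapping[str, int]]) -> CountTable:
    """Tally node x sample counts from per-sample read multisets.

    ``per_sample_reads`` maps sample id -> {sequence: multiplicity}. Reads
    whose sequence was noise-filtered do not appear in the output.
    """
    seq_to_node = {}
    for node in result.nodes:
        for seq in node.members:
            seq_to_node[seq] = node.node_id
    node_ids = [n.node_id for n in result.nodes]
    sample_ids = list(per_sample_reads)
    counts = np.zeros((len(node_ids), len(sample_ids)), dtype=np.int64)
    node_index = {nid: i for i, nid in enumerate(node_ids)}
    for j, sample in enumerate(sample_ids):
        for seq, mult in per_sample_reads[sample].items():
            nid = seq_to_node.get(seq)
            if nid is not None:
                counts[node_index[nid], j] += mult
    return CountTable(node_ids, sample_ids, counts)


def read_sized_fasta(path: str | Path) -> dict[str, int]:
    """Read a FASTA whose headers may carry ``;size=N`` abundance annotations.

    Records without an annotation count once. Identical sequences are pooled.
    """
    from Bio import SeqIO

    multiset: Counter[str] = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        size = 1
        for part in rec.id.split(";"):
            if part.startswith("size="):
                size = int(part[len("size="):])
        multiset[str(rec.seq).upper().replace("U", "T")] += size
    return dict(multiset)
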