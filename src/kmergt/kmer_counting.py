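"""Stream reads and accumulate observed kmer support per allele node.

Every length-k window of every read (skipping windows containing non-ACGT
bases) is canonicalized and looked up in the kmer index; each allele node
the kmer represents is incremented once per occurrence. A kmer hitting
multiple nodes increments all of them — ambiguity is not resolved here,
the count model absorbs it. The result is deterministic and independent of
read order or how the stream is chunked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .kmer_index import KmerIndex, encode_sequence
from .variant_graph import VariantGraph

logger = logging.getLogger("kmergt")


@dataclass
class NodeCounts:
    """Observed kmer-support count per allele node."""

    counts: dict[int, int] = field(default_factory=dict)
    total_reads: int = 0
    total_kmers: int = 0

    def get(self, node: int) -> int:
        return self.counts.get(node, 0)

    def add(self, other: "NodeCounts") -> "NodeCounts":
        merged = dict(self.counts)
        for node, c in other.counts.items():
            merged[node] = merged.get(node, 0) + c
        return NodeCounts(
            counts=merged,
            total_reads=self.total_reads + other.total_reads,
            total_kmers=self.total_kmers + other.total_kmers,
        )


def count_reads(reads: Iterable[str], index: KmerIndex) -> NodeCounts:
    """Accumulate node counts over a read stream.

    Reads shorter than k contribute nothing. Windows containing non-ACGT
    bases are skipped; everything else is canonicalized and looked up.
    """
    k = index.k
    counts: dict[int, int] = {}
    lookup = index.lookup_table
    total_reads = 0
    total_kmers = 0
    for read in reads:
        total_reads += 1
        if len(read) < k:
            continue
        codes, valid = encode_sequence(read, k)
        total_kmers += int(valid.sum())
        for code in codes[valid].tolist():
            nodes = lookup.get(code)
            if nodes:
                for node in nodes:
                    counts[node] = counts.get(node, 0) + 1
    return NodeCounts(counts=counts, total_reads=total_reads, total_kmers=total_kmers)


def variant_counts(
    node_counts: NodeCounts, graph: VariantGraph, variant_id: int
) -> tuple[int, int]:
    """(K_ref, K_alt): observed counts at a variant's two allele nodes,
    each already summed over the allele's selected kmer set."""
    if variant_id not in graph.variant_nodes:
        raise KeyError(f"unknown variant id {variant_id}")
    ref_node, alt_node = graph.variant_nodes[variant_id]
    return node_counts.get(ref_node), node_counts.get(alt_node)


def write_node_counts(node_counts: NodeCounts, path: str | Path) -> None:
    """Dump counts as tab-separated ``node_id<TAB>count`` lines, sorted by
    node id, with a small commented header recording totals."""
    with open(path, "w") as fh:
        fh.write(f"#total_reads\t{node_counts.total_reads}\n")
        fh.write(f"#total_kmers\t{node_counts.total_kmers}\n")
        for node in sorted(node_counts.counts):
            fh.write(f"{node}\t{node_counts.counts[node]}\n")


def read_node_counts(path: str | Path) -> NodeCounts:
    """Read a dump written by :func:`write_node_counts`."""
    counts: dict[int, int] = {}
    total_reads = 0
    total_kmers = 0
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#"):
                if fields[0] == "#total_reads":
                    total_reads = int(fields[1])
                elif fields[0] == "#total_kmers":
                    total_kmers = int(fields[1])
                continue
            counts[int(fields[0])] = int(fields[1])
    return NodeCounts(counts=counts, total_reads=total_reads, total_kmers=total_kmers)
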