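"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's graph machinery: haplotype
genomes are written out as plain strings and scanned window by window, so
they provide an independent check of the graph-walk implementations.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from kmergt import SimulationConfig, simulate_all

_COMP = str.maketrans("ACGT", "TGCA")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_canonical(kmer: str) -> str:
    """Lexicographic-on-codes canonical form, computed from strings."""
    rc = revcomp(kmer)
    fwd = tuple(_CODE[c] for c in kmer)
    rev = tuple(_CODE[c] for c in rc)
    return kmer if fwd <= rev else rc


def oracle_apply_haplotype(reference_seq: str, variants, alleles) -> str:
    """Reference with alt alleles spliced in; independent of the package's
    own splicing code."""
    pieces = []
    cursor = 0
    for v in variants:
        pieces.append(reference_seq[cursor : v.position])
        pieces.append(v.alt_allele if alleles[v.id] else v.ref_allele)
        cursor = v.position + len(v.ref_allele)
    pieces.append(reference_seq[cursor:])
    return "".join(pieces)


def oracle_kmer_counts(seq: str, k: int) -> Counter:
    """Canonical kmer multiset of one string (windows with N skipped)."""
    counts: Counter = Counter()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if set(window) <= set("ACGT"):
            counts[oracle_canonical(window)] += 1
    return counts


def oracle_population_frequency(reference_seq: str, variants, panel, k: int) -> dict:
    """Write out all 2n haplotype genomes, count canonical kmers, divide
    by the number of individuals."""
    n = panel.n_individuals
    total: Counter = Counter()
    for h in range(2 * n):
        genome = oracle_apply_haplotype(reference_seq, variants, panel.haplotypes[:, h])
        total += oracle_kmer_counts(genome, k)
    return {kmer: c / n for kmer, c in total.items()}


def oracle_duplicate_count(
    reference_seq: str, variants, panel, individual: int, kmers: set[str], k: int
) -> int:
    """Occurrences of a canonical kmer set in one individual's written-out
    diploid genome."""
    targets = {oracle_canonical(km) for km in kmers}
    d = 0
    for h in (2 * individual, 2 * individual + 1):
        genome = oracle_apply_haplotype(reference_seq, variants, panel.haplotypes[:, h])
        counts = oracle_kmer_counts(genome, k)
        d += sum(counts[t] for t in targets)
    return d


def oracle_scan_reads(reads, indexed_kmers: dict) -> Counter:
    """Quadratic scanner: every read window against every indexed kmer
    string; returns node -> count."""
    counts: Counter = Counter()
    for read in reads:
        for kmer, nodes in indexed_kmers.items():
            k = len(kmer)
            rc = revcomp(kmer)
            for i in range(len(read) - k + 1):
                window = read[i : i + k]
                if window == kmer or window == rc:
                    for node in nodes:
                        counts[node] += 1
    return counts


def concordance(calls, truth) -> float:
    pred = np.array([int(c.genotype) for c in calls])
    return float((pred == np.asarray(truth)).mean())


@pytest.fixture(scope="session")
def toy_dataset():
    """Small fixture (200 bp, 8 variants, 4 individuals) with indels,
    suitable for exact oracle comparisons."""
    config = SimulationConfig(
        genome_length=200,
        n_variants=8,
        n_individuals=4,
        coverage=8.0,
        read_length=50,
        indel_fraction=0.3,
        ld_block_length=3,
        seed=2,
    )
    return simulate_all(config)


@pytest.fixture(scope="session")
def midsize_dataset():
    """Mid-size fixture used by several end-to-end tests (20 kb, 100
    variants, 20 individuals, 15x reads)."""
    config = SimulationConfig(
        genome_length=20_000,
        n_variants=100,
        n_individuals=20,
        coverage=15.0,
        seed=3,
    )
    return simulate_all(config)
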