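"""The versioned single-file index archive and its construction.

Indexing is done once per reference population and variant set: graph
construction, candidate-window enumeration, population-frequency scoring,
kmer selection, the kmer-to-node index, the duplicate-count model and the
helper-variant tables. The archive is self-describing (format version and
k recorded) and loadable without the original FASTA/VCF.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .count_model import DEFAULT_EPSILON, CountModel, build_count_model
from .helper_variants import HelperTable, build_helper_table
from .io_formats import BiallelicVariant, GenotypePanel, ReferenceGenome
from .kmer_index import (
    KmerFrequencyModel,
    KmerIndex,
    SelectedKmers,
    build_frequency_model,
    build_kmer_index,
    select_variant_kmers,
)
from .variant_graph import ALT, REF, VariantGraph, build_graph, enumerate_allele_windows

logger = logging.getLogger("kmergt")

ARCHIVE_VERSION = 1
DEFAULT_K = 31  # recommended kmer length; must be odd and <= 31


class ArchiveVersionError(RuntimeError):
    """Raised when loading an archive written by an incompatible version."""


@dataclass
class IndexArchive:
    """Everything needed to genotype samples against one variant set."""

    version: int
    k: int
    graph: VariantGraph
    kmer_index: KmerIndex
    count_model: CountModel
    helper_table: HelperTable
    selections: dict[int, SelectedKmers]
    frequency_model: KmerFrequencyModel
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def variants(self) -> list[BiallelicVariant]:
        return self.graph.variants


def _contig_ranges(variants: list[BiallelicVariant]) -> list[tuple[int, int]]:
    """[start, end) id ranges per contig over the sorted variant list."""
    ranges: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(variants) + 1):
        if i == len(variants) or variants[i].contig != variants[i - 1].contig:
            ranges.append((start, i))
            start = i
    return ranges


def build_index(
    reference: ReferenceGenome,
    variants: list[BiallelicVariant],
    panel: GenotypePanel,
    k: int = DEFAULT_K,
    lambda0: float = 6.0,
    epsilon: float = DEFAULT_EPSILON,
    naive: bool = False,
) -> IndexArchive:
    """Run the full indexing stage and assemble the archive.

    Variants skipped during graph construction (overlaps) are also
    dropped from the panel so all tables stay aligned.
    """
    if not (1 <= k <= 31) or k % 2 == 0:
        raise ValueError(f"k must be odd and in [1, 31], got {k}")
    orig_row = {id(v): i for i, v in enumerate(variants)}
    graph = build_graph(reference, variants)
    keep_rows = [orig_row[id(v)] for v in graph.variants]
    if len(keep_rows) != len(variants):
        panel = GenotypePanel(
            panel.genotypes[keep_rows],
            panel.haplotypes[keep_rows],
            panel.sample_names,
        )
    elif keep_rows != list(range(len(variants))):
        panel = GenotypePanel(
            panel.genotypes[keep_rows],
            panel.haplotypes[keep_rows],
            panel.sample_names,
        )

    freq_model = build_frequency_model(graph, panel, k)
    selections: dict[int, SelectedKmers] = {}
    for v in graph.variants:
        ref_windows = enumerate_allele_windows(graph, v.id, REF, k)
        alt_windows = enumerate_allele_windows(graph, v.id, ALT, k)
        selections[v.id] = select_variant_kmers(ref_windows, alt_windows, freq_model, k)
    kmer_index = build_kmer_index(graph, selections, k)
    count_model = build_count_model(
        graph, panel, freq_model, selections, lambda0, epsilon, naive=naive
    )
    helper_table = build_helper_table(panel, _contig_ranges(graph.variants))

    n_low = sum(s.low_confidence for s in selections.values())
    logger.info(
        "indexed %d variants (%d low-confidence), %d distinct kmers, "
        "mean chosen max-frequency %.2f",
        len(graph.variants),
        n_low,
        len(kmer_index),
        float(np.mean([s.chosen_score for s in selections.values()]))
        if selections
        else 0.0,
    )
    return IndexArchive(
        version=ARCHIVE_VERSION,
        k=k,
        graph=graph,
        kmer_index=kmer_index,
        count_model=count_model,
        helper_table=helper_table,
        selections=selections,
        frequency_model=freq_model,
        contig_lengths={c: len(reference[c]) for c in reference.names()},
    )


def classify_unique_kmers(archive: IndexArchive) -> np.ndarray:
    """Boolean per variant: both alleles have at least one selected kmer
    occurring nowhere else in the graph (every catalogued occurrence of
    the kmer constrains that allele)."""
    occ = archive.frequency_model.occurrences
    out = np.zeros(len(archive.variants), dtype=bool)
    for vid, sel in archive.selections.items():
        unique = True
        for allele in (REF, ALT):
            has_unique = False
            for code in sel.codes(allele):
                occs = occ.get(code, [])
                if occs and all((vid, allele) in a for a in occs):
                    has_unique = True
                    break
            unique &= has_unique
        out[vid] = unique
    return out


def save_archive(archive: IndexArchive, path: str | Path) -> None:
    """Serialize the archive (binary, version-tagged)."""
    with open(path, "wb") as fh:
        pickle.dump({"format_version": archive.version, "archive": archive}, fh)


def load_archive(path: str | Path) -> IndexArchive:
    """Load an archive, checking the format version."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    version = payload.get("format_version")
    if version != ARCHIVE_VERSION:
        raise ArchiveVersionError(
            f"archive format version {version} != supported {ARCHIVE_VERSION}"
        )
    return payload["archive"]
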