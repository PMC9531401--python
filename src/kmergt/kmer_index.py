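"""Kmer scoring, selection and the kmer-to-allele-node lookup index.

Reads are strand-unknown, so every kmer (in the graph and in the reads) is
canonicalized to the numerically smaller of its 2-bit encoding and that of
its reverse complement. Candidate kmers for a variant are scored by their
expected number of copies in a random panel individual's diploid genome
("population frequency"); one window offset per variant is chosen to
minimize the maximum frequency over its ref+alt kmer sets, so that alleles
are represented by the most nearly unique kmers available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenotypePanel
from .variant_graph import (
    ALT,
    REF,
    AlleleWindowSet,
    VariantGraph,
    enumerate_window_occurrences,
    reference_scan_starts,
)

logger = logging.getLogger("kmergt")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _LUT[ord(_b)] = _c
    _LUT[ord(_b.lower())] = _c


def encode_kmer(kmer: str) -> tuple[int, bool] | None:
    """Canonical 2-bit integer code of a kmer.

    Returns ``(code, is_forward)`` where the code is the smaller of the
    encodings of the kmer and its reverse complement, or ``None`` as the
    skip signal when the kmer contains a non-ACGT base. Requires
    ``len(kmer) <= 31`` so the code fits 62 bits.
    """
    fwd = 0
    rev = 0
    for i, ch in enumerate(kmer):
        v = _BASE_CODE.get(ch)
        if v is None:
            return None
        fwd = (fwd << 2) | v
        rev |= (3 - v) << (2 * i)
    return (fwd, True) if fwd <= rev else (rev, False)


def encode_sequence(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes of every k-window of a sequence, vectorized.

    Returns ``(codes, valid)`` arrays of length ``len(seq) - k + 1``;
    ``valid`` is False for windows containing a non-ACGT base (whose code
    is meaningless).
    """
    vals = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n_win = len(seq) - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = (vals == 255).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    v64 = np.where(vals == 255, 0, vals).astype(np.uint64)
    fwd = np.zeros(n_win, dtype=np.uint64)
    rev = np.zeros(n_win, dtype=np.uint64)
    for j in range(k):
        fwd |= v64[j : j + n_win] << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) - v64[j : j + n_win]) << np.uint64(2 * j)
    return np.minimum(fwd, rev), valid


@dataclass
class KmerFrequencyModel:
    """Expected diploid copy number per canonical kmer, with provenance.

    ``frequencies`` maps canonical code to expected copies per panel
    individual's diploid genome; absent kmers have frequency 0.
    ``occurrences`` maps each catalogued code to its physical windows in
    the graph, each as the tuple of (variant id, allele) constraints a
    haplotype must satisfy to carry that window (empty tuple: carried by
    every haplotype). The occurrence lists also drive per-individual
    duplicate-count computation downstream.
    """

    k: int
    n_individuals: int
    frequencies: dict[int, float] = field(default_factory=dict)
    occurrences: dict[int, list[tuple[tuple[int, int], ...]]] = field(
        default_factory=dict
    )

    def lookup(self, code: int) -> float:
        return self.frequencies.get(code, 0.0)

    def lookup_kmer(self, kmer: str) -> float:
        enc = encode_kmer(kmer)
        return 0.0 if enc is None else self.lookup(enc[0])


def _haplotypes_consistent(
    haplotypes: np.ndarray, assignment: tuple[tuple[int, int], ...]
) -> np.ndarray:
    """Boolean mask over haplotype columns satisfying an assignment."""
    mask = np.ones(haplotypes.shape[1], dtype=bool)
    for vid, allele in assignment:
        mask &= haplotypes[vid] == allele
    return mask


def _extended_offsets(graph: VariantGraph, vid: int, allele: int, k: int) -> range:
    """Offsets covering every window that overlaps the allele on its path."""
    v = graph.variants[vid]
    span = len(v.ref_allele if allele == REF else v.alt_allele)
    return range(-(k - 1), max(1, span))


def build_frequency_model(
    graph: VariantGraph, panel: GenotypePanel, k: int
) -> KmerFrequencyModel:
    """Catalog every graph window spelling a candidate kmer and sum its
    expected copies over the panel.

    Candidates are all kmers spelled by windows overlapping any allele.
    Each distinct physical window contributes the mean number of panel
    haplotypes per individual consistent with its local allele
    combination; windows on the plain reference (no variant within k-1
    bases) contribute 2.0 (both chromosomes of everyone).
    """
    n = panel.n_individuals
    haps = panel.haplotypes
    model = KmerFrequencyModel(k=k, n_individuals=n)
    seen_keys: set[tuple] = set()
    occ_by_code = model.occurrences

    # Pass 1: windows overlapping alleles, deduplicated by physical key.
    for v in graph.variants:
        for allele in (REF, ALT):
            occs = enumerate_window_occurrences(
                graph, v.id, allele, k, _extended_offsets(graph, v.id, allele, k)
            )
            for windows in occs.values():
                for key, w in windows.items():
                    if key in seen_keys:
                        continue
                    seen_keys.add(key)
                    enc = encode_kmer(w.kmer)
                    if enc is None:
                        continue
                    occ_by_code.setdefault(enc[0], []).append(w.assignment)

    # Pass 2: plain-reference occurrences of the catalogued codes.
    candidate_codes = set(occ_by_code)
    for contig in graph.reference.names():
        seq = graph.reference[contig]
        if len(seq) < k:
            continue
        codes, valid = encode_sequence(seq, k)
        for p in reference_scan_starts(graph, contig, k):
            if valid[p] and int(codes[p]) in candidate_codes:
                key = (contig, (p, 0), ())
                if key in seen_keys:
                    continue  # already catalogued from a variant anchor
                seen_keys.add(key)
                occ_by_code[int(codes[p])].append(())

    for code, occs in occ_by_code.items():
        freq = 0.0
        for assignment in occs:
            if not assignment:
                freq += 2.0
            else:
                freq += _haplotypes_consistent(haps, assignment).sum() / n
        model.frequencies[code] = freq
    return model


@dataclass
class SelectedKmers:
    """The chosen window offset and kmer sets for one variant."""

    variant_id: int
    offset: int
    ref_kmers: set[str]
    alt_kmers: set[str]
    chosen_score: float
    low_confidence: bool = False

    def codes(self, allele: int) -> list[int]:
        kmers = self.ref_kmers if allele == REF else self.alt_kmers
        out = []
        for kmer in kmers:
            enc = encode_kmer(kmer)
            if enc is not None:
                out.append(enc[0])
        return out


def select_variant_kmers(
    ref_windows: list[AlleleWindowSet],
    alt_windows: list[AlleleWindowSet],
    freq: KmerFrequencyModel,
    k: int,
) -> SelectedKmers:
    """Choose the offset minimizing the maximum population frequency.

    The score of an offset is the max frequency over the union of its ref
    and alt kmer sets. Ties break toward the most window-centred offset
    (nearest -floor((k-1)/2)), then the lower offset. If every offset is
    degenerate, the one with fewest kmers is used and the variant flagged
    low-confidence.
    """
    ref_by_off = {w.offset: w for w in ref_windows}
    alt_by_off = {w.offset: w for w in alt_windows}
    shared = sorted(set(ref_by_off) & set(alt_by_off))
    if not shared:
        raise ValueError("no common in-bounds offset for ref and alt windows")
    vid = ref_windows[0].variant_id
    centre = -((k - 1) // 2)

    def tie_key(off: int) -> tuple[int, int]:
        return (abs(off - centre), off)

    usable = [
        o for o in shared if not (ref_by_off[o].degenerate or alt_by_off[o].degenerate)
    ]
    if usable:
        scored = []
        for o in usable:
            kmers = ref_by_off[o].kmers | alt_by_off[o].kmers
            score = max(freq.lookup_kmer(km) for km in kmers)
            scored.append((score, tie_key(o), o))
        score, _, best = min(scored)
        low_confidence = False
    else:
        best = min(
            shared,
            key=lambda o: (len(ref_by_off[o].kmers) + len(alt_by_off[o].kmers),)
            + tie_key(o),
        )
        kmers = ref_by_off[best].kmers | alt_by_off[best].kmers
        score = max(freq.lookup_kmer(km) for km in kmers)
        low_confidence = True
    return SelectedKmers(
        variant_id=vid,
        offset=best,
        ref_kmers=set(ref_by_off[best].kmers),
        alt_kmers=set(alt_by_off[best].kmers),
        chosen_score=score,
        low_confidence=low_confidence,
    )


@dataclass
class KmerIndex:
    """Lookup from canonical kmer code to the allele nodes it represents."""

    k: int
    lookup_table: dict[int, list[int]] = field(default_factory=dict)

    def lookup(self, code: int) -> list[int]:
        return self.lookup_table.get(code, [])

    def __len__(self) -> int:
        return len(self.lookup_table)


def build_kmer_index(
    graph: VariantGraph, selections: dict[int, SelectedKmers], k: int
) -> KmerIndex:
    """Index every selected kmer to the allele node(s) it was chosen for.

    A kmer selected for several alleles lists all of their nodes (one
    entry per allele it represents); lookups of unselected kmers return
    an empty list.
    """
    index = KmerIndex(k=k)
    for vid, sel in selections.items():
        ref_node, alt_node = graph.variant_nodes[vid]
        for allele, node in ((REF, ref_node), (ALT, alt_node)):
            for code in sel.codes(allele):
                nodes = index.lookup_table.setdefault(code, [])
                if node not in nodes:
                    nodes.append(node)
    return index
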