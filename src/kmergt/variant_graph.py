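"""Acyclic genome graph over reference segments and variant alleles.

The graph has one reference-allele node and one alternative-allele node per
biallelic variant, joined by reference segments. Deletions are represented
by an empty-sequence alt node so that paths skip the deleted bases;
insertions by an empty ref node. Every source-to-sink path spells a
haplotype (the reference with some subset of alt alleles applied).

Besides the node/edge structure, this module provides local path-window
enumeration: all k-length spellings around an allele, one per combination
of neighbouring variant alleles intersecting the window. This underlies
both kmer selection and the population kmer catalog.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator

from .io_formats import BiallelicVariant, ReferenceGenome

logger = logging.getLogger("kmergt")

REF_SEGMENT = 0
REF_ALLELE = 1
ALT_ALLELE = 2

REF = 0
ALT = 1

# At most 2^8 kmers per window set; windows constrained by more than 8
# variants are marked degenerate and excluded from selection.
MAX_WINDOW_VARIANTS = 8
MAX_WINDOW_KMERS = 2 ** MAX_WINDOW_VARIANTS
# Neighbour variants spliced per enumeration region (2^12 combinations
# worst case; regions denser than this are degenerate for selection anyway).
MAX_REGION_VARIANTS = 12

_ACGT = frozenset("ACGT")


class GraphError(ValueError):
    """Raised when variants are inconsistent with the reference."""


@dataclass
class AlleleWindowSet:
    """All k-length path spellings at one offset relative to an allele.

    ``offset`` is in [-(k-1), 0], measured from the first base of the
    allele on its path (the junction position for empty alleles).
    ``kmers`` holds one spelling per combination of neighbouring alleles
    intersecting the window; ``degenerate`` marks offsets whose neighbour
    blow-up exceeds the enumeration cap.
    """

    variant_id: int
    allele: int  # REF or ALT
    offset: int
    kmers: set[str]
    degenerate: bool = False


@dataclass
class WindowOccurrence:
    """One physical k-window on some path through the graph.

    ``key`` identifies the window (contig, path coordinate of its first
    base, and the alleles it is constrained by) so the same window reached
    from two different variant anchors deduplicates. ``assignment`` lists
    the (variant id, allele) pairs a haplotype must carry for the window
    to occur on it; an empty assignment means every haplotype carries it.
    """

    kmer: str
    key: tuple
    assignment: tuple[tuple[int, int], ...]


@dataclass
class VariantGraph:
    """Graph structure plus the coordinate data needed to splice paths."""

    nodes: list[tuple[str, int]]  # (sequence, role)
    edges: list[tuple[int, int]]
    variant_nodes: dict[int, tuple[int, int]]  # variant id -> (ref node, alt node)
    reference_path: dict[str, list[int]]  # contig -> ordered node ids
    reference: ReferenceGenome | None = None
    variants: list[BiallelicVariant] = field(default_factory=list)
    variants_by_contig: dict[str, list[BiallelicVariant]] = field(
        default_factory=dict
    )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def variant(self, vid: int) -> BiallelicVariant:
        return self.variants[vid]

    def reference_spelling(self, contig: str) -> str:
        return "".join(self.nodes[n][0] for n in self.reference_path[contig])

    def n_paths(self, contig: str) -> int:
        """Number of distinct source-to-sink paths (2^v for v variants)."""
        return 2 ** len(self.variants_by_contig.get(contig, []))


def _overlaps(a: BiallelicVariant, b: BiallelicVariant) -> bool:
    """Reference intervals intersect; b is at or after a by sort order.

    Two insertions at the same junction do not overlap (they apply in
    order on the path).
    """
    return a.end > b.position


def build_graph(
    reference: ReferenceGenome, variants: list[BiallelicVariant]
) -> VariantGraph:
    """Build the acyclic graph for sorted biallelic variants.

    A variant whose REF allele disagrees with the reference raises
    :class:`GraphError` naming the variant; a variant overlapping the
    previous kept one is skipped with a warning. Kept variants are
    renumbered to dense ids in (contig, position) order.
    """
    kept: list[BiallelicVariant] = []
    by_contig: dict[str, list[BiallelicVariant]] = {}
    for v in sorted(variants, key=lambda u: (u.contig, u.position, u.end)):
        if v.contig not in reference.contigs:
            raise GraphError(f"variant {v.id}: unknown contig {v.contig!r}")
        seq = reference[v.contig]
        if seq[v.position : v.end] != v.ref_allele:
            raise GraphError(
                f"variant {v.id} at {v.contig}:{v.position}: REF "
                f"{v.ref_allele!r} does not match reference "
                f"{seq[v.position:v.end]!r}"
            )
        prev = by_contig.get(v.contig)
        if prev and _overlaps(prev[-1], v):
            logger.warning(
                "skipping variant at %s:%d overlapping previous variant",
                v.contig,
                v.position,
            )
            continue
        by_contig.setdefault(v.contig, []).append(v)
        kept.append(v)
    for new_id, v in enumerate(kept):
        v.id = new_id

    nodes: list[tuple[str, int]] = []
    edges: list[tuple[int, int]] = []
    variant_nodes: dict[int, tuple[int, int]] = {}
    reference_path: dict[str, list[int]] = {}

    def add_node(seq: str, role: int) -> int:
        nodes.append((seq, role))
        return len(nodes) - 1

    for contig, seq in reference.contigs.items():
        path: list[int] = []
        cursor = 0
        prev_pair: tuple[int, int] | None = None
        for v in by_contig.get(contig, []):
            seg = add_node(seq[cursor : v.position], REF_SEGMENT)
            if prev_pair is not None:
                edges.extend([(prev_pair[0], seg), (prev_pair[1], seg)])
            path.append(seg)
            ref_node = add_node(v.ref_allele, REF_ALLELE)
            alt_node = add_node(v.alt_allele, ALT_ALLELE)
            variant_nodes[v.id] = (ref_node, alt_node)
            edges.extend([(seg, ref_node), (seg, alt_node)])
            path.append(ref_node)
            prev_pair = (ref_node, alt_node)
            cursor = v.end
        tail = add_node(seq[cursor:], REF_SEGMENT)
        if prev_pair is not None:
            edges.extend([(prev_pair[0], tail), (prev_pair[1], tail)])
        path.append(tail)
        reference_path[contig] = path

    return VariantGraph(
        nodes=nodes,
        edges=edges,
        variant_nodes=variant_nodes,
        reference_path=reference_path,
        reference=reference,
        variants=kept,
        variants_by_contig=by_contig,
    )


# ---------------------------------------------------------------------------
# Path splicing and window enumeration
# ---------------------------------------------------------------------------

def _splice_region(
    seq: str,
    region_start: int,
    region_end: int,
    region_variants: list[BiallelicVariant],
    choices: dict[int, int],
) -> tuple[str, list[tuple[int, int]], dict[int, tuple[int, int]]]:
    """Spell the path through a reference region under an allele choice.

    Returns the spliced string, a per-base path coordinate (ref position,
    0) for reference bases or (variant position, 1+i) for inserted/alt
    bases, and each variant's [start, end) span in the spliced string
    (start == end marks the junction of an empty allele).
    """
    out: list[str] = []
    coords: list[tuple[int, int]] = []
    spans: dict[int, tuple[int, int]] = {}
    cursor = region_start
    for v in region_variants:
        for p in range(cursor, v.position):
            out.append(seq[p])
            coords.append((p, 0))
        a = len(out)
        if choices[v.id] == REF:
            for p in range(v.position, v.end):
                out.append(seq[p])
                coords.append((p, 0))
        else:
            for i, ch in enumerate(v.alt_allele):
                out.append(ch)
                coords.append((v.position, 1 + i))
        spans[v.id] = (a, len(out))
        cursor = v.end
    for p in range(cursor, region_end):
        out.append(seq[p])
        coords.append((p, 0))
    return "".join(out), coords, spans


def _constrains(span: tuple[int, int], start: int, k: int) -> bool:
    """Does the window [start, start+k) depend on this variant's allele?"""
    a, b = span
    if a == b:  # empty allele: window must strictly span the junction
        return start < a < start + k
    return start < b and start + k > a


def enumerate_window_occurrences(
    graph: VariantGraph,
    variant_id: int,
    allele: int,
    k: int,
    offsets: range,
) -> dict[int, dict[tuple, WindowOccurrence]]:
    """Enumerate all physical k-windows around an allele at given offsets.

    For every combination of neighbouring variant alleles, the local path
    is spliced and a window extracted at each offset relative to the
    allele start (junction for empty alleles). Windows are deduplicated
    per offset by their physical identity key. Windows containing
    non-ACGT bases are skipped.
    """
    if variant_id not in graph.variant_nodes:
        raise KeyError(f"unknown variant id {variant_id}")
    v = graph.variants[variant_id]
    seq = graph.reference[v.contig]
    pad = 3 * k  # headroom for neighbour deletions shifting the path
    region_start = max(0, v.position - (k - 1) - pad)
    region_end = min(len(seq), v.end + k + pad)

    region = [
        u
        for u in graph.variants_by_contig[v.contig]
        if u.end >= region_start and u.position <= region_end
    ]
    neighbours = [u for u in region if u.id != variant_id]
    if len(neighbours) > MAX_REGION_VARIANTS:
        neighbours.sort(key=lambda u: abs(u.position - v.position))
        neighbours = sorted(
            neighbours[:MAX_REGION_VARIANTS], key=lambda u: u.position
        )
        region = sorted(neighbours + [v], key=lambda u: (u.position, u.end))

    result: dict[int, dict[tuple, WindowOccurrence]] = {o: {} for o in offsets}
    for combo in itertools.product((REF, ALT), repeat=len(neighbours)):
        choices = {u.id: c for u, c in zip(neighbours, combo)}
        choices[variant_id] = allele
        spliced, coords, spans = _splice_region(
            seq, region_start, region_end, region, choices
        )
        anchor = spans[variant_id][0]
        for offset in offsets:
            start = anchor + offset
            if start < 0 or start + k > len(spliced):
                continue  # clipped at a contig end
            kmer = spliced[start : start + k]
            if not _ACGT.issuperset(kmer):
                continue
            assignment = tuple(
                sorted(
                    (u.id, choices[u.id])
                    for u in region
                    if _constrains(spans[u.id], start, k)
                )
            )
            key = (v.contig, coords[start], assignment)
            result[offset].setdefault(
                key, WindowOccurrence(kmer=kmer, key=key, assignment=assignment)
            )
    return result


def enumerate_allele_windows(
    graph: VariantGraph, variant_id: int, allele: int, k: int
) -> list[AlleleWindowSet]:
    """One AlleleWindowSet per in-bounds offset in [-(k-1), 0].

    Offsets whose windows run off the contig are dropped; offsets whose
    enumeration exceeds the neighbour cap are flagged degenerate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    occs = enumerate_window_occurrences(
        graph, variant_id, allele, k, range(-(k - 1), 1)
    )
    sets: list[AlleleWindowSet] = []
    for offset in sorted(occs):
        windows = occs[offset]
        if not windows:
            continue
        kmers = {w.kmer for w in windows.values()}
        degenerate = len(kmers) > MAX_WINDOW_KMERS or any(
            len(w.assignment) > MAX_WINDOW_VARIANTS for w in windows.values()
        )
        sets.append(
            AlleleWindowSet(
                variant_id=variant_id,
                allele=allele,
                offset=offset,
                kmers=kmers,
                degenerate=degenerate,
            )
        )
    return sets


def reference_scan_starts(
    graph: VariantGraph, contig: str, k: int
) -> Iterator[int]:
    """Window start positions on the reference that no variant constrains.

    A window [p, p+k) is excluded when it overlaps a variant's reference
    interval or strictly spans an insertion junction; those windows are
    produced by :func:`enumerate_window_occurrences` instead.
    """
    seq = graph.reference[contig]
    excluded: set[int] = set()
    for u in graph.variants_by_contig.get(contig, []):
        if u.position == u.end:  # insertion: exclude strict-interior spans
            lo, hi = u.position - k + 1, u.position - 1
        else:
            lo, hi = u.position - k + 1, u.end - 1
        excluded.update(range(max(0, lo), min(len(seq) - k, hi) + 1))
    for p in range(0, len(seq) - k + 1):
        if p not in excluded:
            yield p
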