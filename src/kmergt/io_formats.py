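"""Readers and writers for FASTA, FASTQ and VCF.

Converts external files into the internal data model (reference genome,
biallelic variants, genotype panel) and emits genotyped VCF 4.2 with GT,
GL and GQ FORMAT fields. Internal coordinates are 0-based half-open;
conversion to/from VCF's 1-based anchored representation happens here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pysam

logger = logging.getLogger("kmergt")

GL_FLOOR = 1e-10  # posterior floor before log10, keeps GL finite


class FormatError(ValueError):
    """Raised for malformed input files."""


class Genotype(IntEnum):
    """Diploid genotype at a biallelic site; HET is unordered (0/1 == 1/0)."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


@dataclass
class ReferenceGenome:
    """Ordered mapping of contig name to uppercase DNA sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} has an empty sequence")

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def names(self) -> list[str]:
        return list(self.contigs)


@dataclass
class BiallelicVariant:
    """One biallelic SNP or short indel.

    ``position``/``ref_allele``/``alt_allele`` are the trimmed internal
    representation: the shared prefix (and suffix) of the VCF alleles is
    removed so that a deletion or insertion has one empty allele, and
    ``position`` is the 0-based coordinate of the first affected base
    (the junction for insertions). The original anchored VCF fields are
    kept for byte-stable round-tripping.
    """

    id: int
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    population_allele_frequency: float = 0.0
    vcf_pos: int = -1  # 0-based POS of the anchored record
    vcf_ref: str = ""
    vcf_alt: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"variant {self.id}: identical alleles")
        if self.vcf_pos < 0:
            self.vcf_pos, self.vcf_ref, self.vcf_alt = _anchor(
                self.position, self.ref_allele, self.alt_allele
            )

    @property
    def end(self) -> int:
        """End of the affected reference interval (half-open)."""
        return self.position + len(self.ref_allele)

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-trim the shared prefix, then right-trim the shared suffix."""
    while ref and alt and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return pos, ref, alt


def _anchor(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Anchored (VCF-style) form of a trimmed variant.

    Empty alleles get a one-base left anchor; the anchor base itself is
    unknown here and written as the placeholder recovered at output time,
    so synthetic variants should be constructed from anchored input.
    """
    if ref and alt:
        return pos, ref, alt
    # anchor base must be prepended by the caller who knows the reference
    return pos - 1, "?" + ref, "?" + alt


def make_variant(
    vid: int,
    contig: str,
    vcf_pos: int,
    vcf_ref: str,
    vcf_alt: str,
    af: float = 0.0,
) -> BiallelicVariant:
    """Build a variant from an anchored (VCF-style) record."""
    pos, ref, alt = _trim(vcf_pos, vcf_ref, vcf_alt)
    return BiallelicVariant(
        id=vid,
        contig=contig,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        population_allele_frequency=af,
        vcf_pos=vcf_pos,
        vcf_ref=vcf_ref,
        vcf_alt=vcf_alt,
    )


@dataclass
class GenotypePanel:
    """Genotypes (and phased haplotypes) of a reference panel.

    ``genotypes``   : (n_variants, n_individuals) array of Genotype values.
    ``haplotypes``  : (n_variants, 2*n_individuals) array of 0/1 alleles;
                      columns 2t and 2t+1 are individual t's haplotypes.
    Unphased HETs are stored in the order given by the VCF; the model only
    uses haplotypes for kmer copy-number bookkeeping, where the within-
    individual phase is immaterial for non-overlapping variants.
    """

    genotypes: np.ndarray
    haplotypes: np.ndarray
    sample_names: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    def genotype(self, variant_id: int, individual: int) -> Genotype:
        return Genotype(int(self.genotypes[variant_id, individual]))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a (possibly gzipped) FASTA file into a ReferenceGenome.

    Sequences are uppercased and multi-line records joined; duplicate
    contig names or an empty file raise :class:`FormatError`.
    """
    contigs: dict[str, str] = {}
    try:
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                if rec.name in contigs:
                    raise FormatError(f"duplicate contig name {rec.name!r}")
                if not rec.sequence:
                    raise FormatError(f"contig {rec.name!r} has no sequence")
                contigs[rec.name] = rec.sequence.upper()
    except OSError as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not contigs:
        raise FormatError(f"{path}: no FASTA records")
    return ReferenceGenome(contigs)


def read_reads(path: str | Path) -> Iterator[str]:
    """Stream read sequences from FASTA or FASTQ (optionally gzipped).

    Qualities are ignored; reads containing N are passed through (kmer
    windows containing non-ACGT bases are skipped downstream).
    """
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            if rec.sequence is None:
                raise FormatError(f"{path}: truncated record {rec.name!r}")
            yield rec.sequence.upper()


def _gt_to_genotype(gt: tuple) -> tuple[Genotype, int, int]:
    """Map a pysam GT tuple to (genotype, hap_a, hap_b).

    Missing alleles are treated as reference (logged by the caller);
    non-diploid calls are a format error.
    """
    if len(gt) != 2:
        raise FormatError(f"non-diploid genotype {gt}")
    a = 0 if gt[0] is None else int(gt[0])
    b = 0 if gt[1] is None else int(gt[1])
    return Genotype(min(a, 1) + min(b, 1)), min(a, 1), min(b, 1)


def read_panel_vcf(
    path: str | Path,
    min_af: float | None = None,
) -> tuple[list[BiallelicVariant], GenotypePanel]:
    """Read a panel VCF with GT fields for all samples.

    Multi-allelic records are skipped with a warning (the model is
    strictly biallelic). Missing genotypes (./.) count as homozygous
    reference, with the total logged. With ``min_af`` set, only variants
    whose alternative allele frequency is strictly greater are kept; the
    frequency comes from INFO/AF when present, otherwise from the panel
    genotypes themselves.
    """
    variants: list[BiallelicVariant] = []
    gt_rows: list[list[int]] = []
    hap_rows: list[list[int]] = []
    n_missing = 0
    n_multiallelic = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multiallelic += 1
                continue
            gts, haps = [], []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if None in gt:
                    n_missing += 1
                g, ha, hb = _gt_to_genotype(gt)
                gts.append(int(g))
                haps.extend((ha, hb))
            if "AF" in rec.info:
                af_val = rec.info["AF"]
                af = float(af_val[0] if isinstance(af_val, tuple) else af_val)
            else:
                af = sum(h for h in haps) / len(haps) if haps else 0.0
            if min_af is not None and not af > min_af:
                continue
            variants.append(
                make_variant(
                    len(variants), rec.contig, rec.pos - 1, rec.ref, rec.alts[0], af
                )
            )
            gt_rows.append(gts)
            hap_rows.append(haps)
    if n_multiallelic:
        logger.warning("skipped %d multi-allelic records", n_multiallelic)
    if n_missing:
        logger.warning("treated %d missing genotypes as 0/0", n_missing)
    order = sorted(range(len(variants)), key=lambda i: (variants[i].contig, variants[i].position))
    variants = [variants[i] for i in order]
    for new_id, v in enumerate(variants):
        v.id = new_id
    genotypes = np.array([gt_rows[i] for i in order], dtype=np.uint8).reshape(
        len(variants), len(samples)
    )
    haplotypes = np.array([hap_rows[i] for i in order], dtype=np.uint8).reshape(
        len(variants), 2 * len(samples)
    )
    return variants, GenotypePanel(genotypes, haplotypes, samples)


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

def _vcf_header(
    variants: Sequence[BiallelicVariant],
    reference: ReferenceGenome | None,
    sample: str,
    contig_lengths: dict[str, int] | None = None,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##source=kmergt')
    contigs: list[str] = []
    for v in variants:
        if v.contig not in contigs:
            contigs.append(v.contig)
    for c in contigs:
        if reference is not None and c in reference.contigs:
            header.add_line(f"##contig=<ID={c},length={len(reference[c])}>")
        elif contig_lengths and c in contig_lengths:
            header.add_line(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            header.add_line(f"##contig=<ID={c}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=GL,Number=G,Type=Float,'
        'Description="Log10 genotype likelihoods for 0/0, 0/1, 1/1">'
    )
    header.add_line(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
    )
    header.add_sample(sample)
    return header


_GT_STRINGS = {Genotype.HOM_REF: (0, 0), Genotype.HET: (0, 1), Genotype.HOM_ALT: (1, 1)}


def write_genotyped_vcf(
    variants: Sequence[BiallelicVariant],
    calls: Sequence,
    path: str | Path,
    mode: str = "full",
    reference: ReferenceGenome | None = None,
    sample: str = "SAMPLE",
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write one genotyped VCF 4.2 record per variant.

    FORMAT carries GT, GL (log10 of the normalized 3-vector, ordered
    0/0, 0/1, 1/1) and GQ. In ``mode="likelihoods-only"`` the GL values
    are the kmer-only posteriors (no helper prior); in full mode they
    are the helper-adjusted posteriors. ``calls`` must parallel
    ``variants``.
    """
    if len(variants) != len(calls):
        raise ValueError(
            f"{len(calls)} calls for {len(variants)} variants"
        )
    header = _vcf_header(variants, reference, sample, contig_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v, call in zip(variants, calls):
            vec = (
                call.kmer_only_likelihoods
                if mode == "likelihoods-only"
                else call.posterior
            )
            gl = [math.log10(max(float(p), GL_FLOOR)) for p in vec]
            rec = out.new_record(
                contig=v.contig,
                start=v.vcf_pos,
                alleles=(v.vcf_ref, v.vcf_alt),
            )
            rec.samples[sample]["GT"] = _GT_STRINGS[Genotype(call.genotype)]
            rec.samples[sample].phased = False
            rec.samples[sample]["GL"] = gl
            rec.samples[sample]["GQ"] = int(call.quality)
            out.write(rec)
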