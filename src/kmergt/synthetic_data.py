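"""Self-contained synthetic fixtures: reference, panel, sample, reads.

The generator emulates the three inputs the genotyper consumes, with the
two structural features the method exploits built in and tunable:

* segmental duplications in the reference (optionally degraded to a given
  identity), which create shared kmers and hence variants that cannot be
  represented uniquely;
* linkage between nearby variants, produced by a mosaic-founder model:
  every haplotype is a block-wise copy of a small founder set, so genotype
  correlation decays with variant rank distance at a rate set by the block
  length. This gives tunable LD with exact truth, without the machinery of
  a coalescent simulation.

A diploid sample is drawn by the same mosaic process over the panel
haplotypes (in-panel LD, novel combination), and single-end reads are
drawn uniformly from both sample haplotypes with independent per-base
substitution, insertion and deletion errors (defaults 0.001 each). All
outputs are a deterministic function of the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .io_formats import BiallelicVariant, GenotypePanel, ReferenceGenome, make_variant

logger = logging.getLogger("kmergt")

_BASES = np.array(list("ACGT"))

# rng stream tags, one per stage, so stages are independently reproducible
_STAGE_REFERENCE = 1
_STAGE_PANEL = 2
_STAGE_SAMPLE = 3
_STAGE_READS = 4


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output."""

    genome_length: int = 100_000
    n_variants: int = 500
    n_individuals: int = 50
    coverage: float = 15.0
    read_length: int = 150
    substitution_rate: float = 0.001
    insertion_rate: float = 0.001
    deletion_rate: float = 0.001
    # (source_start, source_end, target_pos, identity): copy the source
    # interval over the bases at target_pos with per-base degradation
    duplications: list[tuple[int, int, int, float]] = field(default_factory=list)
    indel_fraction: float = 0.1
    ld_block_length: int = 20
    n_founders: int = 4
    min_allele_frequency: float = 0.1
    max_allele_frequency: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {r}")
        if self.genome_length < self.read_length:
            raise ConfigError("genome shorter than the read length")
        for src_start, src_end, target, identity in self.duplications:
            if not (0 <= src_start < src_end <= self.genome_length):
                raise ConfigError("duplication source outside the genome")
            t_end = target + (src_end - src_start)
            if t_end > self.genome_length or target < 0:
                raise ConfigError("duplication target outside the genome")
            if target < src_end and t_end > src_start:
                raise ConfigError("duplication target overlaps its source")
            if not 0.0 <= identity <= 1.0:
                raise ConfigError("duplication identity must be in [0, 1]")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_reference(config: SimulationConfig) -> ReferenceGenome:
    """Uniform random genome with optional planted duplications."""
    rng = _rng(config, _STAGE_REFERENCE)
    seq = rng.choice(_BASES, size=config.genome_length)
    for src_start, src_end, target, identity in config.duplications:
        copy = seq[src_start:src_end].copy()
        if identity < 1.0:
            mutate = rng.random(copy.shape[0]) < (1.0 - identity)
            shift = rng.integers(1, 4, size=int(mutate.sum()))
            idx = np.searchsorted(_BASES, copy[mutate])
            copy[mutate] = _BASES[(idx + shift) % 4]
        seq[target : target + (src_end - src_start)] = copy
    return ReferenceGenome({"chr1": "".join(seq)})


def _draw_positions(
    rng: np.random.Generator, config: SimulationConfig
) -> np.ndarray:
    """Variant anchor positions, spaced so reference intervals (up to a
    5 bp indel plus its anchor base) never overlap."""
    spacing = 7
    candidates = rng.permutation(
        np.arange(1, config.genome_length - config.read_length)
    )
    chosen: list[int] = []
    taken = np.zeros(config.genome_length, dtype=bool)
    for p in candidates:
        if len(chosen) == config.n_variants:
            break
        lo, hi = max(0, p - spacing), min(config.genome_length, p + spacing)
        if not taken[lo:hi].any():
            chosen.append(int(p))
            taken[p] = True
    if len(chosen) < config.n_variants:
        raise ConfigError("cannot place variants without overlap")
    return np.sort(np.array(chosen))


def simulate_panel(
    config: SimulationConfig, reference: ReferenceGenome
) -> tuple[list[BiallelicVariant], GenotypePanel]:
    """Variant sites plus a phased panel with block-mosaic LD.

    Each haplotype is a block-wise copy of ``n_founders`` founder
    haplotypes; blocks span ``ld_block_length`` consecutive variants.
    Founders carry the alt allele with a per-variant probability drawn
    uniformly from [min_allele_frequency, max_allele_frequency], so panel
    allele frequencies track the founder mixture.
    """
    rng = _rng(config, _STAGE_PANEL)
    seq = reference["chr1"]
    positions = _draw_positions(rng, config)
    m = config.n_variants

    variants: list[BiallelicVariant] = []
    for vid, p in enumerate(positions):
        ref_base = seq[p]
        if rng.random() < config.indel_fraction:
            length = int(rng.integers(1, 6))
            if rng.random() < 0.5 and p + 1 + length <= len(seq):  # deletion
                vcf_ref = seq[p : p + 1 + length]
                vcf_alt = ref_base
            else:  # insertion
                vcf_ref = ref_base
                vcf_alt = ref_base + "".join(rng.choice(_BASES, size=length))
        else:
            alt_base = _BASES[
                (np.searchsorted(_BASES, ref_base) + rng.integers(1, 4)) % 4
            ]
            vcf_ref, vcf_alt = ref_base, str(alt_base)
        variants.append(make_variant(vid, "chr1", int(p), vcf_ref, vcf_alt))

    target_af = rng.uniform(
        config.min_allele_frequency, config.max_allele_frequency, size=m
    )
    founders = (
        rng.random((m, config.n_founders)) < target_af[:, None]
    ).astype(np.uint8)

    haplotypes = _mosaic(rng, founders, 2 * config.n_individuals, config.ld_block_length)
    genotypes = (haplotypes[:, 0::2] + haplotypes[:, 1::2]).astype(np.uint8)
    for v in variants:
        v.population_allele_frequency = float(haplotypes[v.id].mean())
    return variants, GenotypePanel(
        genotypes,
        haplotypes,
        [f"panel{t}" for t in range(config.n_individuals)],
    )


def _mosaic(
    rng: np.random.Generator,
    sources: np.ndarray,
    n_haplotypes: int,
    block_length: int,
) -> np.ndarray:
    """Haplotypes copied block-wise from source haplotype columns."""
    m, n_sources = sources.shape
    n_blocks = (m + block_length - 1) // block_length
    out = np.empty((m, n_haplotypes), dtype=np.uint8)
    for h in range(n_haplotypes):
        picks = rng.integers(0, n_sources, size=n_blocks)
        for b, src in enumerate(picks):
            lo, hi = b * block_length, min(m, (b + 1) * block_length)
            out[lo:hi, h] = sources[lo:hi, src]
    return out


def apply_haplotype(
    reference: ReferenceGenome,
    variants: list[BiallelicVariant],
    alleles: np.ndarray,
    contig: str = "chr1",
) -> str:
    """Reference with the alt alleles of one haplotype applied."""
    seq = reference[contig]
    out: list[str] = []
    cursor = 0
    for v in variants:
        if v.contig != contig:
            continue
        out.append(seq[cursor : v.position])
        out.append(v.alt_allele if alleles[v.id] else v.ref_allele)
        cursor = v.end
    out.append(seq[cursor:])
    return "".join(out)


def simulate_sample(
    panel: GenotypePanel,
    config: SimulationConfig,
    reference: ReferenceGenome,
    variants: list[BiallelicVariant],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Diploid sample drawn from the panel by the same mosaic process.

    Returns (true genotypes, the two haplotype allele vectors stacked as
    an (m, 2) array, and the two spelled-out haplotype genome strings).
    """
    rng = _rng(config, _STAGE_SAMPLE)
    haps = _mosaic(rng, panel.haplotypes, 2, config.ld_block_length)
    truth = (haps[:, 0] + haps[:, 1]).astype(np.uint8)
    genomes = [
        apply_haplotype(reference, variants, haps[:, 0]),
        apply_haplotype(reference, variants, haps[:, 1]),
    ]
    return truth, haps, genomes


def simulate_reads(
    genomes: list[str], config: SimulationConfig
) -> list[str]:
    """Single-end reads with per-base substitution/insertion/deletion
    errors, drawn uniformly from both haplotype genome strings. Expected
    total bases = coverage * genome_length."""
    if config.coverage <= 0:
        raise ConfigError("coverage must be positive")
    if any(config.read_length > len(g) for g in genomes):
        raise ConfigError("read length exceeds a haplotype genome length")
    rng = _rng(config, _STAGE_READS)
    n_reads = round(config.coverage * config.genome_length / config.read_length)
    pad = 16  # extra template for deletions
    sub, ins, dele = (
        config.substitution_rate,
        config.insertion_rate,
        config.deletion_rate,
    )
    reads: list[str] = []
    for _ in range(n_reads):
        g = genomes[int(rng.integers(0, len(genomes)))]
        start = int(rng.integers(0, len(g) - config.read_length + 1))
        template = g[start : start + config.read_length + pad]
        if sub == 0.0 and ins == 0.0 and dele == 0.0:
            reads.append(template[: config.read_length])
            continue
        u = rng.random(4 * len(template))  # two draws max per loop turn
        out: list[str] = []
        i = 0
        j = 0
        while len(out) < config.read_length and i < len(template):
            r = u[j % len(u)]
            j += 1
            if r < dele:
                i += 1
            elif r < dele + ins:
                out.append(str(rng.choice(_BASES)))
            else:
                base = template[i]
                if u[j % len(u)] < sub:
                    base = str(
                        _BASES[
                            (np.searchsorted(_BASES, base) + rng.integers(1, 4)) % 4
                        ]
                    )
                j += 1
                out.append(base)
                i += 1
        reads.append("".join(out))
    return reads


@dataclass
class SimulatedDataset:
    """One complete fixture with the truth needed to score calls."""

    config: SimulationConfig
    reference: ReferenceGenome
    variants: list[BiallelicVariant]
    panel: GenotypePanel
    truth: np.ndarray  # per-variant true genotype of the sample
    sample_haplotypes: np.ndarray  # (m, 2) allele vectors
    sample_genomes: list[str]
    reads: list[str]


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run every stage and bundle the results."""
    reference = simulate_reference(config)
    variants, panel = simulate_panel(config, reference)
    truth, haps, genomes = simulate_sample(panel, config, reference, variants)
    reads = simulate_reads(genomes, config)
    return SimulatedDataset(
        config=config,
        reference=reference,
        variants=variants,
        panel=panel,
        truth=truth,
        sample_haplotypes=haps,
        sample_genomes=genomes,
        reads=reads,
    )


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------

def write_fasta(reference: ReferenceGenome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def _panel_header(
    reference: ReferenceGenome, samples: list[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, seq in reference.contigs.items():
        header.add_line(f"##contig=<ID={name},length={len(seq)}>")
    header.add_line(
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    return header


def write_panel_vcf(
    reference: ReferenceGenome,
    variants: list[BiallelicVariant],
    panel: GenotypePanel,
    path: str | Path,
) -> None:
    """Panel VCF with phased GT columns and INFO/AF."""
    header = _panel_header(reference, panel.sample_names)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.contig, start=v.vcf_pos, alleles=(v.vcf_ref, v.vcf_alt)
            )
            rec.info["AF"] = v.population_allele_frequency
            for t, s in enumerate(panel.sample_names):
                rec.samples[s]["GT"] = (
                    int(panel.haplotypes[v.id, 2 * t]),
                    int(panel.haplotypes[v.id, 2 * t + 1]),
                )
                rec.samples[s].phased = True
            out.write(rec)


def write_truth_vcf(
    reference: ReferenceGenome,
    variants: list[BiallelicVariant],
    truth: np.ndarray,
    path: str | Path,
) -> None:
    """Single-sample VCF with the sample's true genotypes."""
    header = _panel_header(reference, ["TRUTH"])
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.contig, start=v.vcf_pos, alleles=(v.vcf_ref, v.vcf_alt)
            )
            rec.info["AF"] = v.population_allele_frequency
            rec.samples["TRUTH"]["GT"] = gt_map[int(truth[v.id])]
            out.write(rec)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four fixture files plus a truth VCF and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "panel": outdir / "panel.vcf",
        "reads": outdir / "reads.fq",
        "truth": outdir / "truth.vcf",
        "config": outdir / "config.json",
    }
    write_fasta(dataset.reference, paths["reference"])
    write_panel_vcf(dataset.reference, dataset.variants, dataset.panel, paths["panel"])
    write_fastq(dataset.reads, paths["reads"])
    write_truth_vcf(dataset.reference, dataset.variants, dataset.truth, paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(dataset.config), fh, indent=2)
    return paths
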