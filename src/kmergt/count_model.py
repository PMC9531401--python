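"""Population count model: Poisson mixtures over panel duplicate counts.

For every (variant, allele, genotype) the model stores a histogram over the
panel: how many individuals with that genotype carry the allele's selected
kmers d = 0, 1, 2, ... times in their diploid genome (own-site copies plus
copies at duplicate sites elsewhere in the graph). The likelihood of an
observed read-kmer count K given a genotype is then the mixture

    P(K | G) = sum_d  c[d]/sum(c) * Pois(K; lambda0 * (d + eps))

with one Poisson component per duplicate-count class: lambda0 is the
expected read-kmer count contributed by a single genome copy of a kmer and
eps an error-term rate giving non-zero likelihood to counts arising purely
from sequencing errors. This is what lets a duplicated alt kmer that is
*expected* once in a homozygous-reference individual be explained without
calling a spurious variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GenotypePanel
from .kmer_index import KmerFrequencyModel, SelectedKmers
from .variant_graph import ALT, REF, VariantGraph

logger = logging.getLogger("kmergt")

DEFAULT_EPSILON = 0.01
D_MAX = 15  # overflow bin: duplicate counts beyond this clamp to D_MAX

# Idealized per-genotype allele doses: dose[allele][genotype] = copies of
# that allele implied by the genotype alone (ignoring duplicates).
_IDEAL_DOSE = {REF: (2, 1, 0), ALT: (0, 1, 2)}

# Haplotype allele pairs at the variant itself for each genotype.
_GENOTYPE_HAPS = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


@dataclass
class CountModel:
    """Per-(variant, allele, genotype) duplicate-count histograms.

    ``histograms`` has shape (n_variants, 2, 3, D_MAX + 1); entry
    [i, a, g, d] is the number of panel individuals with genotype g at
    variant i whose diploid genome carries allele a's selected kmers d
    times. Every (i, a, g) slice sums to the genotype's panel count (or 1
    for the pseudo-individual filling an empty class).
    """

    lambda0: float
    epsilon: float
    histograms: np.ndarray
    naive: bool = False

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    @property
    def n_variants(self) -> int:
        return self.histograms.shape[0]

    def histogram(self, variant_id: int, allele: int, genotype: int) -> np.ndarray:
        return self.histograms[variant_id, allele, genotype]


def estimate_lambda0(coverage: float, read_length: int, k: int) -> float:
    """Expected read-kmer count of a single-copy (per haploid) kmer.

    A kmer present once per haploid genome is covered by coverage/2 reads
    on average, and a read of length L contains L - k + 1 of its k
    windows, so lambda0 = (C/2) * (L - k + 1) / L.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_length < k:
        raise ValueError(f"read length {read_length} shorter than k={k}")
    return (coverage / 2.0) * (read_length - k + 1) / read_length


def _occurrence_hits(
    freq_model: KmerFrequencyModel,
    codes: list[int],
    haplotypes: np.ndarray,
) -> np.ndarray:
    """Per-haplotype occurrence counts of a kmer set, via the catalog.

    Returns an int array over haplotype columns: how many catalogued
    physical windows spelling any of ``codes`` the haplotype carries.
    """
    hits = np.zeros(haplotypes.shape[1], dtype=np.int64)
    for code in codes:
        for assignment in freq_model.occurrences.get(code, []):
            mask = np.ones(haplotypes.shape[1], dtype=bool)
            for vid, allele in assignment:
                mask &= haplotypes[vid] == allele
            hits += mask
    return hits


def _virtual_duplicate_count(
    freq_model: KmerFrequencyModel,
    codes: list[int],
    variant_id: int,
    genotype: int,
) -> int:
    """Idealized d for a hypothetical individual: the given genotype at the
    variant, homozygous reference everywhere else."""
    d = 0
    for hap_allele in _GENOTYPE_HAPS[genotype]:
        for code in codes:
            for assignment in freq_model.occurrences.get(code, []):
                if all(
                    (hap_allele if vid == variant_id else 0) == allele
                    for vid, allele in assignment
                ):
                    d += 1
    return d


def individual_duplicate_count(
    graph: VariantGraph,
    panel: GenotypePanel,
    freq_model: KmerFrequencyModel,
    selection: SelectedKmers,
    allele: int,
    individual: int,
) -> int:
    """Total occurrences of an allele's selected kmers in one panel
    individual's diploid genome (graph-walk over the occurrence catalog,
    using the individual's actual alleles at every site sharing a kmer)."""
    codes = selection.codes(allele)
    haps = panel.haplotypes[:, [2 * individual, 2 * individual + 1]]
    return int(_occurrence_hits(freq_model, codes, haps).sum())


def build_count_model(
    graph: VariantGraph,
    panel: GenotypePanel,
    freq_model: KmerFrequencyModel,
    selections: dict[int, SelectedKmers],
    lambda0: float,
    epsilon: float = DEFAULT_EPSILON,
    naive: bool = False,
) -> CountModel:
    """Tally duplicate-count histograms over the panel for every variant.

    With ``naive=True`` the duplicate counts are forced to the idealized
    per-genotype allele doses (0/1/2), reproducing a genotyper that
    assumes every kmer is unique in the genome — the ablation baseline
    for the duplicate-kmer modelling.

    Genotype classes with no panel individual are filled with a single
    pseudo-individual at the genotype's idealized d, so every mixture is
    well defined.
    """
    n_variants = len(graph.variants)
    n = panel.n_individuals
    hist = np.zeros((n_variants, 2, 3, D_MAX + 1), dtype=np.uint32)
    genotypes = panel.genotypes
    for v in graph.variants:
        sel = selections[v.id]
        g_row = genotypes[v.id]
        for allele in (REF, ALT):
            codes = sel.codes(allele)
            if naive:
                # each haplotype spells exactly one window at the site, so
                # the idealized d is the allele dose regardless of how many
                # combination kmers the set holds
                dose = _IDEAL_DOSE[allele]
                d_per_ind = np.array([dose[g] for g in g_row], dtype=np.int64)
            else:
                hits = _occurrence_hits(freq_model, codes, panel.haplotypes)
                d_per_ind = hits.reshape(n, 2).sum(axis=1)
            d_per_ind = np.minimum(d_per_ind, D_MAX)
            for g in range(3):
                sel_mask = g_row == g
                if sel_mask.any():
                    hist[v.id, allele, g] = np.bincount(
                        d_per_ind[sel_mask], minlength=D_MAX + 1
                    )
                else:
                    if naive:
                        d_pseudo = _IDEAL_DOSE[allele][g]
                    else:
                        d_pseudo = _virtual_duplicate_count(
                            freq_model, codes, v.id, g
                        )
                    hist[v.id, allele, g, min(d_pseudo, D_MAX)] = 1
    return CountModel(
        lambda0=lambda0, epsilon=epsilon, histograms=hist, naive=naive
    )


def allele_likelihood(
    k_obs: int, histogram: np.ndarray, lambda0: float, epsilon: float
) -> float:
    """Mixture-of-Poissons probability of an observed allele kmer count.

    P(K) = sum_d c[d]/sum(c) * Pois(K; lambda0*(d+eps)); a rate of zero
    is the point mass at K=0.
    """
    if k_obs < 0:
        raise ValueError("observed count must be non-negative")
    total = histogram.sum()
    if total < 1:
        raise ValueError("empty histogram: no mixture components")
    weights = histogram / total
    rates = lambda0 * (np.arange(histogram.shape[0]) + epsilon)
    return float(np.dot(weights, stats.poisson.pmf(k_obs, rates)))


def log_allele_likelihood(
    k_obs: int, histogram: np.ndarray, lambda0: float, epsilon: float
) -> float:
    """log P(K) computed stably in log space (Poisson tails underflow at
    high coverage)."""
    if k_obs < 0:
        raise ValueError("observed count must be non-negative")
    total = histogram.sum()
    if total < 1:
        raise ValueError("empty histogram: no mixture components")
    d_vals = np.flatnonzero(histogram)
    rates = lambda0 * (d_vals + epsilon)
    with np.errstate(divide="ignore"):
        log_w = np.log(histogram[d_vals] / total)
        log_p = stats.poisson.logpmf(k_obs, rates)
    from scipy.special import logsumexp

    return float(logsumexp(log_w + log_p))
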