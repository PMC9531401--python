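"""Posterior genotype probabilities and calls.

A variant's kmer evidence enters as the pair of observed allele counts
K = (K_ref, K_alt); the likelihood of a genotype is the product of the two
allele mixtures (the counts are conditionally independent given the
genotype). The helper variant supplies the prior: for variant i with
helper h,

    P(G_i | K_i, K_h)  ∝  P(K_i|G_i) * sum_{G_h} P(G_h) P(G_i|G_h) P(K_h|G_h)

computed over the 9 genotype combinations and marginalized over G_h. In
likelihoods-only mode the helper term is replaced by the population
marginal P(G_i), yielding output suitable for downstream imputation tools.
Likelihoods are accumulated in log space and normalized by max-subtraction
so high-coverage Poisson tails cannot underflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .count_model import CountModel, log_allele_likelihood
from .helper_variants import HelperTable
from .io_formats import Genotype
from .kmer_counting import NodeCounts, count_reads, variant_counts
from .variant_graph import ALT, REF

logger = logging.getLogger("kmergt")

MAX_QUALITY = 99


@dataclass
class GenotypeCall:
    """One called genotype with its posterior and pre-prior likelihoods."""

    variant_id: int
    genotype: Genotype
    posterior: np.ndarray  # 3-vector, sums to 1
    kmer_only_likelihoods: np.ndarray  # normalized P(K_i|G_i), no prior
    quality: int  # phred-scaled confidence, capped at 99


def genotype_likelihood(
    k_ref: int, k_alt: int, model: CountModel, variant_id: int
) -> np.ndarray:
    """log P(K_i | G_i = g) for g in (0/0, 0/1, 1/1).

    The two allele counts are conditionally independent given the
    genotype, so the log-likelihood is the sum of the two allele
    mixtures' log-probabilities.
    """
    out = np.empty(3)
    for g in range(3):
        out[g] = log_allele_likelihood(
            k_ref, model.histogram(variant_id, REF, g), model.lambda0, model.epsilon
        ) + log_allele_likelihood(
            k_alt, model.histogram(variant_id, ALT, g), model.lambda0, model.epsilon
        )
    return out


def _normalize_log(log_vec: np.ndarray) -> np.ndarray:
    """Linear probabilities from an unnormalized log vector."""
    m = np.max(log_vec)
    if not np.isfinite(m):
        return np.full(3, 1 / 3)
    p = np.exp(log_vec - m)
    return p / p.sum()


def posterior_with_helper(
    lik_i: np.ndarray,
    lik_h: np.ndarray,
    prior_h: np.ndarray,
    transition: np.ndarray,
    prior_i: np.ndarray | None = None,
) -> np.ndarray:
    """Helper-adjusted posterior over G_i.

    ``lik_i`` and ``lik_h`` are linear likelihood 3-vectors (any positive
    scaling); ``transition[a, b]`` is P(G_i = a | G_h = b) and ``prior_h``
    is P(G_h). The sum over G_h of P(G_h) P(G_i|G_h) P(K_h|G_h) is the
    prior term of the 9-combination computation, already marginalized. If
    the unnormalized posterior vanishes, the population prior ``prior_i``
    is returned with a warning.
    """
    prior_term = transition @ (prior_h * lik_h)
    unnorm = lik_i * prior_term
    total = unnorm.sum()
    if total <= 0 or not np.isfinite(total):
        logger.warning("vanishing posterior; falling back to population prior")
        if prior_i is not None:
            return prior_i / prior_i.sum()
        return np.full(3, 1 / 3)
    return unnorm / total


def call(posterior: np.ndarray, variant_id: int = -1,
         kmer_only: np.ndarray | None = None) -> GenotypeCall:
    """Most likely genotype with phred-scaled quality.

    Ties break in the order 0/0 > 0/1 > 1/1; quality is
    round(-10 log10(1 - max posterior)), capped at 99.
    """
    g = Genotype(int(np.argmax(posterior)))
    p_max = float(posterior[g])
    if p_max >= 1.0:
        quality = MAX_QUALITY
    else:
        quality = min(MAX_QUALITY, round(-10.0 * math.log10(1.0 - p_max)))
    return GenotypeCall(
        variant_id=variant_id,
        genotype=g,
        posterior=np.asarray(posterior, dtype=float),
        kmer_only_likelihoods=(
            kmer_only if kmer_only is not None else np.asarray(posterior, dtype=float)
        ),
        quality=quality,
    )


def genotype_from_counts(
    node_counts: NodeCounts,
    graph,
    model: CountModel,
    helpers: HelperTable,
    mode: str = "full",
) -> list[GenotypeCall]:
    """Call every variant from accumulated node counts.

    ``mode="full"`` applies the helper prior; ``mode="likelihoods-only"``
    uses only the population marginal P(G_i). Helper-less variants fall
    back to the marginal in either mode.
    """
    if mode not in ("full", "likelihoods-only"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(graph.variants)
    log_lik = np.empty((n, 3))
    for v in graph.variants:
        k_ref, k_alt = variant_counts(node_counts, graph, v.id)
        log_lik[v.id] = genotype_likelihood(k_ref, k_alt, model, v.id)

    calls: list[GenotypeCall] = []
    for i in range(n):
        lik_i = _normalize_log(log_lik[i])
        h = int(helpers.helper_id[i])
        if mode == "full" and h >= 0:
            lik_h = _normalize_log(log_lik[h])
            post = posterior_with_helper(
                lik_i,
                lik_h,
                helpers.prior_h[i],
                helpers.transition[i],
                prior_i=helpers.prior_self[i],
            )
        else:
            unnorm = lik_i * helpers.prior_self[i]
            total = unnorm.sum()
            post = unnorm / total if total > 0 else helpers.prior_self[i].copy()
        calls.append(call(post, variant_id=i, kmer_only=lik_i))
    return calls


def genotype_sample(archive, reads, mode: str = "full") -> list[GenotypeCall]:
    """Full per-sample pipeline: count kmers in the read stream, then call
    every variant in the archive."""
    node_counts = count_reads(reads, archive.kmer_index)
    return genotype_from_counts(
        node_counts, archive.graph, archive.count_model, archive.helper_table, mode
    )
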