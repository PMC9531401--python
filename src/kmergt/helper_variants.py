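"""Helper-variant selection and panel-derived genotype priors.

Every variant gets one precomputed "helper": the neighbouring variant whose
genotypes co-occur most consistently with its own across the panel,
measured by sum_G log pi(G, G) over the smoothed 3x3 joint genotype
frequency table pi. At genotyping time the helper's kmer evidence adjusts
the variant's prior through P(G_h) and P(G_i | G_h), which is a one-lookup
stand-in for imputation that scales to panels of thousands of haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenotypePanel

logger = logging.getLogger("kmergt")

WINDOW_SIDE = 100  # candidate helpers per side by sorted rank


@dataclass
class HelperTable:
    """Per-variant helper ids and prior tables.

    ``helper_id[i]`` is -1 for helper-less variants (single variant on
    its contig). ``pi[i]`` is the smoothed joint table with rows indexed
    by G_i and columns by G_h; ``prior_h[i]`` its column marginal P(G_h);
    ``transition[i]`` the column-normalized P(G_i | G_h). ``prior_self``
    is the smoothed marginal P(G_i), used for helper-less variants and
    for the likelihoods-only output mode.
    """

    helper_id: np.ndarray  # (n_variants,) int
    pi: np.ndarray  # (n_variants, 3, 3)
    prior_h: np.ndarray  # (n_variants, 3)
    transition: np.ndarray  # (n_variants, 3, 3)
    prior_self: np.ndarray  # (n_variants, 3)
    low_confidence: np.ndarray = field(default=None)

    @property
    def n_variants(self) -> int:
        return self.helper_id.shape[0]


def genotype_cooccurrence(
    panel: GenotypePanel, i: int, v: int, smoothing: float | None = None
) -> np.ndarray:
    """Smoothed 3x3 joint genotype frequency table for variants (i, v).

    pi[a, b] = (#individuals with g_i = a and g_v = b + s) / (n + 9 s);
    the default pseudo-count is s = 1/n so log pi(G, G) is always finite.
    """
    if i == v:
        raise ValueError("a variant cannot be paired with itself")
    n = panel.n_individuals
    s = (1.0 / n) if smoothing is None else smoothing
    joint = np.bincount(
        3 * panel.genotypes[i].astype(np.int64) + panel.genotypes[v],
        minlength=9,
    ).reshape(3, 3)
    return (joint + s) / (n + 9 * s)


def helper_score(pi: np.ndarray) -> float:
    """sum_G log pi(G, G): high when individuals tend to carry the same
    genotype at both variants. Natural log; -inf for a zero diagonal
    entry (valid ordering value when smoothing is disabled)."""
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(np.diagonal(pi))))


def _window(i: int, lo: int, hi: int) -> range:
    """Candidate ranks around i: up to WINDOW_SIDE each side within
    [lo, hi), clipped at contig ends."""
    return range(max(lo, i - WINDOW_SIDE), min(hi, i + WINDOW_SIDE + 1))


def select_helper(
    panel: GenotypePanel,
    i: int,
    contig_range: tuple[int, int] | None = None,
    smoothing: float | None = None,
) -> int:
    """Best-scoring helper for variant i among its neighbouring variants.

    Candidates are the up-to-200 nearest variants by sorted rank (100
    each side, same contig, clipped at ends). Ties break by smaller rank
    distance, then lower id. Returns -1 when no candidate exists.
    """
    lo, hi = contig_range if contig_range is not None else (0, panel.n_variants)
    best_id = -1
    best = None
    for v in _window(i, lo, hi):
        if v == i:
            continue
        score = helper_score(genotype_cooccurrence(panel, i, v, smoothing))
        cand = (-score, abs(v - i), v)
        if best is None or cand < best:
            best = cand
            best_id = v
    return best_id


def build_helper_table(
    panel: GenotypePanel,
    contig_ranges: list[tuple[int, int]] | None = None,
    smoothing: float | None = None,
) -> HelperTable:
    """Select a helper and precompute prior tables for every variant.

    ``contig_ranges`` lists [start, end) id ranges per contig so the rank
    window never crosses a contig boundary; by default all variants are
    treated as one contig. The same smoothed pi drives both the selection
    metric and the genotyping prior.
    """
    m = panel.n_variants
    n = panel.n_individuals
    s = (1.0 / n) if smoothing is None else smoothing
    if contig_ranges is None:
        contig_ranges = [(0, m)]
    helper_id = np.full(m, -1, dtype=np.int64)
    pi = np.zeros((m, 3, 3))
    prior_h = np.zeros((m, 3))
    transition = np.zeros((m, 3, 3))
    counts_self = np.stack(
        [np.sum(panel.genotypes == g, axis=1) for g in range(3)], axis=1
    )
    prior_self = (counts_self + s) / (n + 3 * s)

    for lo, hi in contig_ranges:
        for i in range(lo, hi):
            h = select_helper(panel, i, (lo, hi), smoothing)
            helper_id[i] = h
            if h < 0:
                # graceful degradation: uniform helper tables, never used
                pi[i] = np.full((3, 3), 1 / 9)
            else:
                pi[i] = genotype_cooccurrence(panel, i, h, smoothing)
            prior_h[i] = pi[i].sum(axis=0)
            transition[i] = pi[i] / prior_h[i][np.newaxis, :]
    return HelperTable(
        helper_id=helper_id,
        pi=pi,
        prior_h=prior_h,
        transition=transition,
        prior_self=prior_self,
    )
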