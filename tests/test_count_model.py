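"""Duplicate-count histograms and the mixture-of-Poissons likelihood."""

import math

import numpy as np
import pytest

from kmergt import (
    GenotypePanel,
    ReferenceGenome,
    allele_likelihood,
    build_count_model,
    build_frequency_model,
    build_graph,
    estimate_lambda0,
    individual_duplicate_count,
    make_variant,
)
from kmergt.count_model import D_MAX, log_allele_likelihood
from kmergt.kmer_index import SelectedKmers, encode_kmer
from kmergt.variant_graph import ALT, REF

from conftest import oracle_duplicate_count

# A SNP whose alt-allele kmer TTACC also occurs once on the reference path
# (segmental-duplication situation): reference carries the copy at 7..12.
DUP_SEQ = "GGGGTCGTTACCACTCTGTTCCCACGAGCGGCATTTCTGG"
DUP_POS, DUP_REF, DUP_ALT, DUP_KMER = 20, "C", "A", "TTACC"

# A SNP whose alt kmer ATGAC and ref kmer ATCAC are each unique.
UNIQ_SEQ = "CACTAAACCGAACAATCTATCACCAAGCGAATCCAGAGAG"
UNIQ_POS, UNIQ_REF, UNIQ_ALT = 20, "C", "G"
UNIQ_ALT_KMER, UNIQ_REF_KMER = "ATGAC", "ATCAC"


def _setup(seq, pos, ref_b, alt_b, haplotypes, k=5):
    v = make_variant(0, "c1", pos, ref_b, alt_b)
    reference = ReferenceGenome({"c1": seq})
    graph = build_graph(reference, [v])
    haps = np.asarray(haplotypes, dtype=np.uint8)
    panel = GenotypePanel((haps[:, 0::2] + haps[:, 1::2]).astype(np.uint8), haps)
    freq = build_frequency_model(graph, panel, k)
    return reference, graph, panel, freq


def _selection(ref_kmers, alt_kmers):
    return SelectedKmers(0, 0, set(ref_kmers), set(alt_kmers), 0.0)


class TestIndividualDuplicateCount:
    def test_unique_alt_kmer_doses(self):
        # individuals: HET (1,0), HOM_ALT (1,1), HOM_REF (0,0)
        _, graph, panel, freq = _setup(
            UNIQ_SEQ, UNIQ_POS, UNIQ_REF, UNIQ_ALT, [[1, 0, 1, 1, 0, 0]]
        )
        sel = _selection({UNIQ_REF_KMER}, {UNIQ_ALT_KMER})
        d = [
            individual_duplicate_count(graph, panel, freq, sel, ALT, t)
            for t in range(3)
        ]
        assert d == [1, 2, 0]

    def test_duplicated_alt_kmer_hom_ref_sees_two(self):
        """A homozygous-reference individual still carries the alt kmer
        twice, once per chromosome, through the duplicate site."""
        _, graph, panel, freq = _setup(
            DUP_SEQ, DUP_POS, DUP_REF, DUP_ALT, [[0, 0]]
        )
        sel = _selection({DUP_SEQ[18:23]}, {DUP_KMER})
        assert individual_duplicate_count(graph, panel, freq, sel, ALT, 0) == 2

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_written_out_genome_oracle(self, seed):
        """Graph-walk d equals brute-force counting on the written-out
        diploid genome, for every individual, variant and allele."""
        from kmergt import SimulationConfig, simulate_all
        from kmergt.variant_graph import enumerate_allele_windows
        from kmergt.kmer_index import select_variant_kmers

        config = SimulationConfig(
            genome_length=200, n_variants=8, n_individuals=4, coverage=5.0,
            read_length=50, indel_fraction=0.3, ld_block_length=3, seed=seed,
        )
        ds = simulate_all(config)
        graph = build_graph(ds.reference, ds.variants)
        k = 7
        freq = build_frequency_model(graph, ds.panel, k)
        for v in graph.variants:
            sel = select_variant_kmers(
                enumerate_allele_windows(graph, v.id, REF, k),
                enumerate_allele_windows(graph, v.id, ALT, k),
                freq,
                k,
            )
            for allele, kmers in ((REF, sel.ref_kmers), (ALT, sel.alt_kmers)):
                for t in range(ds.panel.n_individuals):
                    got = individual_duplicate_count(
                        graph, ds.panel, freq, sel, allele, t
                    )
                    expected = oracle_duplicate_count(
                        ds.reference["chr1"], ds.variants, ds.panel, t, kmers, k
                    )
                    assert got == expected


class TestBuildCountModel:
    def test_hand_tally_histograms(self):
        # 4 individuals: 2 HOM_REF, 2 HET; unique kmers
        _, graph, panel, freq = _setup(
            UNIQ_SEQ, UNIQ_POS, UNIQ_REF, UNIQ_ALT,
            [[0, 0, 0, 0, 1, 0, 0, 1]],
        )
        sel = {0: _selection({UNIQ_REF_KMER}, {UNIQ_ALT_KMER})}
        model = build_count_model(graph, panel, freq, sel, lambda0=4.0)
        alt = model.histograms[0, ALT]
        assert alt[0, 0] == 2  # HOM_REF individuals carry the alt kmer 0x
        assert alt[1, 1] == 2  # HET individuals carry it once
        assert alt[2].sum() == 1  # empty class filled by a pseudo-individual
        assert alt[2, 2] == 1  # idealized d for HOM_ALT is 2
        ref = model.histograms[0, REF]
        assert ref[0, 2] == 2 and ref[1, 1] == 2

    def test_duplicated_kmer_hom_ref_histogram_at_two(self):
        _, graph, panel, freq = _setup(
            DUP_SEQ, DUP_POS, DUP_REF, DUP_ALT, [[0, 0, 0, 0]]
        )
        sel = {0: _selection({DUP_SEQ[18:23]}, {DUP_KMER})}
        model = build_count_model(graph, panel, freq, sel, lambda0=4.0)
        alt_hom_ref = model.histograms[0, ALT, 0]
        assert alt_hom_ref[2] == 2 and alt_hom_ref[0] == 0

    def test_naive_mode_ignores_duplicates(self):
        _, graph, panel, freq = _setup(
            DUP_SEQ, DUP_POS, DUP_REF, DUP_ALT, [[0, 0, 0, 0]]
        )
        sel = {0: _selection({DUP_SEQ[18:23]}, {DUP_KMER})}
        model = build_count_model(graph, panel, freq, sel, lambda0=4.0, naive=True)
        assert model.histograms[0, ALT, 0, 0] == 2  # forced to ideal d=0

    def test_histogram_mass_equals_genotype_class_size(self, toy_dataset):
        from kmergt import build_index

        ds = toy_dataset
        archive = build_index(ds.reference, ds.variants, ds.panel, k=7, lambda0=4.0)
        hist = archive.count_model.histograms
        for v in archive.variants:
            for g in range(3):
                n_class = int((ds.panel.genotypes[v.id] == g).sum())
                for allele in (REF, ALT):
                    assert hist[v.id, allele, g].sum() == max(n_class, 1)


class TestAlleleLikelihood:
    def test_single_component_closed_form(self):
        hist = np.zeros(16)
        hist[2] = 5
        expected = 2.0 ** 2 * math.exp(-2.0) / 2  # Pois(2; 2.0)
        assert allele_likelihood(2, hist, 1.0, 0.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.27067, abs=1e-5)

    def test_zero_rate_point_mass(self):
        hist = np.zeros(16)
        hist[0] = 3
        assert allele_likelihood(0, hist, 2.0, 0.0) == 1.0
        assert allele_likelihood(1, hist, 2.0, 0.0) == 0.0

    def test_two_component_mixture(self):
        hist = np.zeros(16)
        hist[0] = hist[1] = 1
        expected = 0.5 * 1.0 + 0.5 * math.exp(-2.0)
        got = allele_likelihood(0, hist, 2.0, 0.0)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.56767, abs=1e-5)

    def test_negative_count_rejected(self):
        hist = np.zeros(16)
        hist[1] = 1
        with pytest.raises(ValueError):
            allele_likelihood(-1, hist, 2.0, 0.0)

    def test_log_version_matches_linear(self):
        hist = np.zeros(16)
        hist[0], hist[1], hist[3] = 2, 5, 1
        for K in (0, 1, 4, 9):
            assert log_allele_likelihood(K, hist, 3.0, 0.01) == pytest.approx(
                math.log(allele_likelihood(K, hist, 3.0, 0.01))
            )

    def test_normalizes_over_counts(self, toy_dataset):
        """Sum over K of the mixture is 1 for every stored histogram."""
        from kmergt import build_index

        ds = toy_dataset
        archive = build_index(ds.reference, ds.variants, ds.panel, k=7, lambda0=4.0)
        model = archive.count_model
        ks = np.arange(0, 201)
        for vid in range(model.n_variants):
            for allele in (REF, ALT):
                for g in range(3):
                    hist = model.histogram(vid, allele, g)
                    total = sum(
                        allele_likelihood(int(K), hist, model.lambda0, model.epsilon)
                        for K in ks
                    )
                    assert total == pytest.approx(1.0, abs=1e-9)

    def test_stochastic_likelihood_ordering(self):
        """With unique kmers and lambda0 >= 4, a HET truth's likelihood
        product beats both homozygous genotypes in >= 90% of draws."""
        rng = np.random.default_rng(17)
        lam = 4.0
        hists = {  # idealized unique-kmer histograms, one individual each
            g: {REF: _delta(dr), ALT: _delta(da)}
            for g, (dr, da) in {0: (2, 0), 1: (1, 1), 2: (0, 2)}.items()
        }
        wins = 0
        n_draws = 1000
        for _ in range(n_draws):
            k_ref = rng.poisson(lam * 1)
            k_alt = rng.poisson(lam * 1)
            scores = {
                g: allele_likelihood(k_ref, hists[g][REF], lam, 0.0)
                * allele_likelihood(k_alt, hists[g][ALT], lam, 0.0)
                for g in range(3)
            }
            if scores[1] > scores[0] and scores[1] > scores[2]:
                wins += 1
        assert wins / n_draws >= 0.90


def _delta(d):
    hist = np.zeros(D_MAX + 1)
    hist[d] = 1
    return hist


class TestEstimateLambda0:
    def test_arithmetic(self):
        assert estimate_lambda0(15, 150, 31) == pytest.approx(6.0)

    def test_read_length_equals_k(self):
        # a single window per read: lambda0 = (C/2) / L
        assert estimate_lambda0(2, 31, 31) == pytest.approx(1 / 31)

    @pytest.mark.parametrize("cov,length", [(0, 150), (-1, 150), (10, 20)])
    def test_domain_errors(self, cov, length):
        with pytest.raises(ValueError):
            estimate_lambda0(cov, length, 31)
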