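"""Canonical encoding, the population frequency model, kmer selection and
the kmer-to-node index."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmergt import (
    GenotypePanel,
    ReferenceGenome,
    build_frequency_model,
    build_graph,
    build_kmer_index,
    encode_kmer,
    encode_sequence,
    make_variant,
    select_variant_kmers,
)
from kmergt.kmer_index import KmerFrequencyModel, SelectedKmers
from kmergt.variant_graph import ALT, REF, AlleleWindowSet, enumerate_allele_windows

from conftest import oracle_population_frequency, revcomp

dna = st.text(alphabet="ACGT", min_size=1, max_size=31)


class TestEncodeKmer:
    def test_palindromic_ordering(self):
        code_aaa, fwd = encode_kmer("AAA")
        assert fwd and code_aaa == 0  # AAA encodes to 0, below TTT

    def test_canonical_pairing(self):
        assert encode_kmer("TTT")[0] == encode_kmer("AAA")[0]

    def test_all_3mers_give_32_classes(self):
        codes = {encode_kmer("".join(p))[0] for p in itertools.product("ACGT", repeat=3)}
        assert len(codes) == 32

    def test_non_acgt_skip_signal(self):
        assert encode_kmer("ACN") is None

    @given(dna)
    @settings(max_examples=200, deadline=None)
    def test_strand_invariance(self, kmer):
        assert encode_kmer(kmer)[0] == encode_kmer(revcomp(kmer))[0]

    @given(st.text(alphabet="ACGTN", min_size=5, max_size=80), st.integers(3, 9))
    @settings(max_examples=100, deadline=None)
    def test_vectorized_matches_scalar(self, seq, k):
        codes, valid = encode_sequence(seq, k)
        for i in range(max(0, len(seq) - k + 1)):
            enc = encode_kmer(seq[i : i + k])
            if enc is None:
                assert not valid[i]
            else:
                assert valid[i] and int(codes[i]) == enc[0]


def _panel(haplotypes):
    haps = np.asarray(haplotypes, dtype=np.uint8)
    genotypes = (haps[:, 0::2] + haps[:, 1::2]).astype(np.uint8)
    return GenotypePanel(genotypes, haps)


class TestBuildFrequencyModel:
    def test_absent_kmer_is_zero(self):
        g = build_graph(ReferenceGenome({"c1": "ACGTACCA"}), [])
        model = build_frequency_model(g, _panel(np.zeros((0, 4))), 3)
        assert model.lookup_kmer("GGG") == 0.0

    def test_reference_kmer_far_from_variants_is_two(self, toy_dataset):
        ds = toy_dataset
        g = build_graph(ds.reference, ds.variants)
        model = build_frequency_model(g, ds.panel, 7)
        seq = ds.reference["chr1"]
        # find a selected candidate kmer occurring once, > k-1 from variants
        occupied = set()
        for v in ds.variants:
            occupied.update(range(v.position - 7, v.end + 7))
        for wset in enumerate_allele_windows(g, 0, REF, 7):
            for kmer in wset.kmers:
                if seq.count(kmer) == 1 and seq.count(revcomp(kmer)) == 0:
                    pos = seq.find(kmer)
                    if all(p not in occupied for p in range(pos, pos + 7)):
                        assert model.lookup_kmer(kmer) == 2.0

    def test_alt_kmer_frequency_counts_carrier_haplotypes(self):
        # 2 individuals / 4 haplotypes; alt carried by exactly one haplotype;
        # the alt kmer (and its reverse complement) occur nowhere else
        seq = "CAGATTTTCATATTAT"
        v = make_variant(0, "c1", 7, "T", "C")
        g = build_graph(ReferenceGenome({"c1": seq}), [v])
        panel = _panel([[1, 0, 0, 0]])
        model = build_frequency_model(g, panel, 5)
        alt_kmer = seq[5:7] + "C" + seq[8:10]  # TTCCA
        assert seq.count(alt_kmer) == 0 and seq.count(revcomp(alt_kmer)) == 0
        assert model.lookup_kmer(alt_kmer) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_written_out_genomes_oracle(self, seed):
        """Graph-walk frequencies equal brute-force counting over all 2n
        written-out haplotype genomes, exactly."""
        from kmergt import SimulationConfig, simulate_all

        config = SimulationConfig(
            genome_length=200,
            n_variants=8,
            n_individuals=4,
            coverage=5.0,
            read_length=50,
            indel_fraction=0.3,
            ld_block_length=3,
            seed=seed,
        )
        ds = simulate_all(config)
        g = build_graph(ds.reference, ds.variants)
        assert len(g.variants) == len(ds.variants)
        k = 7
        model = build_frequency_model(g, ds.panel, k)
        oracle = oracle_population_frequency(
            ds.reference["chr1"], ds.variants, ds.panel, k
        )
        oracle_codes = {encode_kmer(km)[0]: f for km, f in oracle.items()}
        for code, freq in model.frequencies.items():
            assert freq == pytest.approx(oracle_codes.get(code, 0.0), abs=1e-12)


def _wset(vid, allele, offset, kmers, degenerate=False):
    return AlleleWindowSet(vid, allele, offset, set(kmers), degenerate)


def _freq(mapping, k=3):
    model = KmerFrequencyModel(k=k, n_individuals=1)
    for kmer, f in mapping.items():
        model.frequencies[encode_kmer(kmer)[0]] = f
    return model


class TestSelectVariantKmers:
    def test_lowest_maximum_wins(self):
        freq = _freq({"AAC": 2.0, "CCA": 4.0, "GGA": 4.0, "TTG": 1.0})
        ref = [_wset(0, REF, o, km) for o, km in [(-2, {"AAC"}), (-1, {"CCA"}), (0, {"GGA"})]]
        alt = [_wset(0, ALT, o, km) for o, km in [(-2, {"TTG"}), (-1, {"TTG"}), (0, {"TTG"})]]
        sel = select_variant_kmers(ref, alt, freq, 3)
        assert sel.offset == -2
        assert sel.chosen_score == 2.0

    def test_single_candidate_chosen_regardless_of_score(self):
        freq = _freq({"AAC": 99.0, "TTG": 99.0})
        sel = select_variant_kmers(
            [_wset(0, REF, 0, {"AAC"})], [_wset(0, ALT, 0, {"TTG"})], freq, 3
        )
        assert sel.offset == 0 and sel.chosen_score == 99.0

    def test_tie_breaks_toward_centred_offset(self):
        freq = _freq({"AAC": 2.0, "TTG": 2.0})
        offsets = [-2, -1, 0]
        ref = [_wset(0, REF, o, {"AAC"}) for o in offsets]
        alt = [_wset(0, ALT, o, {"TTG"}) for o in offsets]
        sel = select_variant_kmers(ref, alt, freq, 3)
        assert sel.offset == -1  # -floor((k-1)/2) for k=3

    def test_all_degenerate_falls_back_to_fewest_kmers(self):
        freq = _freq({"AAC": 1.0, "CCA": 1.0, "TTG": 1.0})
        ref = [
            _wset(0, REF, -1, {"AAC", "CCA"}, degenerate=True),
            _wset(0, REF, 0, {"AAC"}, degenerate=True),
        ]
        alt = [
            _wset(0, ALT, -1, {"TTG"}, degenerate=True),
            _wset(0, ALT, 0, {"TTG"}, degenerate=True),
        ]
        sel = select_variant_kmers(ref, alt, freq, 3)
        assert sel.offset == 0 and sel.low_confidence

    def test_selection_optimality(self, toy_dataset):
        """The chosen offset's max frequency is minimal over all offsets."""
        ds = toy_dataset
        g = build_graph(ds.reference, ds.variants)
        k = 7
        model = build_frequency_model(g, ds.panel, k)
        for v in g.variants:
            ref_w = enumerate_allele_windows(g, v.id, REF, k)
            alt_w = enumerate_allele_windows(g, v.id, ALT, k)
            sel = select_variant_kmers(ref_w, alt_w, model, k)
            by_off = {w.offset: w for w in ref_w}
            for aw in alt_w:
                if aw.offset in by_off and not aw.degenerate:
                    score = max(
                        model.lookup_kmer(km)
                        for km in by_off[aw.offset].kmers | aw.kmers
                    )
                    assert sel.chosen_score <= score + 1e-12


class TestBuildKmerIndex:
    def test_two_entries_for_one_variant(self):
        g = build_graph(
            ReferenceGenome({"c1": "ATCTGAGGTCCAATGC"}),
            [make_variant(0, "c1", 7, "G", "C")],
        )
        sel = {
            0: SelectedKmers(0, 0, {"GAGGT"}, {"GAGCT"}, 0.0)
        }
        index = build_kmer_index(g, sel, 5)
        assert len(index) == 2
        ref_node, alt_node = g.variant_nodes[0]
        assert index.lookup(encode_kmer("GAGGT")[0]) == [ref_node]
        assert index.lookup(encode_kmer("GAGCT")[0]) == [alt_node]

    def test_shared_kmer_lists_both_nodes(self):
        seq = "ATCTGAGGTCCAATGCATTGGACCTGAGGTACCA"
        variants = [
            make_variant(0, "c1", 7, "G", "C"),
            make_variant(1, "c1", 27, "G", "C"),
        ]
        g = build_graph(ReferenceGenome({"c1": seq}), variants)
        sel = {
            0: SelectedKmers(0, 0, {"AAAAA"}, {"GAGCT"}, 0.0),
            1: SelectedKmers(1, 0, {"CCCCC"}, {"GAGCT"}, 0.0),
        }
        index = build_kmer_index(g, sel, 5)
        hits = index.lookup(encode_kmer("GAGCT")[0])
        assert hits == [g.variant_nodes[0][1], g.variant_nodes[1][1]]

    def test_unseen_kmer_lookup_is_empty(self):
        g = build_graph(ReferenceGenome({"c1": "ATCTGAGG"}), [])
        index = build_kmer_index(g, {}, 5)
        assert index.lookup(encode_kmer("GGGGG")[0]) == []

    def test_index_completeness(self, toy_dataset):
        """Every selected kmer of every variant resolves to that variant's
        allele node."""
        from kmergt import build_index, estimate_lambda0

        ds = toy_dataset
        archive = build_index(
            ds.reference, ds.variants, ds.panel, k=7,
            lambda0=estimate_lambda0(8, 50, 7),
        )
        for vid, sel in archive.selections.items():
            ref_node, alt_node = archive.graph.variant_nodes[vid]
            for allele, node in ((REF, ref_node), (ALT, alt_node)):
                for code in sel.codes(allele):
                    assert node in archive.kmer_index.lookup(code)
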