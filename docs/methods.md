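# Methods

This note documents the model, the numerical and design choices behind
`kmergt`, what the synthetic data generator does and does not emulate,
and the known limitations.

## Genotype model

All variants are biallelic; genotypes are 0/0, 0/1 and 1/1, with 0/1
unordered (1|0 and 0|1 are the same genotype). For variant *i* with
observed allele kmer counts `K_i = (K_ir, K_ia)` and helper variant *h*,
the posterior is

    P(G_i | K_i, K_h) ∝ P(K_i | G_i) · Σ_{G_h} P(G_h) P(G_i|G_h) P(K_h|G_h)

computed over the nine (G_i, G_h) combinations and marginalized over
G_h, then normalized over G_i (the unnormalized form is a
proportionality; normalization over the three genotypes is implied).
`P(K_i | G_i)` is taken as the product of the reference-allele and
alternative-allele count likelihoods — the two counts are treated as
conditionally independent given the genotype. The helper likelihood
`P(K_h | G_h)` uses the same product form at the helper site.

Each allele likelihood is a mixture of Poissons with one component per
panel individual carrying that genotype, with rate `λ₀ (d + ε)` where
`d` is the individual's diploid copy number of the allele's selected
kmers. Individuals are grouped by `d`, so the model stores, per
(variant, allele, genotype), a histogram `c[d]` over the panel and
evaluates

    P(K) = Σ_d c[d]/Σc · Pois(K ; λ₀ (d + ε)),

a rate of zero being the point mass at K = 0. Likelihoods are
accumulated in log space and normalized by max-subtraction; Poisson
tails otherwise underflow at high coverage.

### Parameters

* `k` (kmer length): default 31, odd, ≤ 31 so a 2-bit canonical code
  fits one 64-bit word. Configurable down to 3 for toy instances.
* `λ₀` (expected read-kmer count per genome copy): derived from coverage
  C and read length L as `(C/2)·(L−k+1)/L` — a haploid-unique kmer is
  covered by C/2 reads, each contributing (L−k+1)/L of a full window.
  Can be set directly with `--lambda0`.
* `ε` (error-term rate): default 0.01. It gives non-zero likelihood to
  counts on alleles with d = 0 (sequencing errors produce occasional
  spurious kmers) without drowning real signal; the exact value is not
  critical, as it only matters for the relative penalty of small
  unexpected counts.
* `d_max = 15` with an overflow bin: duplicate counts beyond 15 clamp.
  Rates that large are indistinguishable in practice at these scales.
* Helper window: 100 variants on each side by sorted rank on the same
  contig, clipped at contig ends (so 200 neighbours in the interior).
* π smoothing: pseudo-count s = 1/n (n = panel size) on all 9 cells.
  The selection metric takes logs of the diagonal, so zeros must be
  regularized; the same smoothed π is used for selection and for the
  genotyping prior.

## Indexing

The variants are represented as an acyclic genome graph: one
reference-allele and one alternative-allele node per site, joined by
reference segments; deletions get an empty-sequence alt node, insertions
an empty ref node. Window enumeration considers, for each allele, every
offset in [−(k−1), 0] relative to the allele start on its path (the
junction position for empty alleles), and per offset every combination
of neighbouring variant alleles intersecting the window — capped at 2⁸
kmers per window; denser windows are marked degenerate and excluded
from selection (a fallback picks the smallest window set and flags the
variant low-confidence).

Every candidate kmer is scored by its expected number of copies in a
random panel individual's diploid genome. This is computed from an
occurrence catalog: every physical k-window in the graph spelling a
candidate kmer is recorded together with the set of (variant, allele)
constraints a haplotype must satisfy to carry it; the frequency is the
sum over occurrences of the fraction of consistent panel haplotypes,
times two chromosomes. Plain reference occurrences (no variant within
k−1 bases) contribute 2.0. The same catalog yields the per-individual
duplicate counts `d` by evaluating the constraints against the
individual's two phased haplotypes — equivalent to counting occurrences
in the written-out diploid genome for non-overlapping variants, which
the test suite verifies exactly against a string-scan oracle.

Per variant the offset minimizing the maximum frequency over the union
of its ref and alt kmer sets is selected; ties break toward the most
centred offset (kmers centred on the allele tolerate read-end errors
best), then the lower offset. Selected kmers go into a canonical-code →
allele-node index; a kmer chosen for several alleles lists all of them.

Genotype classes with no panel individual are filled with one
pseudo-individual at the genotype's idealized d (computed for a
hypothetical individual homozygous reference everywhere else), keeping
every mixture well defined at rare genotypes.

Counting is strand-oblivious: graph and read kmers are canonicalized to
min(kmer, reverse complement), since read orientation is unknown. A
read kmer hitting several nodes increments all of them; the count model
absorbs the ambiguity rather than resolving it.

Several (variant, allele) kmer sets may hold more than one kmer (one
per neighbouring-allele combination). Observed counts and duplicate
counts are *sums* over the set, which preserves the mean relationship
with the Poisson rate; evidence is aggregated additively rather than
multiplied per kmer.

## Output conventions

GL is log10 of the normalized posterior 3-vector (0/0, 0/1, 1/1),
floored at 1e-10; GQ is round(−10·log10(1 − max posterior)) capped at
99; calls are the argmax with ties broken 0/0 > 0/1 > 1/1. In
likelihoods-only mode the posterior is the normalized product of the
kmer likelihood and the population marginal P(G_i), and the GL field
carries the normalized kmer likelihood alone — pure kmer evidence,
suitable for downstream imputation. Helper-less variants (single
variant on a contig) fall back to the population marginal in full mode.

The naive-model ablation (`--naive-model`) forces duplicate counts to
the genotype-ideal doses (0/1/2 copies of the allele), reproducing a
genotyper that assumes every kmer unique; it exists to quantify what the
population duplicate-count model buys.

## Input handling

Internal coordinates are 0-based half-open; VCF I/O converts to and
from the 1-based anchored representation, and the original anchored
fields are kept for byte-stable round-trips. Multi-allelic records are
skipped with a warning (the model is strictly biallelic); missing panel
genotypes (./.) count as homozygous reference with the total logged —
a documented bias acceptable for rare missingness, not a statement of
intent for heavily incomplete panels. Overlapping variants keep the
first by position; the rest are skipped with a warning. The optional
allele-frequency filter (keep AF strictly above a threshold, e.g.
0.001) is off by default and meant for large public catalogues.
Unphased panel GTs are taken in the order written; within-individual
phase only affects duplicate-count bookkeeping when two sites share a
kmer, which non-overlapping biallelic sites rarely do.

## Synthetic data

The generator emulates the three inputs end to end with exact truth:

* reference: uniform random sequence, with optional planted segmental
  duplications (source interval copied elsewhere, degraded to a target
  identity) to create shared kmers;
* panel: mosaic-founder haplotypes — each haplotype copies one of a
  small founder set in blocks of `ld_block_length` consecutive
  variants, giving genotype correlation that decays with rank distance.
  This produces the LD structure the helper prior exploits with trivial
  code and exact truth; coalescent realism (recombination maps,
  mutation models, rare-variant site-frequency spectra) is deliberately
  not modelled;
* sample: drawn by the same mosaic process over the panel haplotypes
  (in-panel LD, novel combination);
* reads: single-end, uniform over both haplotypes, independent per-base
  substitution/insertion/deletion errors at 0.001 each by default, no
  quality-score model.

Consequences for interpretation: passing tests show the estimator is
correct under its own assumptions (biallelic, non-overlapping sites; a
panel that represents the sample; uniform coverage). They do not speak
to GC bias, coverage heterogeneity, contamination, panel
misrepresentation, or variant classes outside SNPs and ≤5 bp indels.

## Problem sizes

The default verification scale is a 100 kb genome with 500 variants and
a 50-individual panel at 15–30x coverage, with toy instances (200 bp, 8
variants, 4 individuals) for the exact string-scan oracle comparisons
and 20 kb replicates for the helper-prior comparison at 5x coverage —
the low-coverage regime is where a prior has the most to contribute,
which is what that comparison is designed to isolate. These sizes were
chosen so every stage, including brute-force oracles, runs comfortably
on a laptop-class machine while leaving all model structure (duplicate
kmers, LD, indels, errors) represented.

## Limitations

* Strictly biallelic, non-overlapping SNPs and short indels; no
  structural variants, no nested graphs.
* Single-sample genotyping; no joint calling, phasing or paired-end
  information (kmer counting cannot use read pairing).
* Accuracy depends on the panel representing the sample's ancestry;
  the model has no mechanism to detect panel mismatch.
* The helper prior uses a single neighbour; it is a fast stand-in for
  imputation, not a replacement for a full LD model — the
  likelihoods-only mode exists precisely so external imputation tools
  can be layered on top.
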