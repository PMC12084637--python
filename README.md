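# mutspectra

A toolkit for characterising germline mutation spectra in diploid
populations: it infers an ancestral genome from a whole-genome alignment,
polarizes population variants against it, counts per-sample K-mer SNV and
sequential-dinucleotide (SDM) spectra, normalizes them onto a common
scale, and runs the downstream comparisons (PCA, frequency-binned pulse
analysis, per-channel enrichment tests, and rank-1 signature extraction
with catalogue matching). It is aimed at population geneticists studying
how mutation rates differ and converge between populations, breeds and
species.

## The method

**Polarization.** For each biallelic SNV passing quality filters
(call rate ≥ 0.9, minor allele count > 2), the allele matching the
inferred ancestral base is the ancestral allele and the other the
derived allele; sites with undefined or non-matching ancestral bases, or
derived allele frequency (DAF) ≥ 0.98, are excluded. The ancestral base
comes from a per-position strict-majority vote over the ancestor rows of
MAF alignment blocks.

**Spectra.** Each variant is labelled with its ancestral K-mer context,
strand-collapsed so the central ancestral base is A or C — for K = 3
this gives the 96-channel layout, e.g. `A[C>T]G`. A sample's spectrum
counts the derived-allele copies it carries per channel (het = 1,
hom-derived = 2). Directly adjacent variant pairs are split into MNPs
(identical phased haplotype carriage — one mutational event) and SDMs
(different carriage — two events at different times); an SDM channel is
the ordered path `CA>TA>TG` (ancestral → intermediate → derived
dinucleotide), with the older event taken to be the higher-frequency
one.

**Normalization.** Channel counts are divided by the occurrence count of
their ancestral K-mer (or dinucleotide) in the ancestral genome, then
samples are equalised with median-of-ratios size factors

  ŝⱼ = medianᵢ kᵢⱼ / (∏ᵥ kᵢᵥ)^(1/m),

the median over channels i of sample j's rate divided by the channel's
geometric mean over all m samples. Sparse matrices first receive a small
pseudo-offset of 10^⌊log₁₀(smallest positive entry)⌋ wherever zeros are
present (e.g. smallest positive 3.5 × 10⁻⁹ → offset 10⁻⁹).

**Analyses.** PCA of normalized spectra; per-population DAF-binned
channel fractions, which localise mutation "pulses" confined to a narrow
frequency range; 2×2 chi-square enrichment tests of a channel's share
between two populations (Bonferroni-adjusted across channels); and
rank-1 nonnegative matrix factorization of a pooled spectrum, cosine-
matched against a signature catalogue (COSMIC SBS layout) with a 0.8
similarity cutoff.

A fully synthetic, truth-tracked data generator (`mutspectra.simdata`)
produces ancestral genomes, phased population VCFs with per-channel
rates, injected MNP/SDM pairs and MAF fixtures, so every stage is
testable end to end without external data.

## Worked example

Simulate two 12-diploid populations on a 150 kb genome where population
B carries a doubled `T[C>T]C` mutation rate, then run the pipeline:

```python
from mutspectra import simdata, polarize, snv, normalize, analyze

cfg = simdata.SimulationConfig(
    chrom_lengths={"chr1": 150_000},
    populations={"A": 12, "B": 12},
    variants_per_population=5000,
    rate_multipliers={"B": {"T[C>T]C": 2.0}},
    seed=3,
)
ds = simdata.simulate(cfg)
variants = list(polarize.polarize_sites(iter(ds.sites), ds.ancestral))

spectra = snv.count_spectra(variants, ds.samples, ds.ancestral, k=3)
targets = snv.kmer_targets(ds.ancestral, k=3)
rates = normalize.target_normalize(spectra, targets)
shifted, offset = normalize.zero_offset(rates)
normalized, factors = normalize.median_of_ratios(shifted)

by_pop = {p: [s for s in ds.samples if ds.populations[s] == p] for p in "AB"}
scan = analyze.enrichment_scan(
    spectra.loc[by_pop["A"]].sum(axis=0), spectra.loc[by_pop["B"]].sum(axis=0)
)
```

Output:

```
polarized 10046 of 10046 sites; rejections: none
spectra: 24 samples x 96 channels, 94821 derived-allele copies
pseudo-offset 0; size factors in [0.965, 1.065]
top enrichment hit: T[C>T]C (chi2=138.6, adjusted p=5.08e-30)
normalized T[C>T]C rate ratio B/A: 2.04
```

The enrichment scan correctly flags the boosted channel as the most
differentiated one between the populations, and the normalized
per-sample rate ratio recovers the planted 2× factor.

The same pipeline is available as subcommands of the `mutspectra` CLI
(`simulate`, `ancestor`, `polarize`, `spectrum`, `sdm`, `normalize`,
`analyze`); each command writes its outputs as TSV plus a
`manifest.json` recording parameters, input checksums and the seed.

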