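# Methods

## Ancestral genome reconstruction

The ancestral sequence is assembled in reference coordinates from MAF
alignment blocks that pair the reference genome with a named ancestor
row (as exported from a whole-genome alignment with `hal2maf`).
Internally all coordinates are 0-based half-open; reference rows written
on the '-' strand are converted to forward orientation (start
`srcSize - start - size`, both aligned texts reverse-complemented)
before assignment, so a single coordinate convention holds throughout.

Every reference position covered by a block collects one vote per
covering block: the aligned ancestor base, uppercased; ancestor gaps and
bases outside {A,C,G,T} vote `N`. A position is assigned a base only
when that base holds a **strict majority** (> 50%) of its votes;
plurality without majority, exact ties, and uncovered positions give
`N`. This is deliberately conservative: downstream K-mer windows must be
unambiguous, and a position where aligned blocks disagree is better
dropped than guessed. Soft-masking is not propagated — the spectrum
modules filter on base identity only.

Coverage (fraction of non-N bases, per chromosome and genome-wide) is
reported exactly as covered/length.

## Filtering and polarization

Sites are kept only if they are biallelic single-base substitutions with
allele call rate ≥ 0.9 (computed over allele slots, so half-missing
diploid calls contribute their observed allele only) and minor allele
count ≥ 3 (i.e. MAC > 2). The allele equal to the ancestral base is the
ancestral allele; if neither or an `N` underlies the site it is rejected
(`ancestral_mismatch` / `ancestral_undefined`). DAF is the derived-copy
fraction among non-missing alleles, and sites with DAF ≥ 0.98 are
rejected: a derived allele at near-fixation more plausibly reflects a
misassigned ancestral state. Every input site ends in exactly one
outcome — kept, or counted under one machine-readable rejection reason.
Multiallelic records are rejected rather than split, and no imputation
is performed; phasing and imputation are upstream concerns.

Cohort-wide DAF is used at the filtering stage; per-population DAF is
recomputed inside the frequency-binned analyses.

## K-mer spectra

A variant's channel is its ancestral K-mer (read from the ancestral
genome — the pre-mutation state — not the reference) plus the derived
base, strand-collapsed so the central ancestral base is A or C. For
K = 3 this yields 96 channels; K = 1 gives 6; any odd K is supported.
Channels whose window leaves the chromosome or contains non-ACGT bases
are rejected per variant.

Counting is per derived-allele copy per carrier (heterozygote 1,
homozygote 2) by default. Copy counting preserves each individual's
mutational load; the alternative of randomly allocating each variant to
a single carrier — which trades load information for robustness to
shared ancestry — is available as a seeded `random-allocation` mode.
The homozygote weight of 2 is a documented convention.

K-mer opportunity counts slide a K-window over every ancestral position;
windows containing non-ACGT are skipped and each valid window increments
its collapsed K-mer. CpG>TpG channels can be pooled with their
reverse-direction counterparts (`X[C>T]G` with the strand-collapse of
`X[T>C]G`, i.e. `C[A>G]X'`) to make the CpG deamination signal robust to
ancestral misassignment flipping the direction of change.

## SDM spectra

Adjacent polarized variants (distance exactly 1, same chromosome) are
paired; phased genotypes are required (unphased heterozygotes raise an
error, or pairs can be dropped with `unphased='drop'`). A pair is an MNP
when both derived alleles sit on identical haplotype sets — the
operational single-event signature, robust to coincidentally equal
frequencies — and an SDM otherwise. SDM order is inferred from DAF
(older = more frequent); exact ties go to an `unresolved:` channel
rather than a guess.

An SDM channel is the path ancestral → intermediate → derived
dinucleotide, where the intermediate applies the first event. Between a
path and its reverse complement (each dinucleotide complemented, its
positions swapped), the lexicographically smaller one — by ancestral
dinucleotide, then the full path — is the canonical label, giving a
deterministic 1:1 channel mapping that is invariant under genome-wide
reverse complementation. Per-sample counts are the number of haplotypes
carrying both derived alleles. Opportunity counts are canonical
ancestral-dinucleotide occurrences, the analogue of the K-mer targets.
Codon-position-aware SDM sub-classification would require a variant
annotation source and is out of scope.

## Normalization

Two stages. First, each channel's counts are divided by its ancestral
target count, turning counts into per-opportunity rates comparable
across genomes of different composition. Second, median-of-ratios size
factors ŝⱼ = medianᵢ kᵢⱼ/(∏ᵥ kᵢᵥ)^{1/m} equalise total mutation load
across samples; each sample's rates are divided by its factor. Channels
with zero geometric mean are excluded from the median; with an even
number of contributing channels the median is the mean of the two
central values.

Sparse matrices (the SDM matrix especially) would drive more than half
of a sample's ratios to zero, making its factor degenerate. When any
cell is zero, a pseudo-offset of 10^⌊log₁₀(smallest **positive**
entry)⌋ is added to every cell first (3.5 × 10⁻⁹ → 10⁻⁹); matrices
without zeros are left untouched. The offset is applied per matrix,
whenever zeros are present.

One numerical convention deserves note: the size-factor formula pins the
factors only up to a single global constant — multiplying every factor
by c and the normalized matrix by 1/c changes no ratio, ordering or
comparison the method supports, and re-deriving factors from a
normalized matrix returns that constant (the geometric mean of the
first-pass factors), not 1. The default implementation returns the
factors exactly as the formula prints them; `stabilize=True` pins the
free constant by rescaling factors to geometric mean 1, which makes the
operation exactly idempotent. Scale equivariance holds exactly in ratio
form: a sample that is c × another receives c × its factor and an
identical normalized row.

Cross-dataset combination concatenates target-normalized matrices with
identical channel sets and applies offset + median-of-ratios to the
joint matrix, placing all cohorts on one scale.

## Analyses

- **PCA** centers (and by default unit-scales) channels and uses an
  exact full SVD; constant channels are dropped. Standardization is the
  default because cross-cohort comparisons should not be dominated by
  high-opportunity channels; a flag disables it.
- **DAF-binned fractions** recompute DAF within each population and
  report, per half-open bin `(e, e']`, each channel's share of the bin's
  segregating variants. Default edges are logarithmic over
  (1/n_haplotypes, 0.98], resolving the ~1% frequency range where
  mutation-rate pulses concentrate.
- **Enrichment** tests one channel's share between two populations with
  Pearson's chi-square (1 df, no continuity correction) on the 2×2
  table [channel, all others] × [A, B]; expected cells < 5 flag the
  result `low_count` without suppressing it. The scan across channels
  adjusts with Bonferroni by default (BH and none available). Counts
  are per-carrier copy counts, matching the spectra.
- **Rank-1 NMF** is initialized from the leading singular pair (whose
  nonnegative rectification attains the rank-1 optimum up to scale) and
  refined with multiplicative updates until the relative reconstruction
  error changes by < 1e-9 (cap 1000 sweeps); the signature is
  normalized to sum 1. **Cosine matching** canonicalizes channel labels
  (this package's central-A/C convention and the COSMIC central-
  pyrimidine convention meet on the same canonical form), requires
  identical channel sets, and reports the best catalogue signature,
  unmatched below cosine 0.8.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
a random ancestral genome of configurable length and GC (default 200 kb
at 42% GC), a reference diverged from it at 0.5% of positions,
phased diploid cohorts (default two populations of 30), SNVs placed
channel-by-channel where the ancestral K-mer matches — expected numbers
proportional to per-channel rate multipliers × K-mer availability,
Poisson-realized — and derived-copy counts from a discretized
neutral-like 1/x distribution truncated to [3 copies, 0.98], so every
site clears the MAC filter. About 10% of sites are encoded with REF =
derived allele to exercise both polarization paths. Adjacent placements
are forbidden except for explicitly injected pairs: MNPs share carrier
sets; SDMs have nested carriers with distinct copy numbers and a known
event order. MAF fixtures align reference against ancestor with
configurable gaps, overrides (for conflict fixtures) and strands.

The default of 6000 variants per population gives each of the 96
channels ≈ 60 sites — enough for stable per-channel rate estimates at
the default genome size; with markedly fewer sites per channel the
heavy-tailed copy distribution (E[c²]/E[c] ≈ 30 at 60 haplotypes)
dominates per-channel totals. A low-frequency pulse (`PulseSpec`)
multiplies a channel's expected per-sample *carried-copy* rate by
`fold`, implementing the extra mass as many low-copy sites (default
3–6 copies); scaling by site count alone would not move the quantity
the spectra measure.

What the generator does **not** emulate: coalescent ancestry (no shared
genealogy, so no linkage disequilibrium or relatedness structure),
recombination, selection, sequencing error, or genotype uncertainty.
Passing recovery tests therefore demonstrate the pipeline's estimators
are correct under the stated sampling model, not that real cohorts are
free of confounding from demography or data quality.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng` from a single
  integer seed; identical seeds give byte-identical outputs.
- Zero-target channels in normalization, all-zero matrices in offset or
  NMF, constant matrices in PCA, and non-increasing bin edges raise
  errors rather than producing NaNs.
- Ancestral-genome ties break to `N` (never to an arbitrary base); SDM
  frequency ties break to `unresolved` (never to an arbitrary order).
- Medians of even-length sets are means of the central pair; floors of
  log10 define the pseudo-offset exponent.

## Limitations

- Per-channel enrichment chi-square treats carried copies as independent
  observations; copies at one segregating site are shared across
  carriers, so the test is anti-conservative for channels dominated by
  few high-frequency sites. At the paper-scale regime (millions of
  variants) this is standard practice; on small cohorts interpret
  per-channel p-values comparatively.
- The SDM order rule (older = higher DAF) is a point estimate; drift can
  invert frequencies, which the synthetic truth (built with the same
  monotone assumption) does not exercise.
- Consequence-aware sub-spectra (coding vs intergenic) require an
  annotation source and are not implemented.
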