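"""Truth-tracked synthetic data for the whole pipeline.

Generates an ancestral genome, a diverged reference, population VCFs
whose sites are placed channel-by-channel with configurable relative
rates and a derived-allele-frequency distribution, injected adjacent
variant pairs (MNPs sharing haplotype carriage, SDMs with nested
carriage and distinct frequencies), and MAF alignment fixtures with
known ancestor truth.  Every random draw flows from a single seed, and
the emitted truth tables are sufficient to recompute each module's
output exactly.

The generator emulates the statistical structure the spectra modules
assume — channel-specific mutation rates over ancestral K-mer
opportunities, a neutral-like 1/x frequency distribution, phased diploid
genotypes — not a population-genetic ancestry process (no coalescent,
recombination or selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import IO, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .ancestral import AncestralGenome
from .polarize import SiteRecord
from .snv import channel_labels, collapse_kmer, parse_label

__all__ = [
    "SimulationConfig",
    "PulseSpec",
    "SimulatedDataset",
    "MafBlockSpec",
    "gen_ancestral",
    "gen_population_vcf",
    "gen_sdm_pairs",
    "gen_maf",
    "simulate",
]

_BASES = "ACGT"


@dataclass
class PulseSpec:
    """An excess of one channel confined to low derived-allele counts.

    ``fold`` multiplies the channel's expected per-sample carried-copy
    rate in ``population`` (fold 2 doubles what the spectra measure);
    the extra sites carry derived-copy counts drawn uniformly from
    ``copies_range`` (inclusive), placing the excess in the
    low-frequency bins.
    """

    population: str
    channel: str = "T[C>T]C"
    fold: float = 2.0
    copies_range: tuple[int, int] = (3, 6)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the fixture used throughout the test-bench: a
    200 kb two-chromosome genome at 42% GC, two populations of 30
    diploids, ~6000 variants per population spread over the 96 K=3
    channels in proportion to ancestral K-mer availability (a density
    chosen so each channel collects enough sites, ~60, for stable
    per-channel rate estimates at this genome size), a neutral-like 1/x
    derived-allele-count distribution starting at 3 copies (so every
    site clears the MAC > 2 filter), and 0.5% ancestral-to-reference
    divergence.
    """

    chrom_lengths: dict[str, int] = dc_field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 100_000}
    )
    gc: float = 0.42
    k: int = 3
    populations: dict[str, int] = dc_field(
        default_factory=lambda: {"A": 30, "B": 30}
    )
    variants_per_population: int = 6000
    rate_multipliers: dict[str, dict[str, float]] = dc_field(default_factory=dict)
    pulse: Optional[PulseSpec] = None
    min_copies: int = 3
    daf_kind: str = "neutral"  # or "uniform"
    daf_max: float = 0.98
    ref_divergence: float = 0.005
    flip_prob: float = 0.1  # REF=derived VCF encoding probability
    sdm_pairs_per_population: dict[str, int] = dc_field(default_factory=dict)
    mnp_pairs_per_population: dict[str, int] = dc_field(default_factory=dict)
    seed: int = 0

    def sample_names(self) -> list[str]:
        return [
            f"{pop}{i:03d}" for pop, n in self.populations.items() for i in range(n)
        ]

    def population_map(self) -> dict[str, str]:
        return {s: s.rstrip("0123456789") for s in self.sample_names()}


@dataclass
class SimulatedDataset:
    """Everything one seeded simulation produced."""

    config: SimulationConfig
    ancestral: AncestralGenome
    reference: dict[str, str]
    samples: list[str]
    populations: dict[str, str]
    sites: list[SiteRecord]
    snv_truth: pd.DataFrame
    sdm_truth: pd.DataFrame
    divergence_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# Genome generation


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(_BASES[i] for i in idx)


def gen_ancestral(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[AncestralGenome, dict[str, str], pd.DataFrame]:
    """Ancestral genome + diverged reference + substitution truth table."""
    sequences = {}
    reference = {}
    truth_rows = []
    for chrom, length in config.chrom_lengths.items():
        if length < 1000:
            raise ValueError("chromosomes shorter than 1 kb are not supported")
        anc = _random_sequence(length, config.gc, rng)
        ref = list(anc)
        n_sub = rng.binomial(length, config.ref_divergence)
        positions = rng.choice(length, size=n_sub, replace=False)
        for pos in sorted(positions.tolist()):
            old = ref[pos]
            choices = [b for b in _BASES if b != old]
            new = choices[int(rng.integers(3))]
            ref[pos] = new
            truth_rows.append({"chrom": chrom, "pos0": pos, "anc": old, "ref": new})
        sequences[chrom] = anc
        reference[chrom] = "".join(ref)
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos0", "anc", "ref"])
    return AncestralGenome(sequences=sequences), reference, truth


# ---------------------------------------------------------------------------
# Eligible-position bookkeeping


def _eligible_positions(
    ancestral: AncestralGenome, reference: dict[str, str], k: int
) -> dict[str, list[tuple[str, int]]]:
    """Map collapsed K-mer -> (chrom, 0-based central position) lists.

    Positions where the reference diverged from the ancestor are
    excluded so every simulated site has REF equal to the ancestral
    base before optional encoding flips.
    """
    h = k // 2
    out: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in ancestral.sequences.items():
        ref = reference[chrom]
        for pos in range(h, len(seq) - h):
            window = seq[pos - h : pos + h + 1]
            if any(b not in _BASES for b in window):
                continue
            if ref[pos] != seq[pos]:
                continue
            out.setdefault(collapse_kmer(window), []).append((chrom, pos))
    return out


class _PositionPool:
    """Draws variant positions while forbidding reuse and adjacency."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def blocked(self, chrom: str, pos: int) -> bool:
        return any((chrom, pos + d) in self.used for d in (-1, 0, 1))

    def take(self, chrom: str, pos: int) -> None:
        self.used.add((chrom, pos))

    def draw(
        self, candidates: Sequence[tuple[str, int]], n: int
    ) -> list[tuple[str, int]]:
        picks: list[tuple[str, int]] = []
        if not candidates or n <= 0:
            if n > 0:
                raise ValueError("requested sites exceed eligible positions")
            return picks
        order = self.rng.permutation(len(candidates))
        for idx in order:
            chrom, pos = candidates[idx]
            if self.blocked(chrom, pos):
                continue
            self.take(chrom, pos)
            picks.append((chrom, pos))
            if len(picks) == n:
                return picks
        raise ValueError("requested sites exceed eligible positions")


# ---------------------------------------------------------------------------
# Population VCF generation


def _copies_distribution(
    n_haplotypes: int, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the derived-copy-count distribution."""
    lo = config.min_copies
    hi = max(int(np.floor(config.daf_max * n_haplotypes)), lo)
    support = np.arange(lo, hi + 1)
    if config.daf_kind == "neutral":
        w = 1.0 / support
    elif config.daf_kind == "uniform":
        w = np.ones_like(support, dtype=float)
    else:
        raise ValueError(f"unknown DAF distribution {config.daf_kind!r}")
    return support, w / w.sum()


def _draw_copies(
    n: int,
    n_haplotypes: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Derived-copy counts following the configured DAF distribution."""
    support, p = _copies_distribution(n_haplotypes, config)
    return rng.choice(support, size=n, p=p)


def _site_record(
    chrom: str,
    pos0: int,
    anc_base: str,
    derived_base: str,
    carrier_haps: Sequence[int],
    hap_offset: int,
    n_samples: int,
    flip: bool,
) -> SiteRecord:
    """Assemble a phased SiteRecord from cohort-wide haplotype indices."""
    derived_code = 0 if flip else 1
    anc_code = 1 - derived_code
    gts = [[anc_code, anc_code] for _ in range(n_samples)]
    for h in carrier_haps:
        g = hap_offset + h
        gts[g // 2][g % 2] = derived_code
    ref, alt = (derived_base, anc_base) if flip else (anc_base, derived_base)
    return SiteRecord(
        chrom=chrom,
        pos=pos0 + 1,
        ref=ref,
        alts=(alt,),
        genotypes=[tuple(g) for g in gts],
        phased=[True] * n_samples,
    )


def gen_population_vcf(
    config: SimulationConfig,
    ancestral: AncestralGenome,
    reference: dict[str, str],
    rng: np.random.Generator,
    pool: _PositionPool | None = None,
) -> tuple[list[SiteRecord], pd.DataFrame]:
    """Simulate population-private SNVs over all channels.

    Expected site numbers per (population, channel) are proportional to
    the channel's rate multiplier times its ancestral K-mer availability,
    scaled so each population expects ``variants_per_population`` sites;
    realized numbers are Poisson.  An optional :class:`PulseSpec` adds a
    low-frequency-only excess for one channel in one population.
    Returns phased sites (unsorted) plus an exact truth table.
    """
    pool = pool or _PositionPool(rng)
    labels = channel_labels(config.k)
    eligible = _eligible_positions(ancestral, reference, config.k)
    samples = config.sample_names()
    n_samples = len(samples)
    truth_rows = []
    sites: list[SiteRecord] = []

    hap_offset = 0
    for pop, n_dip in config.populations.items():
        n_hap = 2 * n_dip
        mults = config.rate_multipliers.get(pop, {})
        avail = np.array(
            [len(eligible.get(parse_label(lab).anc_kmer, ())) for lab in labels],
            dtype=float,
        )
        if avail.sum() <= 0:
            raise ValueError("no eligible positions for any channel")
        weights = avail * np.array([mults.get(lab, 1.0) for lab in labels])
        # scale fixed by the multiplier-free baseline, so a channel multiplier
        # of 2 doubles that channel's absolute rate instead of being
        # renormalized against the other channels
        lam = config.variants_per_population * weights / avail.sum()
        for lab, l in zip(labels, lam):
            mt = parse_label(lab)
            n_sites = int(rng.poisson(l))
            extra = 0
            if (
                config.pulse is not None
                and config.pulse.population == pop
                and config.pulse.channel == lab
            ):
                # fold applies to the channel's per-sample carried-copy rate
                # (what the spectra measure): pulse sites carry few copies
                # each, so the extra site count is scaled by the ratio of
                # mean copies per site, baseline vs pulse
                support, p = _copies_distribution(n_hap, config)
                mean_base = float(support @ p)
                lo, hi = config.pulse.copies_range
                mean_pulse = (lo + hi) / 2.0
                extra = int(
                    rng.poisson((config.pulse.fold - 1.0) * l * mean_base / mean_pulse)
                )
            if n_sites + extra == 0:
                continue
            positions = pool.draw(eligible.get(mt.anc_kmer, []), n_sites + extra)
            copies = np.concatenate(
                [
                    _draw_copies(n_sites, n_hap, config, rng),
                    rng.integers(
                        config.pulse.copies_range[0],
                        config.pulse.copies_range[1] + 1,
                        size=extra,
                    )
                    if extra
                    else np.zeros(0, dtype=int),
                ]
            )
            for (chrom, pos0), c in zip(positions, copies):
                window = ancestral.sequences[chrom][
                    pos0 - config.k // 2 : pos0 + config.k // 2 + 1
                ]
                if window == mt.anc_kmer:
                    anc_base, derived_base = mt.central, mt.derived_base
                else:  # site realizes the channel on the reverse strand
                    anc_base = revcomp(mt.central)
                    derived_base = revcomp(mt.derived_base)
                carriers = rng.choice(n_hap, size=int(c), replace=False)
                flip = bool(rng.random() < config.flip_prob)
                sites.append(
                    _site_record(
                        chrom,
                        pos0,
                        anc_base,
                        derived_base,
                        carriers.tolist(),
                        hap_offset,
                        n_samples,
                        flip,
                    )
                )
                truth_rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos0 + 1,
                        "population": pop,
                        "channel": lab,
                        "anc": anc_base,
                        "derived": derived_base,
                        "copies": int(c),
                        "daf": c / (2 * n_samples),
                        "carrier_haps": ",".join(
                            str(hap_offset + h) for h in sorted(carriers.tolist())
                        ),
                        "flipped": flip,
                        "is_pulse": False,
                    }
                )
            # mark which of this channel's rows were pulse-injected
            if extra:
                for row in truth_rows[-extra:]:
                    row["is_pulse"] = True
        hap_offset += n_hap
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "pos",
            "population",
            "channel",
            "anc",
            "derived",
            "copies",
            "daf",
            "carrier_haps",
            "flipped",
            "is_pulse",
        ],
    )
    return sites, truth


# ---------------------------------------------------------------------------
# Adjacent-pair injection


def gen_sdm_pairs(
    config: SimulationConfig,
    ancestral: AncestralGenome,
    reference: dict[str, str],
    rng: np.random.Generator,
    pool: _PositionPool | None = None,
) -> tuple[list[SiteRecord], pd.DataFrame]:
    """Inject adjacent variant pairs with known class and order.

    MNP injections put both derived alleles on the same haplotype set;
    SDM injections give the first (older) event a strictly larger,
    nested carrier set, so classification and order are fully determined
    by the truth table.
    """
    pool = pool or _PositionPool(rng)
    samples = config.sample_names()
    n_samples = len(samples)
    truth_rows = []
    sites: list[SiteRecord] = []

    # candidate left positions: both bases (plus one flank each side for
    # K-mer context) clean and un-diverged
    candidates = []
    for chrom, seq in ancestral.sequences.items():
        ref = reference[chrom]
        for pos in range(1, len(seq) - 2):
            quad = seq[pos - 1 : pos + 3]
            if any(b not in _BASES for b in quad):
                continue
            if ref[pos] != seq[pos] or ref[pos + 1] != seq[pos + 1]:
                continue
            candidates.append((chrom, pos))

    hap_offset = 0
    for pop, n_dip in config.populations.items():
        n_hap = 2 * n_dip
        specs = [("MNP", config.mnp_pairs_per_population.get(pop, 0))] + [
            ("SDM", config.sdm_pairs_per_population.get(pop, 0))
        ]
        for kind, count in specs:
            for _ in range(count):
                order_idx = rng.permutation(len(candidates))
                for idx in order_idx:
                    chrom, pos = candidates[idx]
                    if not pool.blocked(chrom, pos) and not pool.blocked(
                        chrom, pos + 1
                    ):
                        pool.take(chrom, pos)
                        pool.take(chrom, pos + 1)
                        break
                else:
                    raise ValueError("requested pairs exceed eligible positions")
                anc_l = ancestral.sequences[chrom][pos]
                anc_r = ancestral.sequences[chrom][pos + 1]
                der_l = [b for b in _BASES if b != anc_l][int(rng.integers(3))]
                der_r = [b for b in _BASES if b != anc_r][int(rng.integers(3))]
                if kind == "MNP":
                    c = int(
                        rng.integers(config.min_copies, max(n_hap // 3, config.min_copies + 1))
                    )
                    carriers = rng.choice(n_hap, size=c, replace=False).tolist()
                    carriers_l = carriers_r = sorted(carriers)
                    order = ""
                else:
                    c_high = int(rng.integers(config.min_copies + 1, n_hap // 2))
                    c_low = int(rng.integers(config.min_copies, c_high))
                    first = rng.choice(n_hap, size=c_high, replace=False)
                    second = rng.choice(first, size=c_low, replace=False)
                    if rng.random() < 0.5:
                        order = "left_first"
                        carriers_l, carriers_r = sorted(first.tolist()), sorted(
                            second.tolist()
                        )
                    else:
                        order = "right_first"
                        carriers_l, carriers_r = sorted(second.tolist()), sorted(
                            first.tolist()
                        )
                for p0, anc_b, der_b, carr in (
                    (pos, anc_l, der_l, carriers_l),
                    (pos + 1, anc_r, der_r, carriers_r),
                ):
                    sites.append(
                        _site_record(
                            chrom, p0, anc_b, der_b, carr, hap_offset, n_samples, False
                        )
                    )
                truth_rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos + 1,  # 1-based left position
                        "population": pop,
                        "kind": kind,
                        "order": order,
                        "anc_dinuc": anc_l + anc_r,
                        "derived_dinuc": der_l + der_r,
                        "copies_left": len(carriers_l),
                        "copies_right": len(carriers_r),
                        "carriers_left": ",".join(
                            str(hap_offset + h) for h in carriers_l
                        ),
                        "carriers_right": ",".join(
                            str(hap_offset + h) for h in carriers_r
                        ),
                    }
                )
        hap_offset += n_hap
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "pos",
            "population",
            "kind",
            "order",
            "anc_dinuc",
            "derived_dinuc",
            "copies_left",
            "copies_right",
            "carriers_left",
            "carriers_right",
        ],
    )
    return sites, truth


# ---------------------------------------------------------------------------
# MAF fixtures


@dataclass
class MafBlockSpec:
    """One MAF block over reference span [start, end) of one chromosome.

    ``anc_gaps`` lists reference positions aligned to a gap in the
    ancestor row; ``anc_override`` substitutes the ancestor base at given
    positions (for conflicting-overlap fixtures); ``strand`` '-' writes
    the reference row in reverse-complement MAF convention.
    """

    chrom: str
    start: int
    end: int
    anc_gaps: frozenset[int] = dc_field(default_factory=frozenset)
    anc_override: dict[int, str] = dc_field(default_factory=dict)
    strand: str = "+"


def gen_maf(
    reference: dict[str, str],
    ancestral: AncestralGenome,
    blocks: Sequence[MafBlockSpec],
    out: str | IO[str],
    ref_name: str = "ref",
    anc_name: str = "anc",
) -> None:
    """Write a MAF fixture aligning reference and ancestor rows.

    Each block aligns the reference span against the ancestral sequence
    over the same coordinates (an identity alignment apart from the
    requested gaps and overrides), so the reconstruction truth is the
    ancestral sequence itself on covered, ungapped spans.
    """
    handle: IO[str]
    close = False
    if isinstance(out, str):
        handle = open(out, "w")
        close = True
    else:
        handle = out
    try:
        handle.write("##maf version=1 scoring=none\n")
        for spec in blocks:
            ref_seq = reference[spec.chrom]
            anc_seq = ancestral.sequences[spec.chrom]
            if spec.end > len(ref_seq) or spec.start < 0 or spec.start >= spec.end:
                raise ValueError(f"block span outside {spec.chrom}")
            ref_text = []
            anc_text = []
            for pos in range(spec.start, spec.end):
                ref_text.append(ref_seq[pos])
                if pos in spec.anc_gaps:
                    anc_text.append("-")
                else:
                    anc_text.append(spec.anc_override.get(pos, anc_seq[pos]))
            ref_aln = "".join(ref_text)
            anc_aln = "".join(anc_text)
            size = spec.end - spec.start
            src_size = len(ref_seq)
            if spec.strand == "-":
                start = src_size - spec.end
                ref_aln = revcomp(ref_aln)
                anc_aln = revcomp(anc_aln)
                strand = "-"
            else:
                start = spec.start
                strand = "+"
            anc_ungapped = len(anc_aln) - anc_aln.count("-")
            handle.write("a score=0.000000\n")
            handle.write(
                f"s {ref_name}.{spec.chrom} {start} {size} {strand} {src_size} {ref_aln}\n"
            )
            handle.write(
                f"s {anc_name}.{spec.chrom} 0 {anc_ungapped} + {anc_ungapped} {anc_aln}\n"
            )
            handle.write("\n")
    finally:
        if close:
            handle.close()


def write_vcf(dataset: "SimulatedDataset", path: str) -> None:
    """Write the simulated cohort as a phased VCF 4.x file."""
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in dataset.config.chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in dataset.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for site in dataset.sites:
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref, site.alt),
            )
            for i, s in enumerate(dataset.samples):
                rec.samples[s]["GT"] = site.genotypes[i]
                rec.samples[s].phased = site.phased[i]
            out.write(rec)


# ---------------------------------------------------------------------------
# One-call simulation


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator under the config's seed."""
    rng = np.random.default_rng(config.seed)
    ancestral, reference, div_truth = gen_ancestral(config, rng)
    pool = _PositionPool(rng)
    snv_sites, snv_truth = gen_population_vcf(
        config, ancestral, reference, rng, pool=pool
    )
    sdm_sites, sdm_truth = gen_sdm_pairs(config, ancestral, reference, rng, pool=pool)
    sites = sorted(snv_sites + sdm_sites, key=lambda s: (s.chrom, s.pos))
    return SimulatedDataset(
        config=config,
        ancestral=ancestral,
        reference=reference,
        samples=config.sample_names(),
        populations=config.population_map(),
        sites=sites,
        snv_truth=snv_truth,
        sdm_truth=sdm_truth,
        divergence_truth=div_truth,
    )
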